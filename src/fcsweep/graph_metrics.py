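"""Five topological metrics on binary undirected networks.

Distances are hop counts on the binarized graph. Conventions for
disconnected graphs are explicit: inverse distance of an unreachable pair is
zero, and the average path length is taken over the reachable pairs only
(flagged). Betweenness is normalized by (N-1)(N-2)/2 over unordered pairs.
"""

from __future__ import annotations

import numpy as np

from .types import MetricsRecord

_INF = np.inf


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    return a.astype(np.int64)


def shortest_paths(adjacency: np.ndarray) -> np.ndarray:
    """Hop-count distance matrix via layered BFS; unreachable pairs are inf."""
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    dist = np.full((n, n), _INF)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier @ a > 0) & ~reached
        dist[frontier] = d
        reached |= frontier
    return dist


def global_efficiency(adjacency: np.ndarray,
                      _dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest path length over ordered pairs (1/inf := 0)."""
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    dist = shortest_paths(a) if _dist is None else _dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(adjacency: np.ndarray) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency.

    Nodes with fewer than two neighbors contribute zero.
    """
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    if n == 0:
        raise ValueError("local efficiency needs at least 1 node")
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if nbrs.size < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def betweenness(adjacency: np.ndarray,
                normalized: bool = True) -> tuple[np.ndarray, float]:
    """Shortest-path betweenness per node (Brandes accumulation) and its mean.

    Raw scores count unordered source-target pairs; normalization divides by
    (N-1)(N-2)/2, the number of pairs excluding the node itself.
    """
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    neighbors = [np.nonzero(a[i])[0] for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source BFS with path counting
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = [s]
        queue = [s]
        while queue:
            nxt = []
            for v in queue:
                for w in neighbors[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                        order.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = nxt
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair counted from both endpoints
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc, float(bc.mean())


def clustering_coefficient(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node triangle density 2*T_i / (k_i (k_i - 1)) and its mean.

    Degree-0 and degree-1 nodes score zero; the network value is the
    unweighted mean over all nodes.
    """
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    if n == 0:
        return np.zeros(0), 0.0
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    cc = np.zeros(n)
    ok = deg >= 2
    cc[ok] = 2.0 * triangles[ok] / (deg[ok] * (deg[ok] - 1))
    return cc, float(cc.mean())


def avg_path_length(adjacency: np.ndarray,
                    _dist: np.ndarray | None = None) -> tuple[float, bool]:
    """Mean hop distance over reachable pairs, plus a connectivity flag."""
    a = _check_adjacency(adjacency)
    dist = shortest_paths(a) if _dist is None else _dist
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = off & np.isfinite(dist)
    if not finite.any():
        raise ValueError("no connected node pair: average path length undefined")
    connected = bool(finite.sum() == off.sum())
    return float(dist[finite].mean()), connected


def metrics_record(adjacency: np.ndarray) -> MetricsRecord:
    """Bundle the five metrics for one network."""
    a = _check_adjacency(adjacency)
    dist = shortest_paths(a)
    l_avg, connected = avg_path_length(a, _dist=dist)
    _, bc_mean = betweenness(a)
    _, cc = clustering_coefficient(a)
    return MetricsRecord(
        e_glob=global_efficiency(a, _dist=dist),
        e_loc=local_efficiency(a),
        bc_mean=bc_mean,
        cc=cc,
        l_avg=l_avg,
        connected=connected,
    )
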