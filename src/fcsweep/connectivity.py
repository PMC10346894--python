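"""ROI signal extraction, Fisher-z connectivity and FDR-thresholded adjacency.

Per subject: node time series are the unweighted voxel means within each ROI,
Pearson-correlated pairwise and mapped through arctanh. At the group level
each edge gets a one-sample two-sided t-test of the subject z-values against
zero, Benjamini–Hochberg correction over all N(N-1)/2 edges jointly, and the
rejected edges form a binary symmetric adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import FmriImage, RoiAtlas, RoiTimeseries
from .synthetic_data import standardize_rows

#: p-value floor for edges with zero across-subject variance but nonzero mean.
P_FLOOR = 1e-30

#: |r| is clipped here before arctanh so degenerate inputs stay finite.
R_CLIP = 1.0 - 1e-7


def extract_roi_timeseries(image: FmriImage, atlas: RoiAtlas) -> RoiTimeseries:
    """Mean voxel signal per node, rows standardized to zero mean / unit SD."""
    if image.data.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: image {image.data.shape[:3]} vs atlas {atlas.labels.shape}"
        )
    labels = atlas.labels.ravel()
    data = image.data.reshape(labels.size, image.n_volumes)
    n = atlas.n_nodes
    counts = np.bincount(labels, minlength=n + 1)[1:]
    empty = np.nonzero(counts == 0)[0] + 1
    if empty.size:
        raise ValueError(f"atlas labels with zero voxels: {empty.tolist()}")
    sums = np.zeros((n, image.n_volumes))
    np.add.at(sums, labels[labels > 0] - 1, data[labels > 0])
    means = sums / counts[:, None]
    sd = means.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        names = [atlas.node_names[i] for i in flat]
        raise ValueError(f"zero-variance node time series for: {names}")
    return RoiTimeseries(matrix=standardize_rows(means),
                         node_names=list(atlas.node_names), tr_s=image.tr_s)


def correlation_matrix(ts: RoiTimeseries | np.ndarray) -> np.ndarray:
    """Pearson correlation between all node pairs; symmetric, unit diagonal."""
    matrix = ts.matrix if isinstance(ts, RoiTimeseries) else np.asarray(ts, dtype=float)
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 time points for a correlation matrix")
    if np.any(matrix.std(axis=1) == 0):
        raise ValueError("zero-variance rows cannot be correlated")
    r = np.corrcoef(matrix)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """arctanh(r); |r| clipped just below 1 so perfect correlations stay finite."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(z) if np.isscalar(r) else z


def connectivity_z(ts: RoiTimeseries | np.ndarray) -> np.ndarray:
    """Subject connectivity matrix: Fisher z of the correlations, zero diagonal."""
    z = fisher_z(correlation_matrix(ts))
    np.fill_diagonal(z, 0.0)
    return z


@dataclass
class GroupEdgeStats:
    """Edge-wise group statistics over the upper-triangle pair family."""

    node_names: list[str]
    pairs: np.ndarray     # M x 2 node indices, i < j
    mean_z: np.ndarray    # M
    t: np.ndarray         # M
    p: np.ndarray         # M two-sided
    q: np.ndarray         # M BH-adjusted
    n_subjects: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def group_edge_test(z_matrices: list[np.ndarray] | np.ndarray,
                    node_names: list[str] | None = None) -> GroupEdgeStats:
    """One-sample two-sided t-test of subject Fisher-z values per edge.

    df = n_subjects - 1. Edges with zero across-subject variance get p = 1
    when the mean is zero, else the floor ``P_FLOOR``.
    """
    z = np.asarray(z_matrices, dtype=np.float64)
    if z.ndim != 3 or z.shape[1] != z.shape[2]:
        raise ValueError("expected a stack of square z matrices")
    n_sub, n = z.shape[0], z.shape[1]
    if n_sub < 2:
        raise ValueError("group test needs at least 2 subjects")
    if node_names is None:
        node_names = [f"node{i:02d}" for i in range(1, n + 1)]
    iu = np.triu_indices(n, k=1)
    vals = z[:, iu[0], iu[1]]  # n_sub x M
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    p = np.ones_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n_sub))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n_sub - 1)
    degenerate = (~ok) & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    p[degenerate] = P_FLOOR
    q = bh_qvalues(p)
    return GroupEdgeStats(node_names=list(node_names),
                          pairs=np.column_stack(iu), mean_z=mean, t=t, p=p, q=q,
                          n_subjects=n_sub)


def fdr_threshold(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.nonzero(below)[0].max())
        mask[order[: k + 1]] = True
    return mask


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone), satisfying q >= p elementwise."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


@dataclass
class AdjacencyMatrix:
    """Binary symmetric adjacency with the edge sign kept alongside."""

    matrix: np.ndarray  # N x N of {0, 1}
    sign: np.ndarray    # N x N of {-1, 0, +1}: sign of the group t at kept edges
    node_names: list[str]

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


def binarize(stats_: GroupEdgeStats, q: float = 0.05,
             positive_only: bool = False) -> AdjacencyMatrix:
    """Adjacency with an edge wherever the FDR-corrected test rejects."""
    keep = stats_.q <= q
    if positive_only:
        keep = keep & (stats_.t > 0)
    n = stats_.n_nodes
    adj = np.zeros((n, n), dtype=np.int8)
    sign = np.zeros((n, n), dtype=np.int8)
    i, j = stats_.pairs[keep, 0], stats_.pairs[keep, 1]
    adj[i, j] = adj[j, i] = 1
    s = np.sign(stats_.t[keep]).astype(np.int8)
    sign[i, j] = sign[j, i] = s
    return AdjacencyMatrix(matrix=adj, sign=sign, node_names=list(stats_.node_names))


def subject_connectivity(images: list[FmriImage], atlas: RoiAtlas) -> list[np.ndarray]:
    """Convenience: per-subject Fisher-z matrices from images and an atlas."""
    return [connectivity_z(extract_roi_timeseries(img, atlas)) for img in images]
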