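"""FWHM-sweep orchestration: smoothing -> connectivity -> metrics -> decomposition.

For each kernel in the sweep and each state (rest, task) the cohort is
smoothed first, then the group connectivity network is built and its graph
metrics computed, and optionally PCA/ICA shape statistics are collected.
Outputs mirror the target tables: a kernel x metric table with an Average
row, per-kernel edge reports, and cross-kernel shape-stat p-value matrices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import decomposition as dec
from . import graph_metrics as gm
from . import smoothing
from .synthetic_data import SimulationConfig, TaskDesign, render_cohort
from .types import FmriImage, MetricsRecord, RoiAtlas

logger = logging.getLogger(__name__)

DEFAULT_FWHM_LIST = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
METRIC_COLUMNS = ("e_glob", "e_loc", "bc_mean", "cc", "l_avg")


@dataclass
class SweepConfig:
    fwhm_list: tuple[float, ...] = DEFAULT_FWHM_LIST
    states: tuple[str, ...] = ("rest", "task")
    q: float = 0.05
    positive_only: bool = False
    regress_task: bool = False
    run_decomposition: bool = True
    n_components: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        fw = tuple(float(f) for f in self.fwhm_list)
        if any(f < 0 for f in fw):
            raise ValueError("FWHM values must be non-negative")
        if len(set(fw)) != len(fw):
            raise ValueError("FWHM values must be unique")
        if tuple(sorted(fw)) != fw:
            raise ValueError("FWHM values must be sorted ascending")
        self.fwhm_list = fw
        for s in self.states:
            if s not in ("rest", "task"):
                raise ValueError(f"unknown state {s!r}")
        if not (0 < self.q < 1):
            raise ValueError("q must lie in (0, 1)")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StateResult:
    """Everything computed for one (fwhm, state) cell of the sweep."""

    fwhm: float
    state: str
    edge_stats: conn.GroupEdgeStats
    adjacency: conn.AdjacencyMatrix
    metrics: MetricsRecord
    pca_stats: dec.ComponentShapeStats | None = None
    ica_stats: dec.ComponentShapeStats | None = None


@dataclass
class SweepResult:
    config: SweepConfig
    cells: list[StateResult]
    node_names: list[str]

    def cell(self, fwhm: float, state: str) -> StateResult:
        for c in self.cells:
            if c.fwhm == fwhm and c.state == state:
                return c
        raise KeyError((fwhm, state))

    @property
    def states(self) -> tuple[str, ...]:
        return self.config.states


def _load_directory(path: Path) -> tuple[list[FmriImage], RoiAtlas]:
    subject_paths = sorted(set(path.glob("subject*.nii")) |
                           set(path.glob("subject*.nii.gz")))
    if not subject_paths:
        raise FileNotFoundError(f"no subject*.nii[.gz] images under {path}")
    atlas_path = path / "atlas.nii.gz"
    if not atlas_path.exists():
        atlas_path = path / "atlas.nii"
    if not atlas_path.exists():
        raise FileNotFoundError(f"no atlas.nii[.gz] under {path}")
    names = None
    names_path = path / "node_names.tsv"
    if names_path.exists():
        names = [ln for ln in names_path.read_text().splitlines() if ln]
    atlas = RoiAtlas.load(atlas_path, node_names=names)
    return [FmriImage.load(p) for p in subject_paths], atlas


def _synthetic_states(sim: SimulationConfig,
                      states: tuple[str, ...]) -> dict[str, tuple[list[FmriImage], RoiAtlas]]:
    out = {}
    for state in states:
        cfg = dataclasses.replace(
            sim,
            task=(sim.task or TaskDesign()) if state == "task" else None,
            # the encoding run is 288 s at TR 3 s
            n_volumes=96 if state == "task" else sim.n_volumes,
            seed=sim.seed + (1 if state == "task" else 0),
        )
        cohort = render_cohort(cfg)
        out[state] = ([img for img, _ in cohort], cohort[0][1].atlas)
    return out


def _regress_out(ts_matrix: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(regressor), regressor])
    beta, *_ = np.linalg.lstsq(x, ts_matrix.T, rcond=None)
    return ts_matrix - (x @ beta).T


def run_sweep(config: SweepConfig,
              data_source: SimulationConfig | str | Path) -> SweepResult:
    """Run every stage for every (fwhm, state) pair; smoothing always first."""
    if isinstance(data_source, SimulationConfig):
        per_state = _synthetic_states(data_source, config.states)
        task_regressor = None
        if "task" in config.states and config.regress_task:
            from .synthetic_data import make_task_regressor
            task_regressor = make_task_regressor(
                data_source.task or TaskDesign(), data_source.tr_s, 96)
    else:
        images, atlas = _load_directory(Path(data_source))
        per_state = {state: (images, atlas) for state in config.states}
        task_regressor = None

    cells: list[StateResult] = []
    node_names: list[str] = []
    for fwhm in config.fwhm_list:
        for state in config.states:
            t0 = time.time()
            images, atlas = per_state[state]
            node_names = list(atlas.node_names)
            smoothed = [smoothing.smooth_fmri(img, fwhm) for img in images]

            z_mats = []
            for img in smoothed:
                ts = conn.extract_roi_timeseries(img, atlas)
                m = ts.matrix
                if state == "task" and config.regress_task and task_regressor is not None:
                    m = _regress_out(m, task_regressor[: m.shape[1]])
                z_mats.append(conn.connectivity_z(m))
            stats_ = conn.group_edge_test(z_mats, node_names=node_names)
            adjacency = conn.binarize(stats_, q=config.q,
                                      positive_only=config.positive_only)
            metrics = gm.metrics_record(adjacency.matrix)

            pca_stats = ica_stats = None
            if config.run_decomposition:
                group = dec.stack_group_data(smoothed)
                n = min(config.n_components, *group.data.shape)
                pca_stats = dec.shape_stats(dec.pca_components(group, n=n))
                ica_stats = dec.shape_stats(
                    dec.ica_components(group, n=n, seed=config.seed))
            cells.append(StateResult(fwhm=fwhm, state=state, edge_stats=stats_,
                                     adjacency=adjacency, metrics=metrics,
                                     pca_stats=pca_stats, ica_stats=ica_stats))
            logger.info("sweep cell fwhm=%g state=%s edges=%d elapsed=%.1fs",
                        fwhm, state, adjacency.n_edges, time.time() - t0)
    return SweepResult(config=config, cells=cells, node_names=node_names)


def metrics_table(result: SweepResult) -> pd.DataFrame:
    """Kernel x (state, metric) table with a final Average row (column means)."""
    expected = {(f, s) for f in result.config.fwhm_list for s in result.config.states}
    have = {(c.fwhm, c.state) for c in result.cells}
    if expected - have:
        raise ValueError(f"incomplete sweep, missing cells: {sorted(expected - have)}")
    columns = pd.MultiIndex.from_product([result.config.states, METRIC_COLUMNS])
    rows = []
    index = []
    for fwhm in result.config.fwhm_list:
        row = []
        for state in result.config.states:
            rec = result.cell(fwhm, state).metrics.as_dict()
            row.extend(rec[m] for m in METRIC_COLUMNS)
        rows.append(row)
        index.append(f"{fwhm:g} mm")
    table = pd.DataFrame(rows, index=index, columns=columns)
    table.loc["Average"] = table.mean(axis=0)
    return table


def edge_report(result: SweepResult) -> pd.DataFrame:
    """Significant-edge counts and mean |t| per (fwhm, state)."""
    rows = []
    for c in result.cells:
        keep = c.edge_stats.q <= result.config.q
        t_kept = c.edge_stats.t[keep]
        rows.append({
            "fwhm": c.fwhm,
            "state": c.state,
            "n_edges": c.adjacency.n_edges,
            "n_positive": int((t_kept > 0).sum()),
            "n_negative": int((t_kept < 0).sum()),
            "mean_abs_t": float(np.abs(t_kept).mean()) if t_kept.size else 0.0,
            "mean_abs_z": float(np.abs(c.edge_stats.mean_z[keep]).mean())
            if keep.any() else 0.0,
        })
    return pd.DataFrame(rows)


def edge_list(cell: StateResult) -> pd.DataFrame:
    """Exportable list of significant edges with signed t values."""
    stats_ = cell.edge_stats
    keep = np.nonzero(stats_.q <= 0.05)[0]
    names = stats_.node_names
    return pd.DataFrame({
        "node_a": [names[stats_.pairs[k, 0]] for k in keep],
        "node_b": [names[stats_.pairs[k, 1]] for k in keep],
        "t": stats_.t[keep],
        "sign": np.sign(stats_.t[keep]).astype(int),
    })


def write_sweep(result: SweepResult, out_dir: str | Path) -> None:
    """Write TSV tables, per-cell edge lists/adjacency and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = metrics_table(result)
    flat = table.copy()
    flat.columns = [f"{s}_{m}" for s, m in table.columns]
    flat.round(5).to_csv(out / "metrics_table.tsv", sep="\t",
                         index_label="kernel", float_format="%.5f")
    edge_report(result).to_csv(out / "edge_report.tsv", sep="\t", index=False)
    for c in result.cells:
        tag = f"fwhm{c.fwhm:g}_{c.state}"
        np.savetxt(out / f"adjacency_{tag}.tsv", c.adjacency.matrix,
                   fmt="%d", delimiter="\t",
                   header="\t".join(result.node_names), comments="")
        edge_list(c).to_csv(out / f"edges_{tag}.tsv", sep="\t", index=False)
        if c.pca_stats is not None and c.ica_stats is not None:
            stats_rows = []
            for st in (c.pca_stats, c.ica_stats):
                row = {"method": st.method}
                row.update(st.summary())
                stats_rows.append(row)
            pd.DataFrame(stats_rows).to_csv(out / f"shape_stats_{tag}.tsv",
                                            sep="\t", index=False)
    if result.config.run_decomposition:
        _write_shape_pvalues(result, out)
    manifest = {
        "config": dataclasses.asdict(result.config),
        "config_hash": result.config.hash(),
        "n_nodes": len(result.node_names),
        "cells": [{"fwhm": c.fwhm, "state": c.state, "n_edges": c.adjacency.n_edges}
                  for c in result.cells],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _write_shape_pvalues(result: SweepResult, out: Path) -> None:
    for state in result.config.states:
        for method in ("pca", "ica"):
            for stat in ("kurtosis", "skewness"):
                values = {}
                for fwhm in result.config.fwhm_list:
                    st = getattr(result.cell(fwhm, state), f"{method}_stats")
                    if st is not None:
                        values[fwhm] = getattr(st, stat)
                if len(values) < 2:
                    continue
                pmat, levels = dec.compare_across_kernels(values)
                df = pd.DataFrame(pmat, index=[f"{lv:g}" for lv in levels],
                                  columns=[f"{lv:g}" for lv in levels])
                df.to_csv(out / f"pvalues_{method}_{stat}_{state}.tsv", sep="\t",
                          index_label="fwhm")
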