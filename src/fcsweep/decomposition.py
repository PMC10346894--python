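"""Group PCA / spatial ICA and component-shape statistics.

Subjects are standardized voxelwise and concatenated along time; PCA takes
the top singular directions of that matrix, spatial ICA unmixes it with
FastICA (log-cosh contrast, symmetric decorrelation). The distributional
shape of each spatial map — sample skewness and excess kurtosis — is
summarized per decomposition and compared across smoothing kernels with
pairwise Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .types import FmriImage

#: |excess kurtosis| below which every ICA source is considered Gaussian-like
#: and the decomposition is flagged as unidentifiable.
GAUSSIAN_KURTOSIS_TOL = 0.1


@dataclass
class GroupDataMatrix:
    """Concatenated (subjects x time) x voxels matrix with its voxel map."""

    data: np.ndarray          # (sum T) x V
    voxel_index: np.ndarray   # V indices into the flattened grid
    grid_shape: tuple[int, int, int]
    subject_rows: list[int]   # rows contributed per subject

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class ComponentSet:
    """Spatial maps (component x voxel) with matched time courses."""

    maps: np.ndarray          # n_components x V
    timecourses: np.ndarray   # (sum T) x n_components
    method: str               # "pca" | "ica"
    explained_variance_ratio: np.ndarray | None = None
    converged: bool = True
    gaussian_flag: bool = False

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


def stack_group_data(images: list[FmriImage] | list[np.ndarray],
                     mask: np.ndarray | None = None) -> GroupDataMatrix:
    """Standardize each subject voxelwise and concatenate along time.

    Voxels with zero variance in any subject (or excluded by ``mask``) are
    dropped; the surviving flat indices are recorded for mapping back.
    """
    if not images:
        raise ValueError("need at least one subject")
    arrays = []
    grid_shape = None
    for img in images:
        data = img.data if isinstance(img, FmriImage) else np.asarray(img)
        if data.ndim != 4:
            raise ValueError("each subject must be a 4D array")
        if grid_shape is None:
            grid_shape = data.shape[:3]
        elif data.shape[:3] != grid_shape:
            raise ValueError(
                f"inconsistent grids: {data.shape[:3]} vs {grid_shape}"
            )
        arrays.append(data.reshape(-1, data.shape[3]).T)  # T x V_all

    keep = np.ones(arrays[0].shape[1], dtype=bool)
    if mask is not None:
        keep &= np.asarray(mask).reshape(-1).astype(bool)
    sds = [a.std(axis=0) for a in arrays]
    for sd in sds:
        keep &= sd > 0
    voxel_index = np.nonzero(keep)[0]
    if voxel_index.size == 0:
        raise ValueError("no usable voxels after masking")
    blocks = []
    for a, sd in zip(arrays, sds):
        block = a[:, keep]
        block = (block - block.mean(axis=0)) / sd[keep]
        blocks.append(block)
    return GroupDataMatrix(
        data=np.concatenate(blocks, axis=0),
        voxel_index=voxel_index,
        grid_shape=grid_shape,
        subject_rows=[a.shape[0] for a in arrays],
    )


def _fix_signs(maps: np.ndarray, timecourses: np.ndarray) -> None:
    """Deterministic sign convention: largest-|value| map entry is positive."""
    for i in range(maps.shape[0]):
        j = int(np.argmax(np.abs(maps[i])))
        if maps[i, j] < 0:
            maps[i] *= -1.0
            timecourses[:, i] *= -1.0


def pca_components(X: np.ndarray | GroupDataMatrix, n: int = 40) -> ComponentSet:
    """Top-``n`` singular directions; spatial maps are orthonormal rows.

    Uses the Gram-matrix route when rows < columns (the usual fMRI shape),
    which is exact and deterministic.
    """
    data = X.data if isinstance(X, GroupDataMatrix) else np.asarray(X, dtype=float)
    rows, cols = data.shape
    if not (1 <= n <= min(rows, cols)):
        raise ValueError(f"n={n} exceeds min(rows, cols)={min(rows, cols)}")
    total_var = float((data**2).sum())
    if rows <= cols:
        gram = data @ data.T
        vals, vecs = np.linalg.eigh(gram)
        idx = np.argsort(vals)[::-1][:n]
        vals, vecs = np.clip(vals[idx], 0, None), vecs[:, idx]
        svals = np.sqrt(vals)
        safe = np.where(svals > 0, svals, 1.0)
        maps = (vecs.T @ data) / safe[:, None]       # n x V, orthonormal rows
        timecourses = vecs * svals[None, :]          # rows x n
    else:
        u, svals, vt = np.linalg.svd(data, full_matrices=False)
        u, svals, vt = u[:, :n], svals[:n], vt[:n]
        maps = vt
        timecourses = u * svals[None, :]
        vals = svals**2
    evr = vals / total_var if total_var > 0 else np.zeros(n)
    maps = np.ascontiguousarray(maps)
    _fix_signs(maps, timecourses)
    return ComponentSet(maps=maps, timecourses=timecourses, method="pca",
                        explained_variance_ratio=evr)


def ica_components(X: np.ndarray | GroupDataMatrix, n: int = 40,
                   seed: int = 0, max_iter: int = 500,
                   tol: float = 1e-4) -> ComponentSet:
    """Spatial ICA: whiten to ``n`` dimensions, then FastICA (log-cosh).

    The data matrix is time x voxels; voxels act as samples so the estimated
    sources are the spatial maps. Non-convergence is flagged, not raised.
    When every source looks Gaussian (tiny excess kurtosis) the result is
    flagged as unidentifiable.
    """
    data = X.data if isinstance(X, GroupDataMatrix) else np.asarray(X, dtype=float)
    rows, cols = data.shape
    if not (1 <= n <= min(rows, cols)):
        raise ValueError(f"n={n} exceeds min(rows, cols)={min(rows, cols)}")
    ica = FastICA(n_components=n, algorithm="parallel", fun="logcosh",
                  whiten="unit-variance", max_iter=max_iter, tol=tol,
                  random_state=seed)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            # voxels as samples -> sources are spatial maps
            maps = ica.fit_transform(data.T).T       # n x V
        except ConvergenceWarning:
            warnings.simplefilter("ignore", ConvergenceWarning)
            maps = ica.fit_transform(data.T).T
            converged = False
    timecourses = ica.mixing_                        # rows x n
    maps = np.ascontiguousarray(maps)
    _fix_signs(maps, timecourses)
    kurt = np.array([stats.kurtosis(m, fisher=True, bias=True) for m in maps])
    gaussian = bool(np.all(np.abs(kurt) < GAUSSIAN_KURTOSIS_TOL))
    return ComponentSet(maps=maps, timecourses=timecourses, method="ica",
                        converged=converged, gaussian_flag=gaussian)


@dataclass
class ComponentShapeStats:
    """Per-component spatial-map skewness and kurtosis plus their summaries."""

    method: str
    kurtosis: np.ndarray
    skewness: np.ndarray
    excess: bool = True

    def summary(self) -> dict[str, float]:
        out = {}
        for name, vals in (("kurtosis", self.kurtosis), ("skewness", self.skewness)):
            out[f"{name}_min"] = float(vals.min())
            out[f"{name}_mean"] = float(vals.mean())
            out[f"{name}_max"] = float(vals.max())
            out[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return out


def shape_stats(component_set: ComponentSet, excess: bool = True) -> ComponentShapeStats:
    """Population-moment skewness m3/m2^1.5 and kurtosis m4/m2^2 (- 3 if excess)."""
    maps = component_set.maps
    if maps.size == 0:
        raise ValueError("component set has no maps")
    centered = maps - maps.mean(axis=1, keepdims=True)
    m2 = (centered**2).mean(axis=1)
    if np.any(m2 == 0):
        bad = np.nonzero(m2 == 0)[0].tolist()
        raise ValueError(f"zero-variance spatial maps: components {bad}")
    m3 = (centered**3).mean(axis=1)
    m4 = (centered**4).mean(axis=1)
    skew = m3 / m2**1.5
    kurt = m4 / m2**2 - (3.0 if excess else 0.0)
    return ComponentShapeStats(method=component_set.method,
                               kurtosis=kurt, skewness=skew, excess=excess)


def compare_across_kernels(values_by_fwhm: dict[float, np.ndarray]) -> tuple[np.ndarray, list[float]]:
    """Pairwise two-sided Welch t-tests on per-component values across kernels.

    Returns a symmetric p-value matrix with unit diagonal, and the sorted
    kernel levels indexing it.
    """
    levels = sorted(values_by_fwhm)
    if len(levels) < 2:
        raise ValueError("need at least 2 kernel levels to compare")
    sets = []
    for lv in levels:
        v = np.asarray(values_by_fwhm[lv], dtype=float)
        if v.size < 2:
            raise ValueError(f"kernel level {lv} has fewer than 2 component values")
        sets.append(v)
    k = len(levels)
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.array_equal(sets[i], sets[j]):
                p = 1.0
            else:
                p = float(stats.ttest_ind(sets[i], sets[j], equal_var=False).pvalue)
                if np.isnan(p):  # both samples constant with equal means
                    p = 1.0
            pmat[i, j] = pmat[j, i] = p
    return pmat, [float(lv) for lv in levels]
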