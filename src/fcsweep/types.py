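"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class FmriImage:
    """A 4D BOLD series with voxel geometry and repetition time.

    ``data`` has shape (nx, ny, nz, T). ``voxel_size_mm`` is the edge
    length per spatial axis (isotropic scans store the same value three
    times). ``tr_s`` is the sampling interval between volumes in seconds.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"invalid voxel size {self.voxel_size_mm!r}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def affine(self) -> np.ndarray:
        """RAS+ affine with the voxel size on the diagonal."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine())
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "FmriImage":
        zooms = img.header.get_zooms()
        if len(zooms) < 4:
            raise ValueError("image lacks a time axis / TR metadata")
        return cls(
            data=np.asarray(img.get_fdata(), dtype=np.float64),
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
            tr_s=float(zooms[3]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FmriImage":
        return cls.from_nifti(nib.load(str(path)))


@dataclass
class RoiAtlas:
    """Integer label volume (0 = background, 1..N = nodes) with node names."""

    labels: np.ndarray
    node_names: list[str]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        self.voxel_size_mm = vs

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def save(self, path: str | Path) -> None:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(path))

    @classmethod
    def load(cls, path: str | Path, node_names: list[str] | None = None) -> "RoiAtlas":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int64)
        n = int(labels.max())
        if node_names is None:
            node_names = [f"node{i:02d}" for i in range(1, n + 1)]
        zooms = img.header.get_zooms()[:3]
        return cls(labels=labels, node_names=list(node_names),
                   voxel_size_mm=tuple(float(z) for z in zooms))


@dataclass
class RoiTimeseries:
    """Per-subject node signal matrix, one standardized row per node."""

    matrix: np.ndarray  # N x T
    node_names: list[str]
    tr_s: float = 3.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("timeseries matrix must be 2D (nodes x time)")
        if self.matrix.shape[0] != len(self.node_names):
            raise ValueError("row count does not match node names")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MetricsRecord:
    """The five scalar graph metrics for one binary network."""

    e_glob: float
    e_loc: float
    bc_mean: float
    cc: float
    l_avg: float
    connected: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "e_glob": self.e_glob,
            "e_loc": self.e_loc,
            "bc_mean": self.bc_mean,
            "cc": self.cc,
            "l_avg": self.l_avg,
        }
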