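"""Shared spatial containers for the gel-dosimetry pipeline.

All volumes live on axis-aligned regular grids in physical millimetre
coordinates.  Axis convention: index axis 0 = x (left-right, the beam
axis of the tangential fields), axis 1 = y (the MRI slice axis), axis
2 = z (vertical, phantom base at z = 0).  World coordinate of voxel
(i, j, k) is ``origin_mm + (i, j, k) * spacing_mm`` (voxel centres).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "LabelVolume",
    "EchoSeriesVolume",
    "R2Map",
    "DoseVolume",
    "OUTSIDE",
    "WALL",
    "GEL",
    "WATER",
    "METAL",
    "LABEL_NAMES",
]

# Label codes for phantom voxel classes.  Every voxel carries exactly one.
OUTSIDE, WALL, GEL, WATER, METAL = 0, 1, 2, 3, 4
LABEL_NAMES = {OUTSIDE: "outside", WALL: "wall", GEL: "gel", WATER: "water", METAL: "metal"}


@dataclass(frozen=True)
class Grid:
    """Regular 3D sampling grid (voxel counts, mm spacing, mm origin)."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be three positive counts, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = self.axes_mm()
        return tuple(np.meshgrid(*ax, indexing="ij", sparse=True))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points, shape (n, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def contains_point(self, point_mm) -> bool:
        i = self.world_to_index(point_mm)[0]
        return bool(np.all(i >= 0) and np.all(i <= np.asarray(self.shape) - 1))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def same_as(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


def _check_grid(data: np.ndarray, grid: Grid, ndim: int = 3) -> None:
    if data.shape[:3] != grid.shape:
        raise ValueError(f"data shape {data.shape[:3]} does not match grid {grid.shape}")
    if data.ndim != ndim:
        raise ValueError(f"expected {ndim}-dimensional data, got {data.ndim}")


@dataclass
class LabelVolume:
    """Integer phantom-material labels on a grid."""

    labels: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        _check_grid(self.labels, self.grid)

    def mask(self, *label_codes: int) -> np.ndarray:
        return np.isin(self.labels, label_codes)

    def volume_L(self, label_code: int) -> float:
        return float(np.count_nonzero(self.labels == label_code)) * self.grid.voxel_volume_mm3 / 1e6


@dataclass
class EchoSeriesVolume:
    """4D magnitude multi-echo MR data, shape (x, y, z, echo)."""

    data: np.ndarray
    echo_times_ms: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        _check_grid(self.data, self.grid, ndim=4)
        if self.data.shape[3] != self.echo_times_ms.size:
            raise ValueError("number of echoes does not match echo_times_ms")
        if self.echo_times_ms.size < 3:
            raise ValueError("at least 3 echoes are required for relaxometry")
        if np.any(np.diff(self.echo_times_ms) <= 0) or self.echo_times_ms[0] <= 0:
            raise ValueError("echo times must be positive and strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times_ms.size)


@dataclass
class R2Map:
    """Per-voxel transverse relaxation rate (s^-1) with fit uncertainty."""

    r2: np.ndarray
    r2_sigma: np.ndarray
    mask: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        self.r2_sigma = np.asarray(self.r2_sigma, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        for arr in (self.r2, self.r2_sigma, self.mask):
            _check_grid(arr, self.grid)
        if np.any(~np.isfinite(self.r2[self.mask])):
            raise ValueError("r2 must be finite inside the validity mask")
        if np.any(self.r2_sigma[self.mask] < 0):
            raise ValueError("r2_sigma must be non-negative")


@dataclass
class DoseVolume:
    """Scalar 3D dose grid, absolute (Gy) or relative (% of normalization)."""

    dose: np.ndarray
    grid: Grid
    kind: str = "planned"  # "planned" | "measured"
    mask: np.ndarray | None = None
    relative: bool = False
    normalization_value: float | None = None

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        _check_grid(self.dose, self.grid)
        if self.kind not in ("planned", "measured"):
            raise ValueError(f"kind must be 'planned' or 'measured', got {self.kind!r}")
        if self.mask is None:
            self.mask = np.isfinite(self.dose)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_grid(self.mask, self.grid)
        if self.relative and self.normalization_value is None:
            raise ValueError("relative dose volumes must record their normalization_value")

    def copy_with(self, **kw) -> "DoseVolume":
        params = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        params.update(kw)
        return DoseVolume(**params)


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_nifti(path, data: np.ndarray, grid: Grid) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    data = np.asanyarray(img.dataobj)
    grid = Grid(tuple(int(n) for n in data.shape[:3]), spacing, origin)
    return data, grid
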