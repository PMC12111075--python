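"""From corrected R2 maps to registered, normalized dose distributions.

Applies the calibration to turn R2 into absolute dose, registers the
measured frame onto the planned frame via fiducial points (closed-form
orthogonal Procrustes), resamples to the comparison grid, and builds
the relative (%) distributions consumed by the gamma analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CalibrationCurve
from .core import DoseVolume, Grid, R2Map

log = logging.getLogger(__name__)

__all__ = [
    "FiducialSet",
    "RigidTransform",
    "r2_to_dose",
    "rigid_from_fiducials",
    "resample_to",
    "normalize_relative",
    "read_rtdose",
]


@dataclass
class FiducialSet:
    """Labelled marker points (mm) in one spatial frame."""

    points_mm: pd.DataFrame  # columns: label, x, y, z
    frame: str  # "measured" | "planned"

    def __post_init__(self):
        if self.frame not in ("measured", "planned"):
            raise ValueError(f"frame must be 'measured' or 'planned', got {self.frame!r}")
        req = {"label", "x", "y", "z"}
        if not req.issubset(self.points_mm.columns):
            raise ValueError(f"fiducial table needs columns {sorted(req)}")
        if len(self.points_mm) < 3:
            raise ValueError("at least 3 fiducial points are required")
        if _collinear(self.coords()):
            raise ValueError("fiducial points are (near-)collinear")

    def coords(self) -> np.ndarray:
        return self.points_mm[["x", "y", "z"]].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, labels, points_mm, frame) -> "FiducialSet":
        pts = np.asarray(points_mm, dtype=float)
        df = pd.DataFrame({"label": list(labels), "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]})
        return cls(df, frame)

    @classmethod
    def from_csv(cls, path, frame=None) -> "FiducialSet":
        df = pd.read_csv(path)
        frm = frame if frame is not None else df["frame"].iloc[0]
        return cls(df[["label", "x", "y", "z"]], frm)


def _collinear(pts: np.ndarray, cond_limit: float = 1e6) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] < s[0] / cond_limit + 1e-12)


@dataclass
class RigidTransform:
    """Proper rigid map x -> R @ x + t (moving frame to fixed frame)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    fre_mm: float = 0.0  # fiducial registration error (RMS)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (determinant +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.fre_mm)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rotation": self.rotation.tolist(),
                    "translation_mm": self.translation.tolist(),
                    "fre_mm": self.fre_mm,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation_mm"]), d["fre_mm"])


def r2_to_dose(r2: R2Map, curve: CalibrationCurve) -> DoseVolume:
    """Apply the inverse calibration D = (R2 - intercept) / slope.

    Negative doses (R2 below the zero-dose intercept, e.g. from noise)
    are clipped to zero; the number of clipped voxels is logged.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    dose = np.zeros(r2.grid.shape)
    dose[r2.mask] = curve.dose_of_r2(r2.r2[r2.mask])
    n_neg = int(np.count_nonzero(dose[r2.mask] < 0))
    if n_neg:
        log.info("clipping %d voxels with R2 below the calibration intercept", n_neg)
    np.clip(dose, 0.0, None, out=dose)
    return DoseVolume(dose, r2.grid, kind="measured", mask=r2.mask.copy())


def rigid_from_fiducials(moving: FiducialSet, fixed: FiducialSet) -> RigidTransform:
    """Closed-form least-squares rigid registration (orthogonal Procrustes).

    Matches points by label, solves the Kabsch problem with a proper
    rotation enforced, and reports the RMS fiducial registration error.
    """
    m = moving.points_mm.set_index("label")
    f = fixed.points_mm.set_index("label")
    common = m.index.intersection(f.index)
    if len(common) < 3:
        raise ValueError("need at least 3 fiducial pairs with matching labels")
    P = m.loc[common, ["x", "y", "z"]].to_numpy(dtype=float)
    Q = f.loc[common, ["x", "y", "z"]].to_numpy(dtype=float)
    if _collinear(P) or _collinear(Q):
        raise ValueError("fiducial pairs are (near-)collinear; rotation not identifiable")

    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    fre = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return RigidTransform(R, t, fre)


def _resample_array(
    data: np.ndarray,
    mask: np.ndarray,
    src_grid: Grid,
    transform: RigidTransform,
    target: Grid,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear pull-back of (data, mask) onto the target grid.

    Target voxels are mapped through the inverse transform into the
    source frame; points falling outside the source grid or touching
    invalid source voxels become invalid (not zero-filled).
    """
    tx, ty, tz = np.meshgrid(*target.axes_mm(), indexing="ij")
    pts = np.stack([tx.ravel(), ty.ravel(), tz.ravel()], axis=1)
    src_pts = transform.inverse().apply(pts)
    idx = src_grid.world_to_index(src_pts).T

    vals = ndimage.map_coordinates(data, idx, order=1, mode="constant", cval=np.nan)
    cover = ndimage.map_coordinates(
        mask.astype(float), idx, order=1, mode="constant", cval=0.0
    )
    out_mask = (cover > 1.0 - 1e-6) & np.isfinite(vals)
    vals = np.where(out_mask, vals, 0.0)
    return vals.reshape(target.shape), out_mask.reshape(target.shape)


def resample_to(volume, transform: RigidTransform, target_grid: Grid):
    """Resample a DoseVolume or R2Map onto a target grid through a rigid map."""
    if isinstance(volume, DoseVolume):
        vals, mask = _resample_array(
            volume.dose, volume.mask, volume.grid, transform, target_grid
        )
        return DoseVolume(
            vals,
            target_grid,
            kind=volume.kind,
            mask=mask,
            relative=volume.relative,
            normalization_value=volume.normalization_value,
        )
    if isinstance(volume, R2Map):
        vals, mask = _resample_array(volume.r2, volume.mask, volume.grid, transform, target_grid)
        sig, _ = _resample_array(volume.r2_sigma, volume.mask, volume.grid, transform, target_grid)
        return R2Map(vals, sig, mask, target_grid)
    raise TypeError(f"cannot resample object of type {type(volume).__name__}")


def _robust_max(
    vol: DoseVolume,
    percentile: float,
    norm_mask: np.ndarray | None,
    smoothing_mm: float = 0.0,
) -> float:
    mask = vol.mask if norm_mask is None else (vol.mask & norm_mask)
    if not mask.any():
        raise ValueError("empty mask: cannot normalize")
    data = vol.dose
    if smoothing_mm > 0:
        # Masked (normalized-convolution) blur so voxel noise does not
        # inflate the upper percentile of noisy volumes relative to
        # noiseless ones.
        sigma = [smoothing_mm / s for s in vol.grid.spacing_mm]
        m = mask.astype(float)
        num = ndimage.gaussian_filter(data * m, sigma=sigma)
        den = ndimage.gaussian_filter(m, sigma=sigma)
        data = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    return float(np.percentile(data[mask], percentile))


def normalize_relative(
    measured: DoseVolume,
    planned: DoseVolume,
    percentile: float = 99.5,
    norm_mask: np.ndarray | None = None,
    norm_smoothing_mm: float = 3.0,
) -> tuple[DoseVolume, DoseVolume]:
    """Express both distributions in % of their own (robust) maximum.

    Each volume is divided by the stated percentile of its valid voxels
    (99.5 by default, a noise-robust stand-in for the single hottest
    voxel; 100 with no smoothing reproduces literal max normalization).
    The normalization value is read from a lightly smoothed copy
    (``norm_smoothing_mm``) so that voxel noise does not bias the
    percentile of the measured volume relative to the noiseless plan;
    ``norm_mask`` optionally restricts the voxels considered - e.g. gel
    away from walls - without masking the output.
    """
    if not measured.grid.same_as(planned.grid):
        raise ValueError("measured and planned volumes must share a grid")
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must lie in (0, 100]")
    out = []
    for vol in (measured, planned):
        if vol.relative:
            out.append(vol)
            continue
        norm = _robust_max(vol, percentile, norm_mask, norm_smoothing_mm)
        if norm <= 0:
            raise ValueError(f"non-positive normalization value for {vol.kind} volume")
        out.append(
            vol.copy_with(
                dose=100.0 * vol.dose / norm, relative=True, normalization_value=norm
            )
        )
    return out[0], out[1]


def read_rtdose(path) -> DoseVolume:
    """Read a DICOM RT-Dose file into a planned DoseVolume (optional).

    Supports axis-aligned grids with a regular GridFrameOffsetVector;
    requires pydicom.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    # pydicom pixel_array axis order is (frame, row, col) = (z, y, x).
    dose = ds.pixel_array.astype(float) * scaling
    dose = np.transpose(dose, (2, 1, 0))
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
    if offsets.size > 2 and not np.allclose(np.diff(offsets), dz):
        raise ValueError("irregular RT-Dose frame spacing is not supported")
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = Grid(dose.shape, (dx, dy, dz), origin)
    return DoseVolume(dose, grid, kind="planned")
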