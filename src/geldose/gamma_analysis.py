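"""3D global gamma-index comparison of measured vs planned dose.

The gamma index combines dose difference (as % of a global normalization
dose) and distance-to-agreement: for each reference voxel r,

    gamma(r) = min_c sqrt( |c - r|^2 / dta^2 + (D_e(c) - D_r(r))^2 / dd^2 )

over candidate points c of the evaluated distribution within a search
radius, with the evaluated dose trilinearly interpolated on a subvoxel
lattice.  The search enumerates candidate offsets sorted by radius and
terminates per voxel once the distance term alone exceeds the best
gamma so far, which is exact for this discretization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DoseVolume, Grid, save_nifti

log = logging.getLogger(__name__)

__all__ = ["GammaCriteria", "GammaResult", "gamma_3d", "slice_pass_rates", "export_fail_map"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class GammaCriteria:
    """Gamma acceptance criteria (global normalization convention)."""

    dose_diff_pct: float = 3.0
    dta_mm: float = 3.0
    threshold_pct: float = 10.0
    normalization: str | float = "global_max"  # "global_max" or an explicit dose value
    search_radius_mm: float | None = None  # default 3 x dta
    interp_factor: int = 10  # subsamples per voxel pitch
    norm_percentile: float = 99.5

    def __post_init__(self):
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose_diff_pct and dta_mm must be positive")
        if not 0 < self.threshold_pct < 100:
            raise ValueError("threshold_pct must lie in (0, 100)")
        if self.interp_factor < 1:
            raise ValueError("interp_factor must be >= 1")
        if self.search_radius_mm is None:
            self.search_radius_mm = 3.0 * self.dta_mm
        if self.search_radius_mm <= 0:
            raise ValueError("search_radius_mm must be positive")
        if isinstance(self.normalization, str) and self.normalization != "global_max":
            raise ValueError("normalization must be 'global_max' or a dose value")


@dataclass
class GammaResult:
    """Gamma volume with masks and pass-rate statistics."""

    gamma: np.ndarray
    evaluated_mask: np.ndarray
    pass_mask: np.ndarray
    grid: Grid
    normalization_value: float
    criteria: GammaCriteria

    def __post_init__(self):
        if np.any(self.pass_mask & ~self.evaluated_mask):
            raise ValueError("pass mask must be a subset of the evaluated mask")

    @property
    def pass_rate_overall(self) -> float:
        n_eval = int(self.evaluated_mask.sum())
        if n_eval == 0:
            return float("nan")
        return 100.0 * float(self.pass_mask.sum()) / n_eval

    def pass_rate_in(self, submask: np.ndarray) -> float:
        m = self.evaluated_mask & submask
        if not m.any():
            return float("nan")
        return 100.0 * float((self.pass_mask & submask).sum()) / float(m.sum())


def candidate_offsets_mm(
    spacing_mm, interp_factor: int, radius_mm: float
) -> np.ndarray:
    """Subvoxel candidate offsets within the search sphere, sorted by radius."""
    steps = [s / interp_factor for s in spacing_mm]
    ranges = [np.arange(-int(np.floor(radius_mm / st)), int(np.floor(radius_mm / st)) + 1) * st
              for st in steps]
    ox, oy, oz = np.meshgrid(*ranges, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    r = np.linalg.norm(offs, axis=1)
    keep = r <= radius_mm + 1e-12
    offs, r = offs[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return offs[order]


def gamma_3d(
    reference: DoseVolume,
    evaluated: DoseVolume,
    criteria: GammaCriteria = None,
    chunk_budget: int = 4_000_000,
) -> GammaResult:
    """Compute the 3D global gamma of ``evaluated`` against ``reference``.

    Reference-grid voxels whose reference dose is below the low-dose
    threshold, or invalid in either volume's mask within interpolation
    reach, are excluded from all statistics.  Where the search truncates
    at the search radius the reported gamma is capped at
    ``search_radius / dta``.
    """
    if criteria is None:
        criteria = GammaCriteria()
    if not reference.grid.same_as(evaluated.grid):
        raise ValueError("reference and evaluated volumes must share the same grid")
    if reference.relative != evaluated.relative:
        raise ValueError("compare two relative or two absolute volumes, not a mixture")

    grid = reference.grid
    if criteria.normalization == "global_max":
        ref_valid = reference.dose[reference.mask]
        if ref_valid.size == 0:
            raise ValueError("reference volume has an empty mask")
        d_norm = float(np.percentile(ref_valid, criteria.norm_percentile))
    else:
        d_norm = float(criteria.normalization)
    if d_norm <= 0:
        raise ValueError("normalization dose must be positive")

    dd_abs = criteria.dose_diff_pct / 100.0 * d_norm
    dta = criteria.dta_mm
    cap = criteria.search_radius_mm / dta

    thr = criteria.threshold_pct / 100.0 * d_norm
    eval_mask = reference.mask & (reference.dose >= thr)
    if not eval_mask.any():
        raise ValueError("no voxels above the low-dose threshold to evaluate")

    ev = np.where(evaluated.mask, evaluated.dose, np.nan)
    ref_vals = reference.dose[eval_mask]
    vox_idx = np.argwhere(eval_mask).astype(float)  # index units
    spacing = np.asarray(grid.spacing_mm)

    # Offset 0 first: pure dose difference.
    d0 = ev[eval_mask]
    best = ((d0 - ref_vals) / dd_abs) ** 2
    best[~np.isfinite(best)] = np.inf

    offsets = candidate_offsets_mm(grid.spacing_mm, criteria.interp_factor,
                                   criteria.search_radius_mm)
    radii = np.linalg.norm(offsets, axis=1)
    nz = radii > 0
    offsets, radii = offsets[nz], radii[nz]

    order_idx = np.arange(len(best))
    pos = 0
    while pos < len(offsets):
        active = best > (radii[pos] / dta) ** 2
        if not active.any():
            break
        act_idx = order_idx[active]
        n_active = act_idx.size
        n_chunk = min(max(1, chunk_budget // max(n_active, 1)), len(offsets) - pos)
        off_chunk = offsets[pos : pos + n_chunk]
        r_chunk = radii[pos : pos + n_chunk]

        coords = (
            vox_idx[act_idx][None, :, :] + (off_chunk / spacing)[:, None, :]
        ).reshape(-1, 3).T
        vals = ndimage.map_coordinates(ev, coords, order=1, mode="constant", cval=np.nan)
        vals = vals.reshape(n_chunk, n_active)
        gsq = (r_chunk[:, None] / dta) ** 2 + ((vals - ref_vals[act_idx]) / dd_abs) ** 2
        gsq[~np.isfinite(gsq)] = np.inf
        best[act_idx] = np.minimum(best[act_idx], gsq.min(axis=0))
        pos += n_chunk

    gamma_flat = np.sqrt(best)
    truncated = ~np.isfinite(gamma_flat) | (gamma_flat > cap)
    gamma_flat[truncated] = cap

    gamma = np.zeros(grid.shape)
    gamma[eval_mask] = gamma_flat
    pass_mask = eval_mask.copy()
    # Boundary passes; the epsilon keeps exact gamma = 1 cases (e.g. a pure
    # 3% offset at the 3% criterion) from failing through roundoff.
    pass_mask[eval_mask] = gamma_flat <= 1.0 + 1e-9
    return GammaResult(gamma, eval_mask, pass_mask, grid, d_norm, criteria)


def slice_pass_rates(result: GammaResult, axis: str = "y") -> pd.DataFrame:
    """Per-slice pass rates along an axis.

    Slices with no evaluated voxels are reported with NaN (missing),
    never 0.  The evaluated-voxel-weighted mean of the slice rates
    equals the overall pass rate.
    """
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    other = tuple(a for a in range(3) if a != ax)
    n_eval = result.evaluated_mask.sum(axis=other)
    n_pass = result.pass_mask.sum(axis=other)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_eval > 0, 100.0 * n_pass / np.maximum(n_eval, 1), np.nan)
    return pd.DataFrame(
        {
            "slice_index": np.arange(result.grid.shape[ax]),
            "evaluated_voxels": n_eval.astype(int),
            "pass_rate_pct": rate,
        }
    )


def export_fail_map(
    result: GammaResult,
    labels=None,
    shadow_mask: np.ndarray | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Summarize connected gamma-fail regions; optionally write volumes.

    Returns one row per 26-connected component of failing voxels with
    its size, centroid (mm) and, when a shadow mask is supplied, the
    fraction of the component inside the port's beam shadow.  With
    ``out_dir`` the gamma volume and pass/fail masks are written as
    NIfTI files.
    """
    fail = result.evaluated_mask & ~result.pass_mask
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n_comp = ndimage.label(fail, structure=structure)
    rows = []
    vv = result.grid.voxel_volume_mm3
    origin = np.asarray(result.grid.origin_mm)
    spacing = np.asarray(result.grid.spacing_mm)
    for cid in range(1, n_comp + 1):
        m = comp == cid
        n = int(m.sum())
        centroid_idx = np.asarray(ndimage.center_of_mass(m))
        centroid = origin + centroid_idx * spacing
        row = {
            "component": cid,
            "n_voxels": n,
            "size_mm3": n * vv,
            "centroid_x_mm": centroid[0],
            "centroid_y_mm": centroid[1],
            "centroid_z_mm": centroid[2],
        }
        if shadow_mask is not None:
            row["shadow_overlap_frac"] = float((m & shadow_mask).sum()) / n
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("n_voxels", ascending=False).reset_index(drop=True) \
        if rows else pd.DataFrame(
            columns=["component", "n_voxels", "size_mm3",
                     "centroid_x_mm", "centroid_y_mm", "centroid_z_mm"]
        )

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_nifti(out / "gamma.nii.gz", result.gamma, result.grid)
        save_nifti(out / "gamma_pass.nii.gz", result.pass_mask.astype(np.uint8), result.grid)
        save_nifti(out / "gamma_fail.nii.gz", fail.astype(np.uint8), result.grid)
        df.to_csv(out / "gamma_fail_components.csv", index=False)
    return df
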