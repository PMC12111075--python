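"""Linear R2-dose calibration from vial echo data.

Produces the calibration curve with its quality diagnostics: Pearson
correlation of the vial means, the mean relative dose uncertainty of
the batch, and the dose resolution (minimum resolvable dose separation
at a stated confidence).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, special, stats

from .core import EchoSeriesVolume, Grid
from .phantom_sim import VialEchoSet
from .r2_mapping import fit_r2

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "vial_roi_stats",
    "fit_calibration",
    "mean_uncertainty",
    "dose_resolution",
]


@dataclass
class CalibrationCurve:
    """Linear R2(D) = intercept + slope * D model with fit diagnostics."""

    slope: float  # s^-1 / Gy
    intercept: float  # s^-1
    slope_se: float
    intercept_se: float
    pearson_r: float
    residual_sigma_R2: float
    dose_range_Gy: tuple[float, float]
    per_vial: pd.DataFrame  # columns: dose_Gy, R2_mean, R2_sd, n_voxels

    def __post_init__(self):
        if self.dose_range_Gy[0] >= self.dose_range_Gy[1]:
            raise ValueError("dose range must have min < max")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("Pearson r must lie in [-1, 1]")

    def dose_of_r2(self, r2):
        return (np.asarray(r2, dtype=float) - self.intercept) / self.slope

    def to_json(self, path) -> None:
        payload = {
            "slope_s1_per_Gy": self.slope,
            "intercept_s1": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "pearson_r": self.pearson_r,
            "residual_sigma_R2": self.residual_sigma_R2,
            "dose_range_Gy": list(self.dose_range_Gy),
            "per_vial": self.per_vial.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            slope=d["slope_s1_per_Gy"],
            intercept=d["intercept_s1"],
            slope_se=d["slope_se"],
            intercept_se=d["intercept_se"],
            pearson_r=d["pearson_r"],
            residual_sigma_R2=d["residual_sigma_R2"],
            dose_range_Gy=tuple(d["dose_range_Gy"]),
            per_vial=pd.DataFrame(d["per_vial"]),
        )


def vial_roi_stats(
    vials: VialEchoSet,
    erosion_mm: float = 2.0,
    noise_sigma: float | None = None,
    rician_floor_correction: bool = False,
) -> pd.DataFrame:
    """Per-vial R2 statistics from eroded-ROI voxelwise fits.

    The ROI is eroded inward from the vial edge by ``erosion_mm`` to
    exclude susceptibility artifacts at the glass; each remaining voxel
    is fitted individually and the vial is summarized by the mean and
    standard deviation of the fitted R2 values.
    """
    rows = []
    for vid in range(vials.n_vials):
        mask = vials.masks[vid]
        if erosion_mm > 0:
            dist = ndimage.distance_transform_edt(mask, sampling=vials.spacing_mm)
            roi = dist > erosion_mm
        else:
            roi = mask
        if roi.sum() < 2:
            raise ValueError(
                f"vial {vid} (dose {vials.doses_Gy[vid]:.2f} Gy) has fewer than 2 "
                f"voxels after {erosion_mm} mm erosion"
            )
        block = vials.data[vid]
        grid = Grid(block.shape[:3], vials.spacing_mm)
        echoes = EchoSeriesVolume(block, vials.echo_times_ms, grid)
        fit = fit_r2(
            echoes,
            noise_sigma=noise_sigma,
            snr_floor=0.0,
            rician_floor_correction=rician_floor_correction and noise_sigma is not None,
        )
        vals = fit.r2[roi & fit.mask]
        rows.append(
            {
                "dose_Gy": float(vials.doses_Gy[vid]),
                "R2_mean": float(vals.mean()),
                "R2_sd": float(vals.std(ddof=1)),
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def fit_calibration(per_vial: pd.DataFrame, weighted: bool = True) -> CalibrationCurve:
    """Fit the linear R2-dose response to the per-vial statistics.

    Inverse-variance weighted least squares when all vials carry a
    positive spread (variance of a vial mean taken as R2_sd^2 /
    n_voxels, treated as known, so the parameter standard errors come
    from (X' W X)^-1 rather than a 9-point residual scale estimate);
    ordinary least squares otherwise.  Pearson r is computed on the
    (dose, R2_mean) pairs, matching a 9-point calibration curve.
    """
    doses = per_vial["dose_Gy"].to_numpy(dtype=float)
    means = per_vial["R2_mean"].to_numpy(dtype=float)
    sds = per_vial["R2_sd"].to_numpy(dtype=float)
    if np.unique(doses).size < 3:
        raise ValueError("at least 3 distinct doses are required")

    X = sm.add_constant(doses)
    if weighted and np.all(sds > 0):
        n_vox = (
            per_vial["n_voxels"].to_numpy(dtype=float)
            if "n_voxels" in per_vial
            else np.ones_like(sds)
        )
        var_mean = sds**2 / n_vox
        res = sm.WLS(means, X, weights=1.0 / var_mean).fit()
        icpt, slope = res.params
        icpt_se, slope_se = np.sqrt(np.diag(res.normalized_cov_params))
    else:
        res = sm.OLS(means, X).fit()
        icpt, slope = res.params
        icpt_se, slope_se = res.bse

    r, _ = stats.pearsonr(doses, means)
    resid = means - (icpt + slope * doses)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(icpt),
        slope_se=float(slope_se),
        intercept_se=float(icpt_se),
        pearson_r=float(r),
        residual_sigma_R2=float(resid.std(ddof=1)) if resid.size > 2 else 0.0,
        dose_range_Gy=(float(doses.min()), float(doses.max())),
        per_vial=per_vial.copy(),
    )


def mean_uncertainty(curve: CalibrationCurve) -> float:
    """Mean relative dose uncertainty of the calibration batch (%).

    Per vial the single-voxel dose spread is sigma_D = R2_sd / |slope|;
    the diagnostic averages 100 * sigma_D / dose over all positive-dose
    vials (zero-dose vials are excluded with a warning).
    """
    if curve.slope <= 0:
        raise ValueError("mean uncertainty requires a positive calibration slope")
    pv = curve.per_vial
    keep = pv["dose_Gy"] > 0
    if not keep.all():
        log.warning("excluding %d zero-dose vial(s) from mean uncertainty", int((~keep).sum()))
    pv = pv[keep]
    if pv.empty:
        raise ValueError("no positive-dose vials available")
    sigma_d = pv["R2_sd"].to_numpy() / abs(curve.slope)
    return float(np.mean(100.0 * sigma_d / pv["dose_Gy"].to_numpy()))


def dose_resolution(
    curve: CalibrationCurve,
    p: float = 0.95,
    at_dose_Gy: float | None = None,
    coverage_k: float | None = None,
) -> float:
    """Minimum resolvable dose separation D_delta_p (Gy).

    D_delta_p = k_p * sqrt(2) * sigma_D with sigma_D = sigma_R2 / |slope|
    interpolated at ``at_dose_Gy`` from the per-vial spreads (averaged
    over the calibration range when absent).  The coverage factor
    defaults to the two-sided Gaussian k_p = sqrt(2) * erfinv(p)
    (1.96 at 95%); pass ``coverage_k`` to reproduce other conventions.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("confidence p must lie strictly between 0 and 1")
    k = coverage_k if coverage_k is not None else math.sqrt(2.0) * special.erfinv(p)
    pv = curve.per_vial.sort_values("dose_Gy")
    doses = pv["dose_Gy"].to_numpy(dtype=float)
    sds = pv["R2_sd"].to_numpy(dtype=float)
    if at_dose_Gy is not None:
        sigma_r2 = float(np.interp(at_dose_Gy, doses, sds))
    else:
        sigma_r2 = float(sds.mean())
    sigma_d = sigma_r2 / abs(curve.slope)
    return float(k * math.sqrt(2.0) * sigma_d)
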