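"""Voxelwise R2 relaxometry and scanner-bias correction.

Fits the mono-exponential echo decay S(TE) = S0 * exp(-R2 * TE) across
the echo train, voxel by voxel, and divides out the smooth spatial bias
estimated from the uniform reference-phantom scan.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage, optimize

from .core import OUTSIDE, EchoSeriesVolume, R2Map

log = logging.getLogger(__name__)

__all__ = ["fit_r2", "correct_inhomogeneity", "background_sigma"]

_METHODS = ("loglinear_weighted", "nonlinear")


def _loglinear_weighted(
    data: np.ndarray, te_s: np.ndarray, noise_sigma: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signal-weighted least squares on log(S) (weights S^2).

    With Var(log S) ~ sigma^2 / S^2 (delta method), weights w = S^2 make
    this the near-maximum-likelihood estimator at high SNR.  Returns
    (r2, r2_sigma, fit_ok) flattened over voxels.
    """
    pos = data > 0
    n_pos = pos.sum(axis=-1)
    fit_ok = n_pos >= 3

    w = np.where(pos, data, 0.0) ** 2
    y = np.where(pos, np.log(np.where(pos, data, 1.0)), 0.0)
    t = te_s

    sw = w.sum(axis=-1)
    st = (w * t).sum(axis=-1)
    stt = (w * t * t).sum(axis=-1)
    sy = (w * y).sum(axis=-1)
    sty = (w * t * y).sum(axis=-1)
    denom = sw * stt - st**2
    safe = fit_ok & (denom > 0)

    slope = np.zeros(data.shape[:-1])
    icpt = np.zeros(data.shape[:-1])
    np.divide(sw * sty - st * sy, denom, out=slope, where=safe)
    np.divide(stt * sy - st * sty, denom, out=icpt, where=safe)
    r2 = -slope

    # Slope variance: residual-based s^2, or the known channel sigma.
    var = np.zeros(data.shape[:-1])
    if noise_sigma is not None:
        np.divide(noise_sigma**2 * sw, denom, out=var, where=safe)
    else:
        resid = y - (icpt[..., None] + slope[..., None] * t)
        ssr = (w * resid**2 * pos).sum(axis=-1)
        dof = np.maximum(n_pos - 2, 1)
        s2 = ssr / dof
        np.divide(s2 * sw, denom, out=var, where=safe)
    return r2, np.sqrt(np.maximum(var, 0.0)), safe


def _nonlinear(
    data: np.ndarray, te_s: np.ndarray, r2_start: np.ndarray, fit_ok: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel exponential least squares, warm-started from the log fit."""
    flat = data.reshape(-1, data.shape[-1])
    r2_out = np.zeros(flat.shape[0])
    sig_out = np.zeros(flat.shape[0])
    ok = fit_ok.ravel()
    start = r2_start.ravel()

    def model(t, s0, r2):
        return s0 * np.exp(-r2 * t)

    for i in np.flatnonzero(ok):
        s = flat[i]
        s0_guess = max(float(s[0]), 1e-12)
        try:
            popt, pcov = optimize.curve_fit(
                model, te_s, s, p0=(s0_guess, max(float(start[i]), 0.0)), maxfev=200
            )
            r2_out[i] = popt[1]
            sig_out[i] = math.sqrt(max(float(pcov[1, 1]), 0.0))
        except (RuntimeError, ValueError):
            ok[i] = False
    return r2_out.reshape(data.shape[:-1]), sig_out.reshape(data.shape[:-1])


def fit_r2(
    echoes: EchoSeriesVolume,
    method: str = "loglinear_weighted",
    snr_floor: float = 5.0,
    noise_sigma: float | None = None,
    rician_floor_correction: bool = False,
) -> R2Map:
    """Fit per-voxel R2 (s^-1) from the multi-echo magnitude volume.

    Parameters
    ----------
    method:
        ``loglinear_weighted`` (default; weighted LS on log-signal) or
        ``nonlinear`` (exponential least squares, log-linear start).
    snr_floor:
        Voxels whose first-echo signal falls below ``snr_floor *
        noise_sigma`` are masked out (requires ``noise_sigma``).
    noise_sigma:
        Gaussian channel noise std.  When given it is used for the
        delta-method fit variance and the SNR floor; otherwise the fit
        variance is residual-based.
    rician_floor_correction:
        Subtract the Rician noise floor, S <- sqrt(max(S^2 - 2 sigma^2, 0)),
        before fitting (off by default; the first-echo SNR in gel is high
        enough that the magnitude bias is negligible there).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if snr_floor < 0:
        raise ValueError("snr_floor must be non-negative")

    te_s = echoes.echo_times_ms / 1000.0
    data = echoes.data
    if rician_floor_correction:
        if not noise_sigma:
            raise ValueError("rician_floor_correction requires noise_sigma")
        data = np.sqrt(np.maximum(data**2 - 2.0 * noise_sigma**2, 0.0))

    r2, r2_sigma, fit_ok = _loglinear_weighted(data, te_s, noise_sigma)
    if method == "nonlinear":
        r2, r2_sigma = _nonlinear(data, te_s, r2, fit_ok)

    mask = fit_ok.copy()
    if noise_sigma is not None and snr_floor > 0:
        mask &= data[..., 0] >= snr_floor * noise_sigma

    r2 = np.where(mask, r2, 0.0)
    r2_sigma = np.where(mask, r2_sigma, 0.0)
    return R2Map(r2, r2_sigma, mask, echoes.grid)


def _masked_gaussian(field: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian blur that ignores values outside the mask (normalized conv)."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(field * m, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 1e-12)
    return out


def correct_inhomogeneity(
    r2: R2Map, reference: R2Map, smoothing_mm: float = 20.0
) -> R2Map:
    """Divide out the scanner's spatial bias using the uniform reference scan.

    The correction field is the reference R2 map, Gaussian-smoothed by
    ``smoothing_mm`` inside its validity mask and normalized to unit
    mean, so a spatially uniform reference leaves the input untouched
    and a global rescaling of the reference has no effect.
    """
    if not r2.grid.same_as(reference.grid):
        raise ValueError("R2 map and reference must share the same grid")
    if np.any(r2.mask & ~reference.mask):
        raise ValueError("reference mask must cover the R2 map mask")

    sigma_vox = [smoothing_mm / s for s in r2.grid.spacing_mm]
    smooth = _masked_gaussian(reference.r2, reference.mask, sigma_vox)
    mean_ref = smooth[reference.mask].mean()
    if mean_ref <= 0:
        raise ValueError("reference R2 has non-positive mean inside its mask")
    c = smooth / mean_ref
    if np.any(c[r2.mask] <= 0):
        raise ValueError("correction field is non-positive inside the R2 mask")

    corr = np.where(r2.mask, r2.r2 / np.where(r2.mask, c, 1.0), 0.0)
    sig = np.where(r2.mask, r2.r2_sigma / np.where(r2.mask, c, 1.0), 0.0)
    return R2Map(corr, sig, r2.mask.copy(), r2.grid)


def background_sigma(
    echoes: EchoSeriesVolume,
    background_region: np.ndarray,
    labels: np.ndarray | None = None,
) -> float:
    """Estimate the Gaussian channel sigma from a signal-free region.

    In background, magnitude data are Rayleigh distributed with mean
    sigma * sqrt(pi / 2); the estimator inverts that relation using all
    echoes of the region's voxels.
    """
    region = np.asarray(background_region, dtype=bool)
    if not region.any():
        raise ValueError("background region is empty")
    if labels is not None and np.any(region & (np.asarray(labels) != OUTSIDE)):
        log.warning("background region overlaps phantom voxels; sigma may be biased high")
    vals = echoes.data[region, :]
    return float(vals.mean() / math.sqrt(math.pi / 2.0))
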