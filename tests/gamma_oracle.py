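"""Exhaustive brute-force gamma oracle (test suite only).

Evaluates every candidate offset for every voxel with no search-order
optimization or early termination, independently of the package's
shell-search implementation.
"""

import numpy as np
from scipy import ndimage

from geldose.gamma_analysis import GammaCriteria, candidate_offsets_mm


def gamma_brute_force(reference, evaluated, criteria: GammaCriteria):
    """Return (gamma, evaluated_mask) by exhaustive candidate enumeration."""
    grid = reference.grid
    if criteria.normalization == "global_max":
        d_norm = float(
            np.percentile(reference.dose[reference.mask], criteria.norm_percentile)
        )
    else:
        d_norm = float(criteria.normalization)
    dd = criteria.dose_diff_pct / 100.0 * d_norm
    thr = criteria.threshold_pct / 100.0 * d_norm
    cap = criteria.search_radius_mm / criteria.dta_mm

    eval_mask = reference.mask & (reference.dose >= thr)
    ev = np.where(evaluated.mask, evaluated.dose, np.nan)
    spacing = np.asarray(grid.spacing_mm)
    offsets = candidate_offsets_mm(grid.spacing_mm, criteria.interp_factor,
                                   criteria.search_radius_mm)
    vox = np.argwhere(eval_mask).astype(float)
    ref_vals = reference.dose[eval_mask]

    best = np.full(vox.shape[0], np.inf)
    for off in offsets:
        coords = (vox + off / spacing).T
        vals = ndimage.map_coordinates(ev, coords, order=1, mode="constant", cval=np.nan)
        gsq = np.linalg.norm(off) ** 2 / criteria.dta_mm**2 + ((vals - ref_vals) / dd) ** 2
        gsq[~np.isfinite(gsq)] = np.inf
        best = np.minimum(best, gsq)

    gamma = np.minimum(np.sqrt(best), cap)
    out = np.zeros(grid.shape)
    out[eval_mask] = gamma
    return out, eval_mask
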