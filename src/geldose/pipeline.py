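"""End-to-end orchestration: simulate, fit, calibrate, compare, report.

Runs the whole analysis on the synthetic phantom: multi-echo simulation
-> R2 fitting -> reference-based bias correction -> vial calibration ->
dose reconstruction -> fiducial registration -> relative normalization
-> 3D gamma -> port-shadow profile statistics, and emits a
machine-readable summary plus optional figures and volumes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import calibration as cal
from . import dose_reconstruction as recon
from . import gamma_analysis as ga
from . import phantom_sim as sim
from . import profile_analysis as prof
from . import r2_mapping as r2m
from .core import GEL, OUTSIDE, WALL, WATER, DoseVolume, save_nifti

log = logging.getLogger(__name__)

__all__ = [
    "ProfileLineConfig",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "default_profile_lines",
    "derive_seeds",
]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible independent run seeds derived from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class ProfileLineConfig:
    """Placement of the port-shadow profile lines and deficit regions.

    Lines cross the with-metal slice (port centre y) and the
    mirror-matched slice at -y.  Each orientation is averaged over a
    small bundle of parallel lines inside the shadow band for noise
    robustness.  Regions hug the inner-dome wall where the shadow and
    the near-wall inhibition band overlap, mirroring where the measured
    underdose is localized.
    """

    n_lines: int = 3
    line_spacing_mm: float = 2.0
    samples_per_mm: float = 2.0
    horizontal_region_mm: tuple[float, float] = (1.5, 4.5)  # offsets from the dome wall
    vertical_halfwidth_mm: float = 1.2  # about the port-centre height
    vertical_x_offset_mm: float = 5.0  # beyond the dome wall radius
    vertical_span_mm: float = 8.0


@dataclass
class RunConfig:
    """Full configuration of a synthetic end-to-end run."""

    phantom: sim.PhantomSpec = field(default_factory=sim.PhantomSpec)
    beams: sim.BeamModel = field(default_factory=sim.BeamModel)
    perturb: sim.PerturbationModel = field(default_factory=sim.PerturbationModel)
    truth: sim.CalibrationTruth = field(default_factory=sim.CalibrationTruth)
    scanner: sim.ScannerModel = field(
        default_factory=lambda: sim.ScannerModel(bias_mode="r2_mult", bias_amplitude=0.02)
    )
    gamma: ga.GammaCriteria = field(
        default_factory=lambda: ga.GammaCriteria(interp_factor=2)
    )
    profiles: ProfileLineConfig = field(default_factory=ProfileLineConfig)
    seed: int = 0
    voxels_per_vial: int = 2000
    vial_erosion_mm: float = 2.0
    reference_uniform_r2: float = 9.0
    correction_smoothing_mm: float = 20.0
    snr_floor: float = 5.0
    rician_floor_correction: bool = True
    norm_percentile: float = 99.5
    norm_wall_margin_mm: float = 8.0
    wall_exclude_margin_mm: float = 3.0
    run_gamma: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "phantom": sim.PhantomSpec,
            "beams": sim.BeamModel,
            "perturb": sim.PerturbationModel,
            "truth": sim.CalibrationTruth,
            "scanner": sim.ScannerModel,
            "gamma": ga.GammaCriteria,
            "profiles": ProfileLineConfig,
        }
        for key, klass in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunReport:
    """Outputs of one pipeline run."""

    summary: dict
    config: RunConfig
    volumes: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)


def default_profile_lines(spec: sim.PhantomSpec, pcfg: ProfileLineConfig) -> dict:
    """Geometry of the with-metal and mirror profile-line bundles.

    Horizontal lines run along the beam axis (x) at the port-centre
    height; vertical lines run along z just beyond the dome-wall radius.
    Deficit regions are the near-wall segments inside the port's
    geometric shadow (and their mirror images on the port-free side).
    """
    px, py, pz = spec.port_center_mm
    a, b, c = spec.inner_dome
    s = 1.0 - (py / b) ** 2 - (pz / c) ** 2
    if s <= 0:
        raise ValueError("port centre height lies outside the inner-dome footprint")
    x_wall = a * np.sqrt(s)  # dome-wall radius at the port-centre height

    half_span = spec.outer_shell[0] + 2.0
    r_lo, r_hi = pcfg.horizontal_region_mm
    n_h = int(2 * half_span * pcfg.samples_per_mm) + 1
    v_span = pcfg.vertical_span_mm
    n_v = int(2 * v_span * pcfg.samples_per_mm) + 1
    xv = x_wall + pcfg.vertical_x_offset_mm

    offsets = (np.arange(pcfg.n_lines) - (pcfg.n_lines - 1) / 2.0) * pcfg.line_spacing_mm
    lines = {}
    for side, y0 in (("with_metal", py), ("without_metal", -py)):
        bundle_h, bundle_v = [], []
        for dy in offsets:
            y = y0 + dy
            bundle_h.append(
                {
                    "start": (-half_span, y, pz),
                    "end": (half_span, y, pz),
                    "n_samples": n_h,
                    "region": [
                        (half_span - x_wall - r_hi, half_span - x_wall - r_lo),
                        (half_span + x_wall + r_lo, half_span + x_wall + r_hi),
                    ],
                }
            )
            bundle_v.append(
                {
                    "start": (xv, y, pz - v_span),
                    "end": (xv, y, pz + v_span),
                    "n_samples": n_v,
                    "region": [
                        (v_span - pcfg.vertical_halfwidth_mm, v_span + pcfg.vertical_halfwidth_mm)
                    ],
                }
            )
        lines[side] = {"horizontal": bundle_h, "vertical": bundle_v}
    return lines


def _bundle_reduction(planned_rel, measured_rel, bundle) -> tuple[float, float]:
    """Average (mean, sd) profile deficit over a bundle of parallel lines."""
    means, sds = [], []
    for ln in bundle:
        pos, pvals = prof.extract_profile(planned_rel, ln["start"], ln["end"], ln["n_samples"])
        _, mvals = prof.extract_profile(measured_rel, ln["start"], ln["end"], ln["n_samples"])
        pair = prof.ProfilePair(pos, pvals, mvals, region=ln["region"])
        m, s = prof.profile_reduction(pair)
        means.append(m)
        sds.append(s)
    return float(np.mean(means)), float(np.mean(sds))


def _default_fiducials(spec: sim.PhantomSpec, frame: str) -> recon.FiducialSet:
    """Four marker points at the phantom base and apex (shared geometry)."""
    a, b, c = spec.outer_shell
    t = spec.wall_thickness_mm
    pts = [
        ("left", (-(a + t), 0.0, 0.0)),
        ("right", (a + t, 0.0, 0.0)),
        ("front", (0.0, b + t, 0.0)),
        ("apex", (0.0, 0.0, c + t)),
    ]
    return recon.FiducialSet.from_arrays(
        [p[0] for p in pts], [p[1] for p in pts], frame
    )


def run_pipeline(
    config: RunConfig, out_dir=None, make_figures: bool = False
) -> RunReport:
    """Execute the full synthetic analysis chain.

    Any stage failure is re-raised with the stage name; outputs produced
    before the failure are retained in the (partially filled) report
    when ``out_dir`` is given.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("run_pipeline seed=%d  config=%s", config.seed, json.dumps(config.to_dict()))
    report = RunReport(summary={"seed": config.seed}, config=config)
    stage = "setup"
    try:
        rng_bias, rng_scan, rng_ref, rng_vials = [
            np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
        ]
        spec, scanner = config.phantom, config.scanner

        stage = "simulate"
        labels = sim.make_phantom_labels(spec)
        planned = sim.planned_dose(spec, config.beams, labels)
        delivered = sim.delivered_dose(planned, labels, config.beams, config.perturb)
        material = labels.labels != OUTSIDE
        bias = sim.make_bias_field(spec.grid, scanner, rng_bias, norm_mask=material)
        echoes = sim.simulate_echoes(delivered, labels, config.truth, scanner,
                                     rng=rng_scan, bias=bias)
        reference = sim.simulate_reference(spec, scanner, config.reference_uniform_r2,
                                           rng=rng_ref, bias=bias)
        vials = sim.simulate_calibration_vials(config.truth, scanner,
                                               config.voxels_per_vial, rng=rng_vials)
        report.volumes.update(labels=labels, planned=planned, delivered=delivered)

        stage = "background_sigma"
        bg = ndimage.binary_erosion(labels.labels == OUTSIDE, iterations=3)
        sigma_bg = (
            r2m.background_sigma(echoes, bg, labels.labels) if scanner.noise_sigma > 0 else None
        )
        report.summary["background_sigma"] = sigma_bg

        stage = "fit_r2"
        floor = config.rician_floor_correction and sigma_bg is not None
        r2 = r2m.fit_r2(echoes, snr_floor=config.snr_floor, noise_sigma=sigma_bg,
                        rician_floor_correction=floor)
        # Restrict to tissue-equivalent voxels: glass/air voxels that leak
        # past the SNR floor carry no dose information.
        r2.mask &= labels.mask(GEL, WATER)
        r2_ref = r2m.fit_r2(reference, snr_floor=config.snr_floor, noise_sigma=sigma_bg,
                            rician_floor_correction=floor)

        stage = "correct_inhomogeneity"
        r2_corr = r2m.correct_inhomogeneity(r2, r2_ref, config.correction_smoothing_mm)

        stage = "calibrate"
        per_vial = cal.vial_roi_stats(vials, config.vial_erosion_mm, noise_sigma=sigma_bg,
                                      rician_floor_correction=floor)
        curve = cal.fit_calibration(per_vial)
        report.tables["per_vial"] = per_vial
        report.summary["calibration"] = {
            "slope_s1_per_Gy": curve.slope,
            "intercept_s1": curve.intercept,
            "pearson_r": curve.pearson_r,
            "mean_uncertainty_pct": cal.mean_uncertainty(curve),
            "dose_resolution_Gy": cal.dose_resolution(curve),
            "dose_resolution_at_3Gy": cal.dose_resolution(curve, at_dose_Gy=3.0),
        }

        stage = "reconstruct"
        measured = recon.r2_to_dose(r2_corr, curve)
        gel = labels.labels == GEL
        measured = measured.copy_with(mask=measured.mask & gel)

        stage = "register"
        moving = _default_fiducials(spec, "measured")
        fixed = _default_fiducials(spec, "planned")
        transform = recon.rigid_from_fiducials(moving, fixed)
        measured = recon.resample_to(measured, transform, planned.grid)
        report.summary["registration_fre_mm"] = transform.fre_mm

        stage = "normalize"
        wallish = (labels.labels == WALL) | (labels.labels == OUTSIDE)
        wall_dist = ndimage.distance_transform_edt(~wallish, sampling=spec.spacing_mm)
        norm_mask = gel & (wall_dist > config.norm_wall_margin_mm)
        planned_gel = planned.copy_with(mask=planned.mask & gel)
        measured_rel, planned_rel = recon.normalize_relative(
            measured, planned_gel, config.norm_percentile, norm_mask=norm_mask
        )
        report.volumes.update(measured_rel=measured_rel, planned_rel=planned_rel)

        px, py, pz = spec.port_center_mm
        if config.run_gamma:
            stage = "gamma"
            # Relative volumes are in % of their own maximum: the global
            # normalization dose for the dose-difference criterion is 100.
            crit = dataclasses.replace(config.gamma, normalization=100.0)
            result = ga.gamma_3d(planned_rel, measured_rel, crit)
            rates = ga.slice_pass_rates(result, axis="y")
            shadow = sim.port_shadow_weight(labels, config.perturb) > 0.5
            comps = ga.export_fail_map(result, labels, shadow_mask=shadow)
            report.volumes["gamma"] = result
            report.tables.update(slice_pass_rates=rates, fail_components=comps)

            y_ax = spec.grid.axes_mm()[1]
            band = np.abs(y_ax - py) <= spec.port_diameter_mm / 2.0 + 2.0
            rate_vals = rates["pass_rate_pct"].to_numpy()
            in_band = rate_vals[band & np.isfinite(rate_vals)]
            out_band = rate_vals[~band & np.isfinite(rate_vals)]
            wall_core = gel & (wall_dist > config.wall_exclude_margin_mm)
            report.summary["gamma"] = {
                "normalization_value": result.normalization_value,
                "pass_rate_overall_pct": result.pass_rate_overall,
                "pass_rate_wall_excluded_pct": result.pass_rate_in(wall_core),
                "metal_band_min_slice_rate_pct": float(np.min(in_band)),
                "outside_band_median_slice_rate_pct": float(np.median(out_band)),
                "metal_band_slices": [int(i) for i in np.flatnonzero(band)],
            }

        stage = "profiles"
        lines = default_profile_lines(spec, config.profiles)
        deficits = {}
        for side in ("with_metal", "without_metal"):
            for orient in ("horizontal", "vertical"):
                deficits[(side, orient)] = _bundle_reduction(
                    planned_rel, measured_rel, lines[side][orient]
                )
        with_list = [deficits[("with_metal", "horizontal")], deficits[("with_metal", "vertical")]]
        without_list = [
            deficits[("without_metal", "horizontal")],
            deficits[("without_metal", "vertical")],
        ]
        attributed = prof.metal_attributed_reduction(with_list, without_list)
        report.summary["profiles"] = {
            "with_metal_horizontal_pct": deficits[("with_metal", "horizontal")],
            "with_metal_vertical_pct": deficits[("with_metal", "vertical")],
            "without_metal_horizontal_pct": deficits[("without_metal", "horizontal")],
            "without_metal_vertical_pct": deficits[("without_metal", "vertical")],
            "metal_attributed_reduction_pct": attributed[0],
            "metal_attributed_reduction_sd_pct": attributed[1],
        }

        stage = "report"
        if out_dir is not None:
            _write_outputs(report, Path(out_dir), make_figures)
        return report
    except Exception as exc:
        if out_dir is not None:
            try:
                _write_outputs(report, Path(out_dir), False)
            except Exception:  # pragma: no cover - best-effort partial output
                pass
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _write_outputs(report: RunReport, out: Path, make_figures: bool) -> None:
    out.mkdir(parents=True, exist_ok=True)
    summary = dict(report.summary)
    summary["config"] = report.config.to_dict()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    for name, table in report.tables.items():
        table.to_csv(out / f"{name}.csv", index=False)
    for name in ("planned", "delivered"):
        if name in report.volumes:
            vol = report.volumes[name]
            save_nifti(out / f"{name}.nii.gz", vol.dose, vol.grid)
    for name in ("measured_rel", "planned_rel"):
        if name in report.volumes:
            vol = report.volumes[name]
            save_nifti(out / f"{name}.nii.gz", vol.dose, vol.grid)
    if "labels" in report.volumes:
        lab = report.volumes["labels"]
        save_nifti(out / "labels.nii.gz", lab.labels, lab.grid)
    if "gamma" in report.volumes:
        ga.export_fail_map(report.volumes["gamma"], out_dir=out)
    if make_figures:
        make_report_figures(report, out)


def make_report_figures(report: RunReport, out_dir) -> list:
    """Report figures: calibration fit, slice pass rates, slice maps, profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if "per_vial" in report.tables:
        pv = report.tables["per_vial"]
        calinfo = report.summary["calibration"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(pv["dose_Gy"], pv["R2_mean"], yerr=pv["R2_sd"], fmt="o", capsize=3)
        d = np.linspace(0, pv["dose_Gy"].max() * 1.05, 50)
        ax.plot(d, calinfo["intercept_s1"] + calinfo["slope_s1_per_Gy"] * d, "-",
                label=f"r = {calinfo['pearson_r']:.4f}")
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("R2 (s$^{-1}$)")
        ax.legend()
        fig.savefig(out / "calibration_curve.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append("calibration_curve.png")

    if "slice_pass_rates" in report.tables:
        rates = report.tables["slice_pass_rates"]
        band = report.summary["gamma"]["metal_band_slices"]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(rates["slice_index"], rates["pass_rate_pct"], "o-")
        if band:
            ax.axvspan(min(band), max(band), alpha=0.2, color="red", label="metal port slices")
        ax.set_xlabel("slice index (y axis)")
        ax.set_ylabel("gamma pass rate (%)")
        ax.legend()
        fig.savefig(out / "slice_pass_rates.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append("slice_pass_rates.png")

    if {"planned_rel", "measured_rel"} <= report.volumes.keys():
        spec = report.config.phantom
        grid = spec.grid
        j_port = int(round(grid.world_to_index(spec.port_center_mm)[0][1]))
        mirror = [spec.port_center_mm[0], -spec.port_center_mm[1], spec.port_center_mm[2]]
        j_mirr = int(round(grid.world_to_index(mirror)[0][1]))
        pr = report.volumes["planned_rel"].dose
        mr = np.where(report.volumes["measured_rel"].mask,
                      report.volumes["measured_rel"].dose, np.nan)
        gam = report.volumes.get("gamma")
        ncol = 3 if gam is not None else 2
        fig, axes = plt.subplots(2, ncol, figsize=(3.2 * ncol, 6))
        for row, j in enumerate((j_port, j_mirr)):
            axes[row, 0].imshow(pr[:, j, :].T, origin="lower", cmap="jet")
            axes[row, 0].set_title(f"planned, slice {j}")
            axes[row, 1].imshow(mr[:, j, :].T, origin="lower", cmap="jet")
            axes[row, 1].set_title(f"measured, slice {j}")
            if gam is not None:
                g = np.where(gam.evaluated_mask, gam.gamma, np.nan)
                axes[row, 2].imshow(g[:, j, :].T, origin="lower", cmap="hot", vmin=0, vmax=2)
                axes[row, 2].set_title(f"gamma, slice {j}")
        for ax in axes.ravel():
            ax.axis("off")
        fig.savefig(out / "slice_maps.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append("slice_maps.png")

        pcfg = report.config.profiles
        lines = default_profile_lines(spec, pcfg)
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey=True)
        for col, side in enumerate(("with_metal", "without_metal")):
            for row, orient in enumerate(("horizontal", "vertical")):
                ln = lines[side][orient][len(lines[side][orient]) // 2]
                pos, p = prof.extract_profile(
                    report.volumes["planned_rel"], ln["start"], ln["end"], ln["n_samples"]
                )
                _, m = prof.extract_profile(
                    report.volumes["measured_rel"], ln["start"], ln["end"], ln["n_samples"]
                )
                ax = axes[row, col]
                ax.plot(pos, p, "-", label="planned")
                ax.plot(pos, m, ".", ms=3, label="measured")
                for a, b in ln["region"]:
                    ax.axvspan(a, b, alpha=0.2, color="gray")
                ax.set_title(f"{side} {orient}")
                ax.set_xlabel("position (mm)")
        axes[0, 0].set_ylabel("relative dose (%)")
        axes[0, 0].legend()
        fig.savefig(out / "profiles.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append("profiles.png")
    return written
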