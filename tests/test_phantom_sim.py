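"""Phantom geometry, beam surrogate and perturbation-model tests."""

import math

import numpy as np
import pytest

from geldose import phantom_sim as sim
from geldose.core import GEL, METAL, OUTSIDE, WALL, WATER

from conftest import coarse_phantom_spec


class TestPhantomLabels:
    def test_labels_partition_grid(self, default_labels):
        """Every voxel carries exactly one label; label volumes sum to the grid."""
        total = sum(default_labels.volume_L(code) for code in (OUTSIDE, WALL, GEL, WATER, METAL))
        grid = default_labels.grid
        assert total == pytest.approx(np.prod(grid.shape) * grid.voxel_volume_mm3 / 1e6)
        assert set(np.unique(default_labels.labels)) <= {OUTSIDE, WALL, GEL, WATER, METAL}

    def test_gel_volume_matches_fill(self, default_labels):
        """Voxelized gel volume reproduces the 0.282 L fill within 5%."""
        spec = sim.PhantomSpec()
        assert default_labels.volume_L(GEL) == pytest.approx(spec.gel_volume_target_L, rel=0.05)

    def test_degenerate_port_gives_no_metal(self):
        spec = sim.PhantomSpec(port_diameter_mm=0.0)
        labels = sim.make_phantom_labels(spec)
        assert not np.any(labels.labels == METAL)

    def test_port_outside_grid_raises_with_coordinate(self):
        spec = coarse_phantom_spec()
        spec.port_center_mm = (0.0, 24.0, 44.9)  # near the dome apex
        spec.z_min_mm = -2.0
        spec.grid_shape = (72, 36, 24)  # grid top below the port
        with pytest.raises(ValueError, match="outside the grid along z"):
            sim.make_phantom_labels(spec)

    def test_voxelized_shell_volume_matches_closed_form(self):
        """Hemiellipsoid-shell voxel count agrees with the analytic volume to 2%."""
        spec = sim.PhantomSpec(
            grid_shape=(96, 96, 42),
            spacing_mm=(1.0, 1.0, 1.0),
            outer_shell=(40.0, 40.0, 35.0),
            inner_dome=(28.0, 28.0, 25.0),
            port_diameter_mm=0.0,
            z_min_mm=-4.0,
        )
        labels = sim.make_phantom_labels(spec)
        assert labels.volume_L(GEL) == pytest.approx(spec.shell_volume_L(), rel=0.02)

    def test_metal_disk_dimensions(self, default_labels):
        """Metal voxel volume matches the 17.9 x 3.9 mm disk within voxelization error."""
        disk_mm3 = math.pi * (17.9 / 2.0) ** 2 * 3.9
        metal_L = default_labels.volume_L(METAL)
        # The disk is clipped to the dome region, so it can only be smaller.
        assert 0.5 * disk_mm3 / 1e6 < metal_L <= 1.1 * disk_mm3 / 1e6


class TestPlannedDose:
    def test_isocenter_receives_prescription(self, default_planned):
        beams = sim.BeamModel()
        grid = default_planned.grid
        idx = grid.world_to_index(beams.isocenter_mm)[0]
        from scipy.ndimage import map_coordinates

        val = map_coordinates(default_planned.dose, idx[:, None], order=1)[0]
        assert val == pytest.approx(beams.prescription_Gy, abs=1e-9)

    def test_no_attenuation_no_wedge_is_uniform(self):
        spec = coarse_phantom_spec()
        labels = sim.make_phantom_labels(spec)
        beams = sim.BeamModel(mu_eff_per_cm=0.0, wedge_angle_deg=0.0, buildup_mm=0.0)
        dose = sim.planned_dose(spec, beams, labels)
        inside = labels.labels != OUTSIDE
        assert np.allclose(dose.dose[inside], beams.prescription_Gy)

    def test_single_beams_are_mirror_images(self):
        """Gantry 90 and gantry 270 doses are x-mirror images of each other."""
        spec = coarse_phantom_spec()
        labels = sim.make_phantom_labels(spec)
        kw = dict(wedge_angle_deg=0.0, isocenter_mm=(0.0, 0.0, 38.0))
        d90 = sim.planned_dose(spec, sim.BeamModel(gantry_angles_deg=(90.0,), **kw), labels)
        d270 = sim.planned_dose(spec, sim.BeamModel(gantry_angles_deg=(270.0,), **kw), labels)
        assert np.allclose(d90.dose, d270.dose[::-1, :, :], atol=1e-9)

    def test_opposed_beams_symmetric_without_wedge(self):
        """Two opposed beams on the x-symmetric phantom give a mirror-symmetric dose."""
        spec = coarse_phantom_spec()
        labels = sim.make_phantom_labels(spec)
        beams = sim.BeamModel(wedge_angle_deg=0.0)
        dose = sim.planned_dose(spec, beams, labels).dose
        assert np.max(np.abs(dose - dose[::-1, :, :])) < 0.01 * beams.prescription_Gy

    def test_isocenter_outside_grid_raises(self):
        spec = coarse_phantom_spec()
        with pytest.raises(ValueError, match="isocenter"):
            sim.planned_dose(spec, sim.BeamModel(isocenter_mm=(0.0, 0.0, 500.0)))

    def test_non_opposed_beams_rejected(self):
        with pytest.raises(ValueError, match="opposed"):
            sim.BeamModel(gantry_angles_deg=(90.0, 240.0))


class TestDeliveredDose:
    def test_zero_perturbation_is_identity(self, default_labels, default_planned):
        perturb = sim.PerturbationModel(wall_deficit_frac=0.0, shadow_deficit_frac=0.0)
        delivered = sim.delivered_dose(default_planned, default_labels, sim.BeamModel(), perturb)
        assert np.array_equal(delivered.dose, default_planned.dose)

    def test_deep_shadow_deficit_equals_shadow_fraction(self, default_labels, default_planned):
        """With wall effects off, the deficit inside the shadow is the shadow fraction."""
        perturb = sim.PerturbationModel(
            wall_deficit_frac=0.0, shadow_deficit_frac=0.098, shadow_softening_mm=0.25
        )
        delivered = sim.delivered_dose(default_planned, default_labels, sim.BeamModel(), perturb)
        shadow = sim.port_shadow_weight(default_labels, perturb)
        gel = default_labels.labels == GEL
        deep = gel & (shadow > 0.999) & (default_planned.dose > 0)
        assert deep.sum() > 100
        deficit = 1.0 - delivered.dose[deep] / default_planned.dose[deep]
        assert np.allclose(deficit, 0.098, atol=1e-3)

    def test_line_average_difference_recovers_extra_deficit(
        self, default_labels, default_planned
    ):
        """Shadow-line mean deficit minus matched no-shadow-line deficit = s - w."""
        perturb = sim.PerturbationModel()
        delivered = sim.delivered_dose(default_planned, default_labels, sim.BeamModel(), perturb)
        spec = sim.PhantomSpec()
        grid = spec.grid
        px, py, pz = spec.port_center_mm
        # x-line through the shadow at the port-centre height, and its mirror
        # through the port-free side; both lie in the full wall-deficit band.
        j = int(round((py - grid.origin_mm[1]) / grid.spacing_mm[1]))
        jm = int(round((-py - grid.origin_mm[1]) / grid.spacing_mm[1]))
        k = int(round((pz - grid.origin_mm[2]) / grid.spacing_mm[2]))
        gel = default_labels.labels == GEL
        shadow = sim.port_shadow_weight(default_labels, perturb)
        sel = gel[:, j, k] & (shadow[:, j, k] > 0.999)
        sel_m = gel[:, jm, k] & (shadow[:, jm, k] < 1e-6)
        ratio = delivered.dose / np.where(default_planned.dose > 0, default_planned.dose, 1.0)
        d_shadow = 1.0 - ratio[sel, j, k].mean()
        d_clean = 1.0 - ratio[sel_m, jm, k].mean()
        expected = perturb.shadow_deficit_frac - perturb.wall_deficit_frac
        assert d_shadow - d_clean == pytest.approx(expected, abs=0.004)

    def test_shadow_extra_deficit_confined_to_port_columns(
        self, default_labels, default_planned
    ):
        """Outside the (softening-dilated) port columns only the wall term acts."""
        perturb = sim.PerturbationModel()
        delivered = sim.delivered_dose(default_planned, default_labels, sim.BeamModel(), perturb)
        wall = sim.wall_deficit_field(default_labels, perturb)
        expected_wall_only = default_planned.dose * (1.0 - wall)
        metal_cols = (default_labels.labels == METAL).any(axis=0)
        from scipy.ndimage import binary_dilation

        dilated = binary_dilation(metal_cols, iterations=4)  # > 4 sigma of softening
        outside_cols = ~dilated[None, :, :] & (default_labels.labels == GEL)
        assert np.allclose(
            delivered.dose[outside_cols], expected_wall_only[outside_cols], rtol=1e-9
        )

    def test_grid_mismatch_raises(self, default_planned):
        labels = sim.make_phantom_labels(coarse_phantom_spec())
        with pytest.raises(ValueError, match="grid"):
            sim.delivered_dose(default_planned, labels, sim.BeamModel(), sim.PerturbationModel())


class TestEchoSimulation:
    def test_noiseless_log_slope_recovers_r2(self):
        scanner = sim.ScannerModel(noise_sigma=0.0, bias_amplitude=0.0)
        te_s = np.asarray(scanner.echo_times_ms) / 1000.0
        truth = sim.CalibrationTruth()
        dose = 7.0 / 3.0  # R2 = 3 + 3 * dose = 10 s^-1
        spec = coarse_phantom_spec()
        labels = sim.make_phantom_labels(spec)
        dose_vol = sim.planned_dose(spec, sim.BeamModel(mu_eff_per_cm=0.0, wedge_angle_deg=0.0,
                                                        buildup_mm=0.0,
                                                        prescription_Gy=dose), labels)
        echoes = sim.simulate_echoes(dose_vol, labels, truth, scanner)
        gel = labels.labels == GEL
        sig = echoes.data[gel][0]
        slope = np.polyfit(te_s, np.log(sig), 1)[0]
        assert slope == pytest.approx(-10.0, abs=1e-9)
        # Closed-form echo ratio: S(70) / S(35) = exp(-0.035 R2)
        assert sig[1] / sig[0] == pytest.approx(np.exp(-0.035 * 10.0), abs=1e-12)

    def test_rician_mean_matches_high_snr_expansion(self):
        """E[M] ~ S (1 + sigma^2 / (2 S^2)) against a 1e5-sample simulation."""
        rng = np.random.default_rng(42)
        s_true, sigma = 100.0, 10.0
        n1 = rng.normal(0, sigma, 100_000)
        n2 = rng.normal(0, sigma, 100_000)
        mags = np.sqrt((s_true + n1) ** 2 + n2**2)
        approx = s_true * (1 + sigma**2 / (2 * s_true**2))
        mc_se = mags.std() / np.sqrt(mags.size)
        assert abs(mags.mean() - approx) < 4 * mc_se + 0.02

    def test_seed_determinism_bit_identical(self):
        spec = coarse_phantom_spec()
        labels = sim.make_phantom_labels(spec)
        planned = sim.planned_dose(spec, sim.BeamModel(), labels)
        scanner = sim.ScannerModel(seed=123)
        truth = sim.CalibrationTruth()
        e1 = sim.simulate_echoes(planned, labels, truth, scanner)
        e2 = sim.simulate_echoes(planned, labels, truth, scanner)
        assert e1.data.tobytes() == e2.data.tobytes()


class TestVials:
    def test_default_doses_give_nine_vials(self):
        vials = sim.simulate_calibration_vials(
            sim.CalibrationTruth(), sim.ScannerModel(), voxels_per_vial=200
        )
        assert vials.n_vials == 9
        assert vials.doses_Gy[0] == 0.5 and vials.doses_Gy[-1] == 4.5

    def test_zero_noise_fits_exact_line(self):
        from geldose.calibration import fit_calibration, vial_roi_stats

        truth = sim.CalibrationTruth(slope=3.0, intercept=3.0)
        vials = sim.simulate_calibration_vials(
            truth, sim.ScannerModel(noise_sigma=0.0), voxels_per_vial=200
        )
        per_vial = vial_roi_stats(vials, erosion_mm=1.0)
        curve = fit_calibration(per_vial)
        assert curve.slope == pytest.approx(3.0, abs=1e-9)
        assert curve.intercept == pytest.approx(3.0, abs=1e-9)

    def test_identical_seeds_bit_identical(self):
        truth, scanner = sim.CalibrationTruth(), sim.ScannerModel(seed=9)
        v1 = sim.simulate_calibration_vials(truth, scanner, 200)
        v2 = sim.simulate_calibration_vials(truth, scanner, 200)
        assert all(a.tobytes() == b.tobytes() for a, b in zip(v1.data, v2.data))

    def test_empty_dose_list_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_calibration_vials(
                sim.CalibrationTruth(vial_doses_Gy=()), sim.ScannerModel(), 100
            )

    def test_csv_round_trip(self, tmp_path):
        truth = sim.CalibrationTruth(vial_doses_Gy=(1.0, 2.0, 3.0))
        vials = sim.simulate_calibration_vials(truth, sim.ScannerModel(seed=3), 50)
        path = tmp_path / "vials.csv"
        vials.to_csv(path)
        loaded = sim.VialEchoSet.from_csv(path)
        assert loaded.n_vials == 3
        orig = np.sort(vials.data[1][vials.masks[1]].ravel())
        back = np.sort(loaded.data[1][loaded.masks[1]].ravel())
        assert np.allclose(orig, back)


class TestReferenceScan:
    def test_uniform_reference_fits_constant_r2(self):
        from geldose.r2_mapping import fit_r2

        spec = coarse_phantom_spec()
        scanner = sim.ScannerModel(noise_sigma=0.0, bias_amplitude=0.0)
        ref = sim.simulate_reference(spec, scanner, uniform_R2=9.0)
        fit = fit_r2(ref, snr_floor=0.0)
        inside = ref.data[..., 0] > 0.5 * scanner.s0
        assert np.allclose(fit.r2[inside], 9.0, atol=1e-9)

    def test_amplitude_bias_does_not_touch_fitted_r2(self):
        """S0-mode bias rescales amplitudes only; the decay rate is invariant."""
        from geldose.r2_mapping import fit_r2

        spec = coarse_phantom_spec()
        scanner = sim.ScannerModel(noise_sigma=0.0, bias_amplitude=0.05, bias_mode="s0", seed=5)
        ref = sim.simulate_reference(spec, scanner, uniform_R2=9.0)
        fit = fit_r2(ref, snr_floor=0.0)
        inside = ref.data[..., 0] > 0.5 * scanner.s0
        assert np.allclose(fit.r2[inside], 9.0, atol=1e-9)

    def test_nonpositive_uniform_r2_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_reference(coarse_phantom_spec(), sim.ScannerModel(), uniform_R2=0.0)


class TestNoiseCalibration:
    def test_sigma_inversion_hits_target_uncertainty(self):
        """noise_sigma_for_uncertainty inverts the closed-form propagation exactly."""
        truth, scanner = sim.CalibrationTruth(), sim.ScannerModel()
        sigma = sim.noise_sigma_for_uncertainty(truth, scanner, target_pct=3.0)
        rel = [
            100.0
            * sim.predicted_r2_sigma(
                truth, sim.ScannerModel(noise_sigma=sigma), d
            )
            / truth.slope
            / d
            for d in truth.vial_doses_Gy
        ]
        assert np.mean(rel) == pytest.approx(3.0, rel=1e-9)

    def test_default_noise_sigma_matches_three_percent(self):
        truth, scanner = sim.CalibrationTruth(), sim.ScannerModel()
        assert scanner.noise_sigma == pytest.approx(
            sim.noise_sigma_for_uncertainty(truth, scanner, 3.0), rel=1e-6
        )


class TestBiasField:
    def test_bias_positive_and_unit_mean(self):
        spec = coarse_phantom_spec()
        scanner = sim.ScannerModel(bias_amplitude=0.05, seed=11)
        mask = sim.make_phantom_labels(spec).labels != OUTSIDE
        bias = sim.make_bias_field(spec.grid, scanner, norm_mask=mask)
        assert np.all(bias > 0)
        assert bias[mask].mean() == pytest.approx(1.0, abs=1e-12)
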