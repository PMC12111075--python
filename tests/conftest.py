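"""Shared fixtures: expensive pipeline runs are session-scoped."""

import numpy as np
import pytest

from geldose import phantom_sim as sim
from geldose.pipeline import ProfileLineConfig, RunConfig, derive_seeds, run_pipeline

BASE_SEED = 1
N_BATCH_SEEDS = 20


def coarse_phantom_spec() -> sim.PhantomSpec:
    """Half-resolution phantom for fast smoke tests."""
    return sim.PhantomSpec(grid_shape=(72, 36, 34), spacing_mm=(140.0 / 72.0, 4.0, 140.0 / 72.0))


def coarse_profile_lines() -> ProfileLineConfig:
    # Wider regions and a single line per orientation: at half resolution the
    # default near-wall regions fall inside the trilinear validity margin.
    return ProfileLineConfig(
        n_lines=1, vertical_halfwidth_mm=2.5, vertical_x_offset_mm=7.0,
        horizontal_region_mm=(2.5, 7.5), samples_per_mm=3.0,
    )


@pytest.fixture
def coarse_config() -> RunConfig:
    return RunConfig(
        phantom=coarse_phantom_spec(),
        profiles=coarse_profile_lines(),
        seed=7,
        log_level="WARNING",
    )


@pytest.fixture(scope="session")
def batch_summaries():
    """Profile-stage pipeline summaries for the 20-seed recovery batch."""
    out = []
    for s in derive_seeds(BASE_SEED, N_BATCH_SEEDS):
        rep = run_pipeline(RunConfig(seed=s, log_level="WARNING", run_gamma=False))
        out.append(rep.summary)
    return out


@pytest.fixture(scope="session")
def gamma_reports():
    """Three full pipeline runs (including gamma) on distinct seeds."""
    return [
        run_pipeline(RunConfig(seed=s, log_level="WARNING"))
        for s in derive_seeds(BASE_SEED + 1, 3)
    ]


@pytest.fixture(scope="session")
def noiseless_report():
    """Full-resolution noise-free run: the generator's recoverable truth."""
    cfg = RunConfig(
        seed=0,
        log_level="WARNING",
        run_gamma=False,
        scanner=sim.ScannerModel(noise_sigma=0.0, bias_mode="r2_mult", bias_amplitude=0.02),
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_labels():
    return sim.make_phantom_labels(sim.PhantomSpec())


@pytest.fixture(scope="session")
def default_planned(default_labels):
    spec = sim.PhantomSpec()
    return sim.planned_dose(spec, sim.BeamModel(), default_labels)
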