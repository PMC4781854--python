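"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from accumloc.config import RunConfig
from accumloc.pipeline import preprocess_session
from accumloc.spectral import compute_feature_bundle
from accumloc.synthetic import (
    BehaviorDesign,
    NoiseConfig,
    PlantedEffect,
    simulate_session,
)

SMALL_AREAS = ["BA19", "BA19", "BA19", "BA19", "BA9", "BA9", "BA9", "BA9"]


@pytest.fixture(scope="session")
def small_design() -> BehaviorDesign:
    return BehaviorDesign(n_blocks=2, trials_per_block=8)


@pytest.fixture(scope="session")
def planted_session(small_design):
    """16-trial session with a strong theta ramp planted in BA19."""
    rng = np.random.default_rng(2024)
    return simulate_session(
        "SUB0",
        rng,
        design=small_design,
        channel_areas=SMALL_AREAS,
        planted=[PlantedEffect("BA19", "theta", "ramp", amplitude=1.0)],
        noise_cfg=NoiseConfig(pink_sd=0.3, carrier_amplitude=0.5),
    )


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    # thresholds are the analysis defaults; only the cohort is scaled down
    return RunConfig(seed=11, min_correct_per_class=2, min_electrodes_per_area=2)


@pytest.fixture(scope="session")
def planted_bundle(planted_session, small_config):
    """Cleaned + feature-extracted version of the planted session."""
    cs = preprocess_session(planted_session, small_config)
    bundle = compute_feature_bundle(
        cs.session,
        cs.exclusion.retained_trials,
        cs.exclusion.retained_channels,
        cs.exclusion.cell_excluded,
    )
    return bundle, cs
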