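import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from franzperm import (
    DEFAULT_GEOMETRY,
    DEFAULT_SCHEDULE_H,
    SamplingSchedule,
    SimulationConfig,
    simulate_permeation,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def schedule():
    return SamplingSchedule(DEFAULT_SCHEDULE_H)


@pytest.fixture
def make_experiment(geometry, schedule):
    """Factory for simulated experiments with the standard cell and schedule."""

    def _make(true_peff=1e-5, c0=10_000.0, n_replicates=3, noise_cv=0.0, seed=0,
              geometry=geometry, schedule=schedule):
        cfg = SimulationConfig(
            true_peff=true_peff,
            geometry=geometry,
            schedule=schedule,
            donor_concentration_0=c0,
            n_replicates=n_replicates,
            noise_cv=noise_cv,
            seed=seed,
        )
        return simulate_permeation(cfg)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
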