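import numpy as np
import pytest

from breathsig.synthetic import (
    CohortSimConfig, RecordingSimConfig, simulate_cohort, simulate_recording,
)


@pytest.fixture(scope="session")
def drifted_recording():
    """Default-noise recording with a 50 ppm mass-axis drift (14 breaths/min)."""
    cfg = RecordingSimConfig(breath_rate=14, drift_ppm=50.0, seed=1)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def noise_free_recording():
    cfg = RecordingSimConfig(breath_rate=14, seed=1,
                             noise_floor_cps=0.0, noise_shot_scale=0.0)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def small_recording():
    """Reduced mass range for fast feature-level tests."""
    cfg = RecordingSimConfig(breath_rate=14, seed=3, mz_range=(10.0, 120.0),
                             calibrant_mzs=(21.0220,), calibrant_cps=(5e4,),
                             extra_channels=((95.05, 2e4), (79.054, 1.5e4)))
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortSimConfig(n_per_group={"asthma": 30, "copd": 25, "control": 40},
                          n_noise_features=100, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
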