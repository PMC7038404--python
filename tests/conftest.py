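import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grfest import SimulationConfig, fit_bundle, simulate_study

settings.register_profile(
    "deterministic", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_study():
    """Six synthetic subjects, two unilateral jumps each, default noise."""
    cfg = SimulationConfig(n_subjects=6, jumps_per_type=2,
                           landing_types=("unilateral",), seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def noiseless_trial():
    cfg = SimulationConfig(n_subjects=1, jumps_per_type=1,
                           landing_types=("unilateral",),
                           noise_sd_per_sensor=0.0, seed=5)
    return simulate_study(cfg)[0].trials[0]


@pytest.fixture(scope="session")
def sacrum_bundle(small_study):
    """Combined model fit on four subjects of the small study."""
    return fit_bundle(small_study[:4], "unilateral", ("sacrum",), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
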