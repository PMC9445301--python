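import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from burstmosaic import BurstParams, simulate_population

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def telegraph_params() -> BurstParams:
    """Bursty reference kinetics with known closed-form moments.

    p_on = 0.25, per-allele mean mRNA = 10, Fano = 7, variance = 70.
    """
    return BurstParams(k_on=1.0, k_off=3.0, k_tx=40.0, d_m=1.0)


@pytest.fixture(scope="session")
def telegraph_population(telegraph_params):
    """One n=4000 stationary snapshot shared across moment checks."""
    return simulate_population(telegraph_params, 4000, seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230101)
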