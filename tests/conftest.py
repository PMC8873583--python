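import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from strsource import TumorSimConfig, simulate_cohort  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy synthetic cohort shared across unit tests."""
    cfg = TumorSimConfig(n_cases=10, n_ui=12, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """A deterministic-signal cohort: observed shares equal expected shares."""
    cfg = TumorSimConfig(n_cases=12, n_ui=6, seed=7, depth_noise=False,
                         p_loh=0.12, p_aadd=0.05, p_anew=0.03)
    return simulate_cohort(cfg)
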