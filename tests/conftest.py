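import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# Test concentrations (% w/w) and printed 2-decimal relative intensities of
# the 15-condition design around the 20% standard, in group-1 sequence order.
TABLE1_GROUP1 = [
    (12.5, 0.46), (18.6, 0.07), (25.0, 0.22), (29.0, 0.37), (8.0, 0.86),
    (21.5, 0.07), (32.0, 0.46), (30.0, 0.40), (13.3, 0.40), (20.0, 0.00),
    (16.0, 0.22), (50.0, 0.86), (23.5, 0.16), (13.8, 0.37), (17.0, 0.16),
]


@pytest.fixture(scope="session")
def table1_group1():
    return TABLE1_GROUP1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def weber_truth():
    """A Weber's-law ground truth well identified by the default design."""
    from nmweber import PsychometricParams

    return PsychometricParams(m=0.25, s=3.0, lapse=0.1, beta=1.0, scale=1.0)


@pytest.fixture(scope="session")
def near_miss_truth():
    """A near-miss ground truth (beta=2.4) on its natural intensity scale."""
    from nmweber import PsychometricParams
    from nmweber.intensity import natural_scale

    return PsychometricParams(
        m=0.25, s=3.0, lapse=0.1, beta=2.4, scale=natural_scale(2.4)
    )


@pytest.fixture(scope="session")
def simulated_records(weber_truth):
    """One simulated 15-condition experiment (200 visits/condition)."""
    from nmweber import SimulationScenario, simulate_performance

    return simulate_performance(SimulationScenario(params=weber_truth, seed=42))
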