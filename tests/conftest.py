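import numpy as np
import pytest

from chbarcode import CenterConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed cohort (clones, drivers, artifacts) reused across tests."""
    cfg = SimulationConfig(
        n_samples=40, seed=123, n_germline_het=2000, error_bump_rate=100,
        shared_pool_size=300, driver_spike_prob=0.6,
        centers=(CenterConfig("Vanguard", "UKB WGS", 0.5, 35.0),
                 CenterConfig("Sanger", "UKB WGS", 0.5, 35.0)))
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
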