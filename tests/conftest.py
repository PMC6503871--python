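import numpy as np
import pytest

from epiaging import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_cohorts():
    """Three small cohorts with default effects, reused read-only."""
    return simulate_cohorts(SimulationConfig(n_cohorts=3, n_per_cohort=80, seed=11))


@pytest.fixture(scope="session")
def one_cohort(small_cohorts):
    return small_cohorts[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
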