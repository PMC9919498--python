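import numpy as np
import pytest

from cetipm import default_scenario, simulate_dataset
from cetipm.inference import FitConfig, IPMData, fit


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def sim(scenario):
    """One full synthetic study shared across read-only tests."""
    return simulate_dataset(scenario, seed=20_040_419)


@pytest.fixture(scope="session")
def ipm_data(sim):
    return IPMData(histories=sim.histories, counts=sim.counts, effort=sim.effort)


@pytest.fixture(scope="session")
def small_fit(ipm_data):
    """A deliberately short MCMC run shared by smoke-level posterior tests."""
    cfg = FitConfig(n_chains=2, n_iterations=500, n_burnin=250, thin=10, seed=99)
    return fit(ipm_data, config=cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
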