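import numpy as np
import pytest

from eocrc.synthetic import SimulationConfig, make_catalog, simulate_cohort


@pytest.fixture(scope="session")
def sim_cohort():
    """One seeded synthetic discovery cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def catalog():
    """A ten-signature synthetic catalog."""
    return make_catalog(n_signatures=10, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
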