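import numpy as np
import pytest

from trophont import isotope as iso
from trophont import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20160912)


@pytest.fixture(scope="session")
def scenarios():
    return sim.default_scenarios()


@pytest.fixture(scope="session")
def three_species_lake(scenarios):
    return sim.simulate_community(scenarios["three_species"], "tri_L1", seed=11)


@pytest.fixture
def baseline():
    return iso.BaselineSet("lake", littoral=(-20.0, 3.0, 8), pelagic=(-30.0, 4.0, 8))
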