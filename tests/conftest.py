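import numpy as np
import pytest

from mldroplet.io import packaged_table
from mldroplet.kelvin import fit_parameters

#: condensed-phase densities measured from droplet core profiles [mg/mL]
RHO_C = {"NDDX4": 359.0, "FUS-LC": 527.0}


@pytest.fixture(scope="session")
def nddx4_table():
    return packaged_table("NDDX4")


@pytest.fixture(scope="session")
def fus_table():
    return packaged_table("FUS-LC")


@pytest.fixture(scope="session")
def nddx4_fit(nddx4_table):
    return fit_parameters(nddx4_table, RHO_C["NDDX4"])


@pytest.fixture(scope="session")
def fus_fit(fus_table):
    return fit_parameters(fus_table, RHO_C["FUS-LC"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20230209)
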