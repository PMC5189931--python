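import numpy as np
import pytest

from emtensemble.dynamics import compile_model, nominal_parameters
from emtensemble.network import load_packaged_model, parse_model_definition

TOY_GENE_MODEL = """\
# one gene, its mRNA/protein pair, and an activation edge
gene Target mrna_init=0.1 protein_init=10
species Activator kind=protein compartment=nucleus init=5 fixed
control Target rule=max : activation Activator
"""

TOY_BINDING_MODEL = """\
species A kind=protein compartment=cytosol init=10
species B kind=protein compartment=cytosol init=6
species C kind=complex compartment=cytosol init=0
reaction bind mass_action : A + B -> C
reaction unbind mass_action : C -> A + B
"""


@pytest.fixture(scope="session")
def model():
    return load_packaged_model()


@pytest.fixture(scope="session")
def compiled(model):
    return compile_model(model)


@pytest.fixture(scope="session")
def nominal(model):
    return nominal_parameters(model)


@pytest.fixture(scope="session")
def toy_gene_model():
    return parse_model_definition(TOY_GENE_MODEL)


@pytest.fixture(scope="session")
def toy_binding_model():
    return parse_model_definition(TOY_BINDING_MODEL)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
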