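import numpy as np
import pytest

from psaboot import fit_model_set, generate_ipd, load_fixture


@pytest.fixture(scope="session")
def scenario():
    """(ModelConfig, TruePopulation) of the shipped synthetic scenario."""
    return load_fixture("scenario_default")


@pytest.fixture(scope="session")
def model(scenario):
    return scenario[0]


@pytest.fixture(scope="session")
def population(scenario):
    return scenario[1]


@pytest.fixture(scope="session")
def ipd100(population):
    """One trial dataset of 100 patients per strategy arm."""
    return generate_ipd(population, 100, seed=11)


@pytest.fixture(scope="session")
def fitted100(ipd100, model):
    return fit_model_set(ipd100, model.model_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
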