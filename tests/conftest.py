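import pytest

from tasseltime import DGNParameters, SimulationSettings, reference_panel, training_panel
from tasseltime.fit import DGNModel
from tasseltime.synthetic import SyntheticConfig, generate_expression


@pytest.fixture(scope="session")
def ref_params() -> DGNParameters:
    return DGNParameters.reference()

@pytest.fixture(scope="session")
def panel():
    return reference_panel()

@pytest.fixture(scope="session")
def by_name(panel):
    return {g.name: g for g in panel}

@pytest.fixture(scope="session")
def settings() -> SimulationSettings:
    return SimulationSettings()

@pytest.fixture(scope="session")
def noiseless_obs():
    """Noiseless closed-form observations for the four training genotypes."""
    return generate_expression(SyntheticConfig())

@pytest.fixture(scope="session")
def noiseless_model(noiseless_obs):
    return DGNModel(noiseless_obs)
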