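import numpy as np
import pytest

from rhdcea import (CostSet, ParameterSet, RhdCeaModel, default_scenarios,
                    synth_life_table)


@pytest.fixture(scope="session")
def params():
    return ParameterSet.base_case()


@pytest.fixture(scope="session")
def costs():
    return CostSet.base_case()


@pytest.fixture(scope="session")
def life68():
    return synth_life_table(68.0)


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def model(params, costs, life68, scenarios):
    return RhdCeaModel(params, costs, life68, scenarios)


@pytest.fixture(scope="session")
def fitted(model):
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20160811)
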