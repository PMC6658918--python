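import numpy as np
import pytest

from valdcm.design import DesignConfig, build_block_schedule, events_to_inputs
from valdcm.inversion import InversionConfig, make_priors
from valdcm.modelspace import make_model_spec
from valdcm.simulate import default_ground_truth


@pytest.fixture(scope="session")
def default_design():
    return build_block_schedule(DesignConfig())


@pytest.fixture(scope="session")
def default_inputs(default_design):
    return events_to_inputs(default_design)


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def full_model_spec():
    return make_model_spec(255)


@pytest.fixture(scope="session")
def inversion_config():
    return InversionConfig()


@pytest.fixture(scope="session")
def full_model_priors(full_model_spec, inversion_config):
    return make_priors(full_model_spec, inversion_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
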