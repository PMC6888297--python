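import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ampktoggle import (
    ModelVariant,
    default_parameters,
    physiological_steady_state,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def extended():
    return ModelVariant()


@pytest.fixture(scope="session")
def template():
    return ModelVariant(mtor_inhibits_ampk=False)


@pytest.fixture(scope="session")
def rest_state(params, extended):
    """Physiological resting state of the calibrated extended model."""
    return physiological_steady_state(params, extended)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20191107)
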