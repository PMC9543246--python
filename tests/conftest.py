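import numpy as np
import pytest

from mmnet import build_parameters


@pytest.fixture(scope="session")
def updated_params():
    return build_parameters("updated_model")


@pytest.fixture(scope="session")
def initial_params():
    return build_parameters("initial_model")


@pytest.fixture
def default_grid():
    return np.linspace(0.0, 72.0, 73)
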