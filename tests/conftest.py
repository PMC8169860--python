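import numpy as np
import pytest

from tdcal.params import default_parameter_space


@pytest.fixture(scope="session")
def space():
    return default_parameter_space()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
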