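import numpy as np
import pytest
from hypothesis import settings

from dimerforce import DEFAULT_ENV, get_preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def env():
    return DEFAULT_ENV


@pytest.fixture(scope="session")
def shear_construct():
    return get_preset("actn1_shear_full")


@pytest.fixture(scope="session")
def unzip_construct():
    return get_preset("actn1_unzip_full")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
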