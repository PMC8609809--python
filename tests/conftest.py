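import numpy as np
import pytest

from wfcnseg.phantom_gen import PhantomParams, make_dataset, make_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(side=64, seed=2024)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return make_phantom(small_params)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return make_dataset(10, small_params)
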