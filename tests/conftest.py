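import numpy as np
import pytest

from bhcvr import build_paradigm, build_regressor_bank
from bhcvr.phantom import default_truth, generate_phantom


@pytest.fixture(scope="session")
def paradigm():
    """The default breath-hold protocol: 44 s lead-in, 4 x (16/16/24) s, 24 s tail."""
    return build_paradigm()


@pytest.fixture(scope="session")
def bank(paradigm):
    return build_regressor_bank(paradigm)


@pytest.fixture(scope="session")
def noiseless_truth():
    return default_truth(seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_series(noiseless_truth, paradigm):
    return generate_phantom(noiseless_truth, paradigm)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
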