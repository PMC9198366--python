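import numpy as np
import pytest

from shiftwave import DiscreteSignal, delta_impulse, make_daubechies_filterbank


@pytest.fixture(scope="session")
def db8():
    return make_daubechies_filterbank(8)


@pytest.fixture(scope="session")
def haar():
    return make_daubechies_filterbank(1)


@pytest.fixture
def delta_1000(db8):
    """The baseline probe: delta impulse, N=1000, L=500, fs=1000 Hz."""
    return delta_impulse(1000, 500, 1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_signal(rng):
    return DiscreteSignal(rng.standard_normal(256), 1000.0)
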