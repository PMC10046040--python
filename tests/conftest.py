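import numpy as np
import pytest

from neurotsne import SyntheticSpec, WindowSet, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_windows(rng):
    """A small unlabelled 21-channel WindowSet of plain Gaussian noise."""
    data = rng.standard_normal((8, 21, 250))
    return WindowSet(data=data, fs=250.0)


@pytest.fixture(scope="session")
def sleep_wake_set():
    """A modest sleep-wake synthetic dataset shared across tests."""
    ws, params = generate(SyntheticSpec(contrast="sleep_wake", n_per_class=100, seed=7))
    return ws, params
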