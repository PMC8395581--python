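import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fs():
    return 128.0


@pytest.fixture(scope="session")
def time_axis(fs):
    """Four seconds at the standard sampling rate."""
    return np.arange(int(4 * fs)) / fs


def pearson(a, b):
    return float(np.corrcoef(a, b)[0, 1])
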