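import numpy as np
import pytest

from infodyn import BinnedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iid_pair(rng):
    """Two independent fair-coin series."""
    x = BinnedSeries(rng.integers(0, 2, 5000))
    y = BinnedSeries(rng.integers(0, 2, 5000))
    return x, y


def make_copy_pair(n, delay, flip_prob=0.0, seed=0):
    """y_t = x_{t-delay} with optional symmetric flip noise."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    y = np.roll(x, delay)
    y[:delay] = rng.integers(0, 2, delay)
    if flip_prob > 0:
        y = y ^ (rng.random(n) < flip_prob)
    return BinnedSeries(x), BinnedSeries(y.astype(int))
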