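import numpy as np
import pytest

from meanet import SpikeMatrix, SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_train(times, duration=10.0):
    return SpikeTrain(np.asarray(times, dtype=np.float64), duration)


def random_train(rng, duration, max_spikes=30):
    n = rng.integers(0, max_spikes + 1)
    t = np.unique(rng.uniform(0, duration, n))
    return SpikeTrain(t, duration)


@pytest.fixture
def small_matrix():
    return SpikeMatrix.from_times(
        [[0.5, 1.0, 4.0], [0.6, 2.0], [], [1.1, 3.3, 8.0]], duration_s=10.0)
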