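import numpy as np
import pytest

from deltapoint import KernelParams, TimeSeries


@pytest.fixture
def params():
    return KernelParams(alpha=2.0, length_scale=3.0,
                        signal_variance=1.5, noise_variance=0.2)


@pytest.fixture
def small_series():
    rng = np.random.default_rng(42)
    n = 12
    return TimeSeries(np.arange(1, n + 1), rng.normal(size=n))


def random_series(seed: int, n: int) -> TimeSeries:
    rng = np.random.default_rng(seed)
    return TimeSeries(np.arange(1, n + 1), rng.normal(size=n))
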