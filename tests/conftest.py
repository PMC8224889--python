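import numpy as np
import pytest

from tfkit import TimeSeries, reference_dataset


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Exact forward-model pair: known one-Γ kernel, no output noise."""
    return reference_dataset(0.0)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Reference pair with white output noise at 10% of the clean peak."""
    return reference_dataset(0.1, seed=11)


@pytest.fixture
def ramp_series():
    """y(t) = 2t on an irregular grid (linear interpolation is exact)."""
    times = np.array([0.0, 0.3, 0.45, 1.0, 1.7, 2.0, 3.1, 4.0])
    return TimeSeries(times, 2.0 * times)


@pytest.fixture
def uniform_series():
    rng = np.random.default_rng(42)
    times = 0.05 * np.arange(200)
    return TimeSeries(times, rng.normal(size=200))
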