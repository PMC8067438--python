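import numpy as np
import pytest

from intervalreg.core import IntervalFrame, IntervalVector


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_interval_dataset(rng, n=60, p=2, slope=None):
    """Small linear interval dataset: centers linear in X, modest ranges."""
    xc = rng.uniform(0.0, 10.0, size=(n, p))
    slope = np.arange(1, p + 1, dtype=float) if slope is None else np.asarray(slope, float)
    yc = 1.0 + xc @ slope + rng.normal(0, 0.3, size=n)
    xr = rng.uniform(0.2, 1.0, size=(n, p))
    yr = 0.5 + 0.1 * xr.sum(axis=1) + rng.normal(0, 0.05, size=n)
    yr = np.clip(yr, 0.0, None)
    X = IntervalFrame.from_arrays(xc - xr, xc + xr)
    y = IntervalVector(np.column_stack([yc - yr, yc + yr]))
    return X, y


def make_point_dataset(rng, n=50, p=2):
    """Degenerate intervals (a == b): interval regression on point data."""
    x = rng.uniform(0.0, 10.0, size=(n, p))
    yv = 2.0 + x @ np.arange(1, p + 1, dtype=float) + rng.normal(0, 0.5, size=n)
    X = IntervalFrame.from_arrays(x, x.copy())
    y = IntervalVector(np.column_stack([yv, yv]))
    return X, y, x, yv


@pytest.fixture
def interval_dataset(rng):
    return make_interval_dataset(rng)


@pytest.fixture
def point_dataset(rng):
    return make_point_dataset(rng)
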