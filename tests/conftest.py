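import numpy as np
import pytest

import tadstorm as ts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def symmetric_calibration():
    """Astigmatism calibration with wx(z) = wy(-z), focal plane at z = 0."""
    z = np.linspace(-500, 500, 21)
    wx = 160 * np.sqrt(1 + ((z - 200) / 400) ** 2)
    wy = 160 * np.sqrt(1 + ((z + 200) / 400) ** 2)
    return ts.build_calibration(z, wx, wy)


@pytest.fixture
def random_table(rng):
    n = 100
    return ts.LocalizationTable.from_arrays(
        x=rng.uniform(0, 1e4, n), y=rng.uniform(0, 1e4, n),
        z=rng.uniform(-400, 400, n), frame=rng.integers(0, 2000, n),
        channel="647", photons=rng.poisson(2000, n).astype(float),
        width_x=rng.uniform(120, 300, n), width_y=rng.uniform(120, 300, n))
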