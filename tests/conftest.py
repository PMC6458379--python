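import numpy as np
import pytest

import trendgls as tg


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def linear_design_40():
    """Linear design over the 40 consecutive years 1977-2016."""
    return tg.build_polynomial_design(np.arange(1977, 2017, dtype=float), 1)


@pytest.fixture
def linear_design_150():
    """Linear design over the 150 consecutive years 1850-1999."""
    return tg.build_polynomial_design(np.arange(1850, 2000, dtype=float), 1)


def ar1_dataset(N, rho, seed, slope=0.0):
    """AR(1) noise plus an optional linear trend on times 0..N-1."""
    t = np.arange(N, dtype=float)
    design = tg.build_polynomial_design(t, 1)
    y = tg.gen_ar1(N, rho, np.random.default_rng(seed)) + slope * (t - t.mean())
    return design, y
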