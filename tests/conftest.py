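import numpy as np
import pytest

from drcoupling import CompartmentParams, default_grid


@pytest.fixture(scope="session")
def grid():
    """The study (TE, b, NEX) protocol on the desk-scale phantom matrix."""
    return default_grid()


@pytest.fixture
def two_pool_params():
    """A young-regime voxel: high-ADC pool has the lower R2 (positive coupling)."""
    return CompartmentParams(f1=0.6, f2=0.4, adc1=1.0e-3, adc2=0.6e-3,
                             r2_1=18.0, r2_2=22.0, s0=1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def grid_search_monoexp(x, y, rate_lo, rate_hi, n_grid=100_001):
    """Exhaustive least-squares oracle for A * exp(-k x).

    Scans ``k`` on a dense grid; for each ``k`` the optimal amplitude has
    the closed form A(k) = sum(y e^{-kx}) / sum(e^{-2kx}).  Independent of
    the package's NLLS path.
    """
    x = np.asarray(x, float)[:, None]
    y = np.asarray(y, float)[:, None]
    k = np.linspace(rate_lo, rate_hi, n_grid)[None, :]
    e = np.exp(-k * x)
    a = (y * e).sum(axis=0) / (e * e).sum(axis=0)
    sse = ((y - a * e) ** 2).sum(axis=0)
    i = int(np.argmin(sse))
    return float(k[0, i]), float(a[i])
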