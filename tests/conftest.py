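import numpy as np
import pytest

from lostcaps import SizeDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_gaussian():
    """The canonical study condition: unit mean diameter, CV_D = 0.09."""
    return SizeDistribution.gaussian(1.0, 0.09)


def ks_distance(sample, grid, cdf):
    """KS statistic of a sample against a model CDF tabulated on a grid."""
    x = np.sort(np.asarray(sample))
    model = np.interp(x, grid, cdf)
    n = x.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(emp_hi - model)), np.max(np.abs(model - emp_lo))))
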