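import numpy as np
import pytest

from nita.simulate import default_calendar, make_trajectory_library
from nita.timeseries import NITAParams, PixelSeries


@pytest.fixture(scope="session")
def calendar():
    return default_calendar()


@pytest.fixture(scope="session")
def library(calendar):
    """The default 100-trajectory validation library (fixed seed)."""
    return make_trajectory_library(calendar, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_inundation(calendar):
    """A noiseless three-segment inundation history on the full calendar."""
    def snap(day):
        return calendar[np.argmin(np.abs(calendar - day))]

    v1 = snap(calendar[0] + int(4.5 * 365.25))
    v2 = snap(v1 + 500)
    bx = np.array([calendar[0], v1, v2, calendar[-1]])
    by = np.array([0.80, 0.80, 0.15, 0.15])
    series = PixelSeries.from_arrays(calendar, np.interp(calendar, bx, by))
    return series, bx, by


@pytest.fixture
def exact_params():
    """Settings under which noiseless piecewise input is recovered exactly:
    median knots, no error filtering."""
    return NITAParams(prctile=50, filt_dist=0, max_segment=10)
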