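import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tweetsurge import ExposureCalendar, TweetSeries

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20110101)


def make_series(counts, start="2011-01-01"):
    counts = np.asarray(counts, dtype=float)
    dates = pd.date_range(start, periods=len(counts), freq="D")
    return TweetSeries(dates, counts)


def make_calendar(exposed, start="2011-01-01", threshold=1.5):
    """Build a calendar directly from an exposure vector (1/0/nan)."""
    exposed = np.asarray(exposed, dtype=float)
    dates = pd.date_range(start, periods=len(exposed), freq="D")
    return ExposureCalendar(dates, np.full(len(exposed), np.nan), threshold, exposed)


@pytest.fixture
def four_cell_rows():
    """Analysis rows covering each cell of a 2x2 once."""
    return pd.DataFrame(
        {
            "exposed": [False, False, True, True],
            "sex": ["female", "male", "female", "male"],
        }
    )
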