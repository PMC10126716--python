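import datetime as dt

import numpy as np
import pytest

from pulsepanel.series import HeartRateSeries

DAY = dt.date(2017, 3, 1)


def make_series(values, rate_hz=1.0, pid="P0", date=DAY, t0=0.0):
    """Regular-grid series from a plain value list (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(len(values)) / rate_hz
    return HeartRateSeries(pid, date, t, values, rate_hz=rate_hz)


@pytest.fixture
def rng():
    return np.random.default_rng(20170301)
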