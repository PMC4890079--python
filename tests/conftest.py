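import numpy as np
import pandas as pd
import pytest

from circact.preprocess import MinuteSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20160524)


def make_minute_series(values, start="2016-01-04 00:00:00", source_id="test"):
    """MinuteSeries straight from an array (bypasses resampling)."""
    start = pd.Timestamp(start)
    values = np.asarray(values, dtype=float)
    return MinuteSeries(
        start_clock=start.hour * 60 + start.minute,
        start_date=start.normalize(),
        values=values,
        day_count=len(values) // 1440,
        source_id=source_id,
    )


@pytest.fixture
def square_series():
    """7 identical days: 100 counts 08:00-19:59, 0 otherwise."""
    day = np.zeros(1440)
    day[8 * 60 : 20 * 60] = 100.0
    return make_minute_series(np.tile(day, 7))
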