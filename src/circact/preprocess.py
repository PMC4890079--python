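"""Regularization of raw records to the one-per-minute grid.

The pipeline order is fixed: resample → cutoff → trim.  Sub-minute data
are averaged within each clock minute; coarser-than-minute data are
replicated to every minute a sample spans.  The activity cutoff zeroes
values *strictly below* the threshold, and full-day trimming keeps the
first whole multiple of 1440 minutes, anchored at the first sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import PreprocessWarning, ValidationError
from .io_ingest import ActigraphyRecord

MINUTES_PER_DAY = 1440


@dataclass
class MinuteSeries:
    """Activity on a gapless 1-value-per-minute grid.

    Attributes
    ----------
    start_clock
        Minute-of-day (0–1439) of the first value.
    start_date
        Calendar date of the first value.
    values
        Per-minute activity, all finite and ≥ 0.
    day_count
        Number of complete 1440-minute days (meaningful after trimming).
    source_id
        Provenance label inherited from the record.
    """

    start_clock: int
    start_date: pd.Timestamp
    values: np.ndarray
    day_count: int = 0
    source_id: str = "record"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not 0 <= self.start_clock < MINUTES_PER_DAY:
            raise ValidationError("start_clock must be in [0, 1439]")
        if self.values.size == 0:
            raise ValidationError("empty minute series")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("minute series contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("minute series contains negative values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def minute_of_day(self) -> np.ndarray:
        """Clock minute-of-day for every value."""
        return (self.start_clock + np.arange(len(self.values))) % MINUTES_PER_DAY


def resample_to_minutes(record: ActigraphyRecord) -> MinuteSeries:
    """Regularize a record to one value per clock minute.

    For sampling intervals below 60 s each output minute is the
    arithmetic mean of the samples whose timestamps floor to that
    minute (missing samples excluded); at exactly 60 s the values pass
    through; above 60 s each sample's value is replicated to every
    minute its interval spans.

    Raises
    ------
    ValidationError
        If a minute on the grid ends up with no usable sample — gaps
        and wholly-missing minutes are not imputed here, that cleanup
        is the caller's responsibility upstream.
    """
    interval = record.sampling_interval
    first_minute = record.timestamps[0].floor("min")

    if interval <= 60.0:
        minutes = record.timestamps.floor("min")
        frame = pd.DataFrame({"minute": minutes, "activity": record.activity})
        grouped = frame.groupby("minute", sort=True)["activity"].mean()
        grid = pd.date_range(grouped.index[0], grouped.index[-1], freq="min")
        values = grouped.reindex(grid).to_numpy()
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValidationError(
                f"{record.source_id}: no valid samples for minute starting "
                f"{grid[bad[0]]}; exclude or impute invalid periods before analysis"
            )
    else:
        # each sample covers [t, t + interval); assign its value to every
        # minute whose start falls inside that span
        n_rep = max(1, math.ceil(interval / 60.0))
        starts = record.timestamps.floor("min")
        grid = pd.date_range(
            starts[0],
            (record.timestamps[-1] + pd.Timedelta(seconds=interval - 1)).floor("min"),
            freq="min",
        )
        values = np.full(len(grid), np.nan)
        for ts, act in zip(starts, record.activity):
            i0 = int((ts - grid[0]).total_seconds() // 60)
            values[i0 : i0 + n_rep] = act
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValidationError(
                f"{record.source_id}: no valid sample covers minute starting "
                f"{grid[bad[0]]}; exclude or impute invalid periods before analysis"
            )
        values = values[: len(grid)]

    start = grid[0]
    return MinuteSeries(
        start_clock=int(start.hour * 60 + start.minute),
        start_date=start.normalize(),
        values=values,
        day_count=len(values) // MINUTES_PER_DAY,
        source_id=record.source_id,
    )


def apply_cutoff(series: MinuteSeries, cutoff: float = 1.0) -> MinuteSeries:
    """Zero every minute value strictly below ``cutoff``.

    The default of 1 leaves integer count data untouched (no count is
    strictly below 1 except 0, which is already 0).  Values equal to
    the cutoff survive.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be non-negative")
    values = series.values.copy()
    values[values < cutoff] = 0.0
    return MinuteSeries(
        start_clock=series.start_clock,
        start_date=series.start_date,
        values=values,
        day_count=series.day_count,
        source_id=series.source_id,
    )


def trim_full_days(
    series: MinuteSeries, fullday: bool = True, anchor: str = "first"
) -> MinuteSeries:
    """Cut the series to whole 1440-minute days.

    ``anchor="first"`` (default) keeps the first
    ``floor(len/1440) * 1440`` minutes from the first sample;
    ``anchor="midnight"`` first drops leading minutes up to the next
    midnight so every kept day runs 00:00–23:59.

    With ``fullday=False`` the series is returned unchanged and a
    warning is emitted: interdaily stability and intradaily variability
    depend on the day/night ratio, so partial days bias them.
    """
    if not fullday:
        if len(series) % MINUTES_PER_DAY != 0:
            warnings.warn(
                "series not trimmed to full days; IS and IV depend on the "
                "day/night ratio and may be biased",
                PreprocessWarning,
                stacklevel=2,
            )
        return series
    if anchor not in ("first", "midnight"):
        raise ValueError("anchor must be 'first' or 'midnight'")

    start_clock = series.start_clock
    start_date = series.start_date
    values = series.values
    if anchor == "midnight" and start_clock != 0:
        skip = MINUTES_PER_DAY - start_clock
        values = values[skip:]
        start_clock = 0
        start_date = start_date + pd.Timedelta(days=1)
    n_days = len(values) // MINUTES_PER_DAY
    if n_days == 0:
        raise ValidationError(
            f"no complete day: series has {len(values)} minutes (< {MINUTES_PER_DAY})"
        )
    return MinuteSeries(
        start_clock=start_clock,
        start_date=start_date,
        values=values[: n_days * MINUTES_PER_DAY].copy(),
        day_count=n_days,
        source_id=series.source_id,
    )


def preprocess(
    record: ActigraphyRecord,
    cutoff: float = 1.0,
    fullday: bool = True,
) -> MinuteSeries:
    """Full preprocessing chain: resample → cutoff → trim."""
    return trim_full_days(apply_cutoff(resample_to_minutes(record), cutoff), fullday)
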