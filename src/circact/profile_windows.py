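"""Diurnal minute profile, M10/L5/Lflex window search, and relative amplitude.

The minute-of-day average profile (1440 values keyed by true clock
time) is scanned with circular sliding windows: all 1440 start minutes
are evaluated, windows wrap past midnight (L5 typically spans
midnight).  M10 is the 600-minute window with maximal mean, L5 the
300-minute window with minimal mean; Lflex generalizes L5 to a
user-chosen length.  Relative amplitude is
RA = (M10 − L5) / (M10 + L5) ∈ [0, 1].

Ties between window means are broken by the earliest start minute
counting from 00:00, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._errors import UndefinedResultWarning, ValidationError
from .preprocess import MINUTES_PER_DAY, MinuteSeries


@dataclass
class DiurnalProfile:
    """Minute-of-day averages across days.

    ``minute_means[m]`` is the mean over days of activity at clock
    minute m (0 = 00:00, 1439 = 23:59); ``contributing_days[m]`` counts
    how many days contributed to that minute.
    """

    minute_means: np.ndarray
    contributing_days: np.ndarray
    source_id: str = "record"

    def __post_init__(self) -> None:
        self.minute_means = np.asarray(self.minute_means, dtype=float)
        self.contributing_days = np.asarray(self.contributing_days, dtype=int)
        if self.minute_means.size != MINUTES_PER_DAY:
            raise ValidationError("diurnal profile must have exactly 1440 entries")
        if np.any(self.contributing_days < 1):
            raise ValidationError("every clock minute needs at least one day of data")

    @property
    def hourly_means(self) -> np.ndarray:
        """24 clock-hour means of the minute profile (for plotting)."""
        return self.minute_means.reshape(24, 60).mean(axis=1)


@dataclass
class WindowResult:
    """An extremal window on the diurnal profile."""

    level: float
    start_minute: int
    length_minutes: int
    #: number of candidate windows scanned (always 1440, circular convention)
    n_candidates: int = field(default=MINUTES_PER_DAY, repr=False)

    @property
    def start_time(self) -> str:
        """Clock time 'HH:MM' of the window's first minute."""
        return f"{self.start_minute // 60:02d}:{self.start_minute % 60:02d}"


@dataclass
class NonparamResult:
    """One row of the result matrix."""

    source_id: str
    IS: float
    IV: float
    RA: float
    L5: float
    L5_starttime: str
    M10: float
    M10_starttime: str
    Lflex: float | None = None
    Lflex_starttime: str | None = None

    def to_dict(self) -> dict:
        out = {
            "file": self.source_id,
            "IS": self.IS,
            "IV": self.IV,
            "RA": self.RA,
            "L5": self.L5,
            "L5_starttime": self.L5_starttime,
            "M10": self.M10,
            "M10_starttime": self.M10_starttime,
        }
        if self.Lflex is not None:
            out["Lflex"] = self.Lflex
            out["Lflex_starttime"] = self.Lflex_starttime
        return out


def diurnal_minute_profile(series: MinuteSeries) -> DiurnalProfile:
    """Average the minute series across days, keyed by true clock minute.

    Works for any start time: minute values are binned by their clock
    minute-of-day (from the timestamps, not by offset from the first
    sample), so M10/L5 start times are real clock times.
    """
    if len(series) == 0:
        raise ValidationError("empty series")
    mod = series.minute_of_day
    sums = np.bincount(mod, weights=series.values, minlength=MINUTES_PER_DAY)
    counts = np.bincount(mod, minlength=MINUTES_PER_DAY)
    if np.any(counts == 0):
        missing = int(np.argmax(counts == 0))
        raise ValidationError(
            f"{series.source_id}: no data for clock minute "
            f"{missing // 60:02d}:{missing % 60:02d}; need at least one full day"
        )
    return DiurnalProfile(
        minute_means=sums / counts,
        contributing_days=counts,
        source_id=series.source_id,
    )


def sliding_window_stat(
    profile: DiurnalProfile, length_minutes: int, mode: str
) -> WindowResult:
    """Extremal circular window mean over the diurnal profile.

    Evaluates the mean of all 1440 windows of ``length_minutes``
    starting at each clock minute (wrapping past midnight) and returns
    the max (``mode="max"``) or min (``mode="min"``) together with its
    start minute; ties go to the earliest start from 00:00.
    """
    length = int(length_minutes)
    if not 1 <= length <= MINUTES_PER_DAY:
        raise ValidationError(f"window length must be in [1, 1440], got {length}")
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    # wrap the profile so every start minute has a full window, then take
    # exact per-window means; argmin/argmax pick the earliest tie.
    wrapped = np.concatenate([profile.minute_means, profile.minute_means[: length - 1]])
    window_means = sliding_window_view(wrapped, length).mean(axis=1)
    assert window_means.size == MINUTES_PER_DAY
    # mathematically tied windows can differ by summation-order rounding;
    # treat means within 1e-9 of the profile scale as tied and take the
    # earliest start
    tol = 1e-9 * float(np.max(np.abs(window_means), initial=0.0))
    ext = float(window_means.max() if mode == "max" else window_means.min())
    if mode == "max":
        start = int(np.argmax(window_means >= ext - tol))
    else:
        start = int(np.argmax(window_means <= ext + tol))
    return WindowResult(
        level=float(window_means[start]),
        start_minute=start,
        length_minutes=length,
        n_candidates=int(window_means.size),
    )


def m10_l5(profile: DiurnalProfile) -> tuple[WindowResult, WindowResult]:
    """(M10, L5): the maximal 10-h and minimal 5-h windows."""
    m10 = sliding_window_stat(profile, 600, "max")
    l5 = sliding_window_stat(profile, 300, "min")
    return m10, l5


def lflex(profile: DiurnalProfile, minutes: int) -> WindowResult:
    """Minimal window of a user-chosen length (generalized L5)."""
    return sliding_window_stat(profile, minutes, "min")


def relative_amplitude(m10_level: float, l5_level: float) -> float:
    """RA = (M10 − L5) / (M10 + L5); NaN with a warning when M10 + L5 == 0."""
    if m10_level < 0 or l5_level < 0:
        raise ValidationError("window levels must be non-negative")
    total = m10_level + l5_level
    if total == 0.0:
        warnings.warn(
            "RA undefined: M10 + L5 == 0 (no activity at all); returning NaN",
            UndefinedResultWarning,
            stacklevel=2,
        )
        return float("nan")
    return (m10_level - l5_level) / total
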