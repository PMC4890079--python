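"""Interdaily stability (IS) and intradaily variability (IV).

Both statistics are computed on hourly mean activity values
:math:`x_i`, i = 1..n, with p = 24 sampling points per day:

.. math::

    IS = \\frac{n \\sum_{h=1}^{p} (\\bar{x}_h - \\bar{x})^2}
              {p \\sum_{i=1}^{n} (x_i - \\bar{x})^2}

    IV = \\frac{n \\sum_{i=2}^{n} (x_i - x_{i-1})^2}
              {(n-1) \\sum_{i=1}^{n} (x_i - \\bar{x})^2}

where :math:`\\bar{x}_h` is the mean over days of hour h and
:math:`\\bar{x}` the grand mean.  IS lies in [0, 1] (between/within
variance decomposition): 1 for a day pattern repeated identically,
about 1/d for d days of pure noise.  IV is ≥ 0: it approaches 0 for a
smooth 24-h sinusoid, 2 for white noise, and exceeds 2 when a definite
2-h ultradian component is present.

Constant input leaves both statistics undefined (0/0); NaN is returned
with a warning so batch runs keep going.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._errors import UndefinedResultWarning, ValidationError
from .preprocess import MINUTES_PER_DAY, MinuteSeries

HOURS_PER_DAY = 24


@dataclass
class HourlySeries:
    """Hourly mean activity over whole days.

    ``values`` holds the x_i as consecutive 60-minute block means from
    the series start; with full-day input n == 24 × day_count, so block
    j falls on hour-of-day j mod 24 of the recording's day frame.
    """

    values: np.ndarray
    day_count: int
    source_id: str = "record"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != HOURS_PER_DAY * self.day_count:
            raise ValidationError(
                f"hourly series has {self.values.size} values for "
                f"{self.day_count} days (expected {HOURS_PER_DAY * self.day_count})"
            )

    @property
    def n(self) -> int:
        """Total number of hourly sampling points."""
        return self.values.size

    @property
    def p(self) -> int:
        """Sampling points per day (24 at hourly resolution)."""
        return HOURS_PER_DAY

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())

    @property
    def hour_of_day_means(self) -> np.ndarray:
        """Mean over days for each of the 24 hours, x̄_h."""
        return self.values.reshape(self.day_count, HOURS_PER_DAY).mean(axis=0)


def hourly_means(series: MinuteSeries) -> HourlySeries:
    """Collapse a full-day minute series to hourly means.

    Each hourly value is the mean of its 60 constituent minutes; hours
    are consecutive 60-minute blocks from the first sample, which
    coincide with clock hours whenever the series starts on a whole
    hour (minute-of-day 0–59 → hour 0, and so on).
    """
    n_min = len(series)
    if n_min % MINUTES_PER_DAY != 0:
        raise ValidationError(
            f"series has {n_min} minutes, not a whole number of days; trim first"
        )
    hourly = series.values.reshape(-1, 60).mean(axis=1)
    return HourlySeries(
        values=hourly,
        day_count=n_min // MINUTES_PER_DAY,
        source_id=series.source_id,
    )


def interdaily_stability(h: HourlySeries) -> float:
    """IS: between-day stability of the 24-h activity pattern, in [0, 1].

    Returns NaN (with a warning) for a constant signal, where the
    statistic is 0/0, and for single-day input, where it is identically
    1 and carries no information.
    """
    if h.day_count < 2:
        warnings.warn(
            f"{h.source_id}: IS undefined for a single day "
            "(identically 1); returning NaN",
            UndefinedResultWarning,
            stacklevel=2,
        )
        return float("nan")
    x = h.values
    xbar = x.mean()
    ss_total = float(((x - xbar) ** 2).sum())
    if ss_total == 0.0:
        warnings.warn(
            f"{h.source_id}: IS undefined for a constant signal; returning NaN",
            UndefinedResultWarning,
            stacklevel=2,
        )
        return float("nan")
    ss_hours = float(((h.hour_of_day_means - xbar) ** 2).sum())
    return h.n * ss_hours / (h.p * ss_total)


def intradaily_variability(h: HourlySeries) -> float:
    """IV: hour-to-hour fragmentation of the activity rhythm, ≥ 0.

    Returns NaN (with a warning) for a constant signal (0/0).
    """
    x = h.values
    if x.size < 2:
        raise ValidationError("IV needs at least 2 hourly values")
    xbar = x.mean()
    ss_total = float(((x - xbar) ** 2).sum())
    if ss_total == 0.0:
        warnings.warn(
            f"{h.source_id}: IV undefined for a constant signal; returning NaN",
            UndefinedResultWarning,
            stacklevel=2,
        )
        return float("nan")
    ss_diff = float((np.diff(x) ** 2).sum())
    n = h.n
    return n * ss_diff / ((n - 1) * ss_total)
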