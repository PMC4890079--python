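"""Synthetic actigraphy signals with known ground-truth rhythm structure.

Generators for the analytic limit cases of the non-parametric measures:

* ``sine`` — mesor + amplitude·sin(2π·t/period), clipped at 0; a
  noiseless 24-h sine has IV → 0 and IS = 1 over repeated days.
* ``square`` — rest-activity block wave (high inside a daily active
  window, low outside); perfect repetition gives IS = 1 and, with a
  silent rest phase, RA = 1.
* ``noise`` — i.i.d. Gaussian counts around a mesor (default 10 ± 1 so
  clipping at 0 and the default cutoff of 1 never bite); IS ≈ 1/days,
  IV ≈ 2.
* ``ultradian`` — 2-h-period alternation around the mesor, the
  textbook IV > 2 case (IV = 4 exactly at hourly resolution).
* ``composite`` — pointwise sum of component signals.

All generation is deterministic given ``seed``; records start at
midnight by default so square-wave expectations are exact clock times.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_ingest import ActigraphyRecord, write_actigraphy

KINDS = ("sine", "square", "noise", "ultradian", "composite")


@dataclass
class SignalSpec:
    """Parameters of one synthetic actigraphy signal.

    Times are hours of the day; ``sampling_rate`` is in samples per
    second (1/60 = one per minute, 4/60 = one per 15 s, 1/3600 = one
    per hour).
    """

    kind: str = "sine"
    days: int = 7
    sampling_rate: float = 1.0 / 60.0
    mesor: float = 50.0
    amplitude: float = 50.0
    period_hours: float | None = None  # default: 24 for sine, 2 for ultradian
    active_start: float = 8.0   # square wave: activity begins (hour of day)
    active_end: float = 20.0    # square wave: activity ends
    low: float = 0.0            # square wave: level outside the active window
    noise_sd: float = 1.0
    seed: int = 0
    start: str = "2016-01-04 00:00:00"
    components: tuple["SignalSpec", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.kind == "composite" and not self.components:
            raise ValueError("composite spec needs at least one component")
        if self.period_hours is None:
            self.period_hours = 2.0 if self.kind == "ultradian" else 24.0
        if self.period_hours <= 0:
            raise ValueError("period_hours must be > 0")


def _time_hours(spec: SignalSpec) -> np.ndarray:
    """Hours elapsed since the record start for every sample."""
    interval = 1.0 / spec.sampling_rate
    n = int(round(spec.days * 86400 / interval))
    return np.arange(n) * interval / 3600.0


def generate(spec: SignalSpec) -> ActigraphyRecord:
    """Render a spec to a raw actigraphy record (clipped at 0)."""
    interval = 1.0 / spec.sampling_rate
    t = _time_hours(spec)
    start = pd.Timestamp(spec.start)
    hour_of_day = (start.hour + start.minute / 60 + start.second / 3600 + t) % 24.0

    if spec.kind == "sine":
        values = spec.mesor + spec.amplitude * np.sin(2 * np.pi * t / spec.period_hours)
    elif spec.kind == "square":
        active = (hour_of_day >= spec.active_start) & (hour_of_day < spec.active_end)
        values = np.where(active, spec.mesor + spec.amplitude, spec.low)
    elif spec.kind == "noise":
        rng = np.random.default_rng(spec.seed)
        values = rng.normal(spec.mesor, spec.noise_sd, size=t.size)
    elif spec.kind == "ultradian":
        # square alternation: half a period at +amplitude, half at −amplitude
        phase = np.floor(2.0 * t / spec.period_hours).astype(int) % 2
        values = spec.mesor + spec.amplitude * np.where(phase == 0, 1.0, -1.0)
    elif spec.kind == "composite":
        values = np.zeros(t.size)
        for comp in spec.components:
            comp = replace(
                comp, days=spec.days, sampling_rate=spec.sampling_rate, start=spec.start
            )
            values = values + generate(comp).activity
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(spec.kind)

    values = np.clip(values, 0.0, None)
    timestamps = pd.date_range(start, periods=t.size, freq=pd.Timedelta(seconds=interval))
    return ActigraphyRecord(
        timestamps=timestamps,
        activity=values,
        sampling_interval=interval,
        source_id=f"synthetic_{spec.kind}",
    )


def write_fixture(
    record: ActigraphyRecord,
    path: str | os.PathLike,
    dialect: str = "csv",
    date_sep: str = "-",
    header: bool = False,
) -> str:
    """Write a record as a fixture file in the accepted input format.

    Round-trips bit-identically through
    :func:`circact.io_ingest.read_actigraphy`.
    """
    write_actigraphy(record, path, dialect=dialect, date_sep=date_sep, header=header)
    return os.fspath(path)
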