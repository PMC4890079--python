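"""Actogram-style plots: dual-day raster, minute profile, hourly profile.

All figures are written to files (PNG, fixed size) — no display is
required.  The plotted arrays are exactly the minute series, diurnal
minute profile and hourly profile computed by the analysis modules;
helper functions expose them so tests can check the data without
pixel-comparing images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .preprocess import MINUTES_PER_DAY, MinuteSeries
from .profile_windows import DiurnalProfile

_HOUR_TICKS = np.arange(0, 25, 4)
_FIGSIZE = (8.0, 4.0)


@dataclass
class PlotBundle:
    """Paths of the three single-file plot images."""

    dual_day: str
    minute_profile: str
    hourly_profile: str


def dual_day_matrix(series: MinuteSeries) -> np.ndarray:
    """48-h double-plot raster: row k holds day k and day k+1 side by side.

    The last row's right half is NaN (blank).  Days are the series' own
    1440-minute days (first-sample anchored).
    """
    days = series.values[: series.day_count * MINUTES_PER_DAY].reshape(
        series.day_count, MINUTES_PER_DAY
    )
    out = np.full((series.day_count, 2 * MINUTES_PER_DAY), np.nan)
    out[:, :MINUTES_PER_DAY] = days
    out[:-1, MINUTES_PER_DAY:] = days[1:]
    return out


def _style_clock_axis(ax, hours: float = 24.0) -> None:
    ticks = np.arange(0, hours + 1, 4)
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{int(t) % 24:02d}:00" for t in ticks])
    ax.set_xlim(0, hours)
    ax.set_xlabel("clock time")


def plot_single(
    series: MinuteSeries, profile: DiurnalProfile, out_dir: str | os.PathLike
) -> PlotBundle:
    """Write the three single-file plots and return their paths."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    sid = series.source_id

    # (a) dual-day display
    raster = dual_day_matrix(series)
    fig, axes = plt.subplots(
        raster.shape[0], 1, sharex=True, figsize=(8.0, 1.0 + 0.7 * raster.shape[0]),
        squeeze=False,
    )
    t48 = np.arange(2 * MINUTES_PER_DAY) / 60.0
    for k, ax in enumerate(axes[:, 0]):
        row = raster[k]
        ax.fill_between(t48, 0, np.nan_to_num(row), step="post", color="0.2")
        ax.set_yticks([])
        ax.set_ylabel(f"day {k + 1}", rotation=0, ha="right", va="center", fontsize=8)
        ax.set_ylim(bottom=0)
    _style_clock_axis(axes[-1, 0], hours=48.0)
    fig.suptitle(f"{sid}: dual-day display")
    dual_path = os.path.join(out_dir, f"{sid}_dualday.png")
    fig.savefig(dual_path, dpi=100)
    plt.close(fig)

    # (b) minute-wise averages across 24 h
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    ax.plot(np.arange(MINUTES_PER_DAY) / 60.0, profile.minute_means, lw=0.6, color="C0")
    ax.set_ylabel("activity (counts/min)")
    ax.set_ylim(bottom=0)
    _style_clock_axis(ax)
    ax.set_title(f"{sid}: minute-wise average activity")
    minute_path = os.path.join(out_dir, f"{sid}_minute.png")
    fig.savefig(minute_path, dpi=100)
    plt.close(fig)

    # (c) hourly averages across 24 h
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    ax.bar(np.arange(24) + 0.5, profile.hourly_means, width=0.9, color="C0")
    ax.set_ylabel("activity (counts/min)")
    ax.set_ylim(bottom=0)
    _style_clock_axis(ax)
    ax.set_title(f"{sid}: hourly average activity")
    hourly_path = os.path.join(out_dir, f"{sid}_hourly.png")
    fig.savefig(hourly_path, dpi=100)
    plt.close(fig)

    return PlotBundle(dual_path, minute_path, hourly_path)


def plot_group(hourly_grand_mean: np.ndarray, out_dir: str | os.PathLike) -> str:
    """Write the across-files grand-average hourly profile plot."""
    hourly_grand_mean = np.asarray(hourly_grand_mean, dtype=float)
    if hourly_grand_mean.shape != (24,):
        raise ValueError("expected 24 hourly grand-mean values")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    ax.bar(np.arange(24) + 0.5, hourly_grand_mean, width=0.9, color="C0")
    ax.set_ylabel("activity (counts/min)")
    ax.set_ylim(bottom=0)
    _style_clock_axis(ax)
    ax.set_title("grand average hourly activity")
    path = os.path.join(out_dir, "group_hourly.png")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
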