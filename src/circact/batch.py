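"""Single-file and directory-loop analysis producing the result matrix.

``analyze_file`` runs the full pipeline on one recording:
read → resample to minutes → cutoff → trim to full days →
{hourly means → IS, IV} and {diurnal profile → M10, L5 [, Lflex] → RA}.

``analyze_directory`` maps it over every ``.txt``/``.csv`` file in a
directory (lexicographic order); a failing file yields a NaN row, not
an abort, so week-long batch runs survive one malformed recording.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pandas as pd

from ._errors import CircactError
from .io_ingest import read_actigraphy
from .npmetrics import hourly_means, interdaily_stability, intradaily_variability
from .preprocess import preprocess
from .profile_windows import (
    NonparamResult,
    diurnal_minute_profile,
    lflex,
    m10_l5,
    relative_amplitude,
)

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["file", "IS", "IV", "RA", "L5", "L5_starttime", "M10", "M10_starttime"]


@dataclass
class RunConfig:
    """Pipeline options shared by single-file and loop analysis.

    ``sampling_rate`` is samples per second or ``"infer"``;
    ``flex_minutes``, if set, adds the Lflex columns; ``plot`` controls
    figure output (written next to ``out`` or into ``plot_dir``).
    """

    sampling_rate: float | str = "infer"
    cutoff: float = 1.0
    fullday: bool = True
    flex_minutes: int | None = None
    plot: bool = True
    plot_dir: str | None = None

    def __post_init__(self) -> None:
        if self.flex_minutes is not None and not 1 <= int(self.flex_minutes) <= 1440:
            raise ValueError("flex_minutes must be in [1, 1440]")


def analyze_series(series, flex_minutes: int | None = None):
    """Compute all non-parametric measures of a preprocessed minute series.

    Returns ``(NonparamResult, DiurnalProfile)``; the profile is reused
    by callers for plotting and grand averages.
    """
    hourly = hourly_means(series)
    is_val = interdaily_stability(hourly)
    iv_val = intradaily_variability(hourly)

    profile = diurnal_minute_profile(series)
    m10, l5 = m10_l5(profile)
    ra = relative_amplitude(m10.level, l5.level)

    flex = None if flex_minutes is None else lflex(profile, int(flex_minutes))

    result = NonparamResult(
        source_id=series.source_id,
        IS=is_val,
        IV=iv_val,
        RA=ra,
        L5=l5.level,
        L5_starttime=l5.start_time,
        M10=m10.level,
        M10_starttime=m10.start_time,
        Lflex=None if flex is None else flex.level,
        Lflex_starttime=None if flex is None else flex.start_time,
    )
    return result, profile


def analyze_file(path: str | os.PathLike, config: RunConfig | None = None) -> NonparamResult:
    """Run the full non-parametric analysis on one actigraphy file."""
    config = config or RunConfig()
    path = os.fspath(path)
    try:
        record = read_actigraphy(path, sampling_rate=config.sampling_rate)
        series = preprocess(record, cutoff=config.cutoff, fullday=config.fullday)
        result, profile = analyze_series(series, config.flex_minutes)

        if config.plot:
            from .plots import plot_single

            out_dir = config.plot_dir or os.path.dirname(path) or "."
            plot_single(series, profile, out_dir)

        return result
    except CircactError as err:
        if path in str(err):
            raise
        raise type(err)(f"{path}: {err}") from err


def _nan_result(source_id: str, with_flex: bool) -> NonparamResult:
    nan = float("nan")
    return NonparamResult(
        source_id=source_id,
        IS=nan, IV=nan, RA=nan,
        L5=nan, L5_starttime="",
        M10=nan, M10_starttime="",
        Lflex=nan if with_flex else None,
        Lflex_starttime="" if with_flex else None,
    )


def analyze_directory(
    directory: str | os.PathLike, config: RunConfig | None = None
) -> pd.DataFrame:
    """Analyze every .txt/.csv file in ``directory``; one row per file.

    Files are processed in lexicographic order.  A file that fails to
    parse or validate is logged and reported as a NaN row.  When
    plotting is on, only the grand average of hourly activity across
    files is plotted (as for the original loop functions).
    """
    config = config or RunConfig()
    directory = os.fspath(directory)
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith((".txt", ".csv"))
    )
    if not paths:
        raise FileNotFoundError(f"no .txt or .csv files in {directory}")

    with_flex = config.flex_minutes is not None
    rows: list[NonparamResult] = []
    hourly_profiles = []
    for path in paths:
        stem = os.path.splitext(os.path.basename(path))[0]
        try:
            record = read_actigraphy(path, sampling_rate=config.sampling_rate)
            series = preprocess(record, cutoff=config.cutoff, fullday=config.fullday)
            result, profile = analyze_series(series, config.flex_minutes)
            rows.append(result)
            hourly_profiles.append(profile.hourly_means)
        except (CircactError, OSError) as err:
            log.warning("skipping %s: %s", path, err)
            rows.append(_nan_result(stem, with_flex))

    if config.plot and hourly_profiles:
        import numpy as np

        from .plots import plot_group

        grand = np.mean(np.stack(hourly_profiles), axis=0)
        plot_group(grand, config.plot_dir or directory)

    frame = pd.DataFrame([r.to_dict() for r in rows])
    cols = RESULT_COLUMNS + (["Lflex", "Lflex_starttime"] if with_flex else [])
    return frame.reindex(columns=cols)


def result_frame(results: list[NonparamResult]) -> pd.DataFrame:
    """Assemble NonparamResults into the standard result matrix."""
    frame = pd.DataFrame([r.to_dict() for r in results])
    with_flex = "Lflex" in frame.columns
    cols = RESULT_COLUMNS + (["Lflex", "Lflex_starttime"] if with_flex else [])
    return frame.reindex(columns=cols)


def write_results(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the result matrix to CSV at full double precision."""
    frame.to_csv(os.fspath(path), index=False, float_format="%.17g")
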