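"""Reading and writing raw actigraphy files.

Accepted input is plain text with two positional columns: a timestamp in
the form ``YYYY-MM-DD HH:MM:SS`` or ``YYYY/MM/DD HH:MM:SS`` (first
column) and a non-negative activity count (second column), separated by
comma, tab or whitespace.  Any sampling rate is allowed; regularization
to the one-per-minute grid happens downstream in :mod:`circact.preprocess`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import FormatError, ValidationError

#: the two datetime layouts accepted (dash- and slash-separated dates);
#: anything else (e.g. day-first dates) is ambiguous and rejected.
_DATETIME_FORMATS = ("%Y-%m-%d %H:%M:%S", "%Y/%m/%d %H:%M:%S")

@dataclass
class ActigraphyRecord:
    """Validated raw actigraphy samples at the device's native rate.

    Parameters
    ----------
    timestamps
        Sample times at second resolution, strictly increasing.
    activity
        Non-negative device counts (unitless); NaN marks a missing sample.
    sampling_interval
        Nominal spacing between samples, in seconds.
    source_id
        Label for provenance, normally the file stem.
    irregular
        True when consecutive timestamp gaps deviate from
        ``sampling_interval`` by more than 1 s anywhere in the record.
    """

    timestamps: pd.DatetimeIndex
    activity: np.ndarray
    sampling_interval: float
    source_id: str = "record"
    irregular: bool = field(default=False)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.timestamps) != len(self.activity):
            raise ValidationError(
                f"{len(self.timestamps)} timestamps but {len(self.activity)} activity values"
            )
        if len(self.timestamps) == 0:
            raise ValidationError("empty record")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be positive")
        if len(self.timestamps) > 1:
            gaps = np.diff(self.timestamps.asi8) / 1e9
            if np.any(gaps <= 0):
                bad = int(np.argmax(gaps <= 0)) + 2
                raise ValidationError(
                    f"timestamps not strictly increasing (first violation at row {bad})"
                )
            if np.any(np.abs(gaps - self.sampling_interval) > 1.0):
                self.irregular = True
        finite = self.activity[np.isfinite(self.activity)]
        if finite.size and np.any(finite < 0):
            raise ValidationError("negative activity values are not allowed")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def sampling_rate(self) -> float:
        """Samples per second."""
        return 1.0 / self.sampling_interval


def _sniff_separator(first_line: str) -> str:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return r"\s+"


_SEPARATORS = {"csv": ",", "tsv": "\t", "whitespace": r"\s+"}


def _parse_timestamps(raw: pd.Series, path: str) -> pd.DatetimeIndex:
    """Parse the timestamp column against the two accepted layouts."""
    sample = str(raw.iloc[0])
    fmt = _DATETIME_FORMATS[1] if "/" in sample else _DATETIME_FORMATS[0]
    parsed = pd.to_datetime(raw, format=fmt, errors="coerce")
    if parsed.isna().any():
        row = int(np.argmax(parsed.isna().to_numpy()))
        raise FormatError(
            f"{path}: unparseable timestamp {raw.iloc[row]!r} at data row {row + 1}; "
            f"accepted forms are 'YYYY-MM-DD HH:MM:SS' and 'YYYY/MM/DD HH:MM:SS'"
        )
    return pd.DatetimeIndex(parsed)


def _looks_like_datetime(value: str) -> bool:
    for fmt in _DATETIME_FORMATS:
        try:
            pd.to_datetime(value, format=fmt)
            return True
        except (ValueError, TypeError):
            continue
    return False


def read_actigraphy(
    path: str | os.PathLike,
    dialect: str = "auto",
    sampling_rate: float | str = "infer",
) -> ActigraphyRecord:
    """Read a two-column actigraphy text file into a validated record.

    Parameters
    ----------
    path
        CSV/TSV/whitespace-separated text file; timestamp first column,
        activity second.  A header row is detected automatically (first
        row whose timestamp field does not parse) and skipped.
    dialect
        ``"csv"``, ``"tsv"``, ``"whitespace"`` or ``"auto"`` (sniffed
        from the first line).
    sampling_rate
        Samples per second, or ``"infer"`` to use the median timestamp
        gap.  Inference refuses records where more than 5% of gaps
        deviate from the median by over 1 s.

    Returns
    -------
    ActigraphyRecord
        Unparseable activity fields become NaN (missing-marked), never
        silently zero.

    Raises
    ------
    FormatError
        Fewer than two columns, or a timestamp outside the accepted forms.
    ValidationError
        Non-monotone timestamps, or irregular sampling under ``"infer"``.
    """
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: file is empty")

    if dialect == "auto":
        sep = _sniff_separator(lines[-1])
    else:
        try:
            sep = _SEPARATORS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}") from None

    if sep == r"\s+":
        # whitespace splits the datetime into date + time fields; rejoin.
        # Rows are split manually so a narrower header row cannot upset
        # pandas' column-count inference.
        first, second = [], []
        for ln in lines:
            parts = ln.split()
            if len(parts) >= 3:
                first.append(f"{parts[0]} {parts[1]}")
                second.append(parts[2])
            elif len(parts) == 2:  # e.g. a "timestamp activity" header
                first.append(parts[0])
                second.append(parts[1])
            else:
                raise FormatError(
                    f"{path}: expected timestamp and activity columns, got {ln!r}"
                )
        df = pd.DataFrame({0: first, 1: second})
    else:
        df = pd.read_csv(
            io.StringIO("\n".join(lines)),
            sep=sep,
            header=None,
            dtype=str,
            skipinitialspace=True,
            engine="python",
        )
        if df.shape[1] < 2:
            raise FormatError(
                f"{path}: expected at least 2 columns, found {df.shape[1]}"
            )

    # header auto-detection: first row not parseable as datetime -> skip once
    if not _looks_like_datetime(str(df.iloc[0, 0]).strip()):
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise FormatError(f"{path}: no data rows after header")

    timestamps = _parse_timestamps(df[0].str.strip(), path)

    # float() rather than pandas' fast parser: round-trip exactness matters
    raw_act = df[1].astype(str).str.strip()
    activity = np.empty(len(raw_act), dtype=float)
    for i, token in enumerate(raw_act):
        try:
            activity[i] = float(token)
        except ValueError:
            activity[i] = np.nan  # missing-marked, never silently zero

    if sampling_rate == "infer":
        if len(timestamps) < 2:
            raise ValidationError(f"{path}: cannot infer sampling rate from one sample")
        gaps = np.diff(timestamps.asi8) / 1e9
        if np.any(gaps <= 0):
            bad = int(np.argmax(gaps <= 0)) + 2
            raise ValidationError(
                f"{path}: timestamps not strictly increasing at row {bad}"
            )
        interval = float(np.median(gaps))
        frac_bad = float(np.mean(np.abs(gaps - interval) > 1.0))
        if frac_bad > 0.05:
            raise ValidationError(
                f"{path}: sampling too irregular to infer "
                f"({frac_bad:.1%} of gaps deviate from the median {interval:.0f} s by >1 s); "
                f"pass sampling_rate explicitly"
            )
    else:
        rate = float(sampling_rate)
        if rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        interval = 1.0 / rate

    stem = os.path.splitext(os.path.basename(path))[0]
    return ActigraphyRecord(
        timestamps=timestamps,
        activity=activity,
        sampling_interval=interval,
        source_id=stem,
    )


def write_actigraphy(
    record: ActigraphyRecord,
    path: str | os.PathLike,
    dialect: str = "csv",
    date_sep: str = "-",
    header: bool = False,
) -> None:
    """Write a record in the same two-column layout :func:`read_actigraphy` accepts.

    ``date_sep`` selects between the dash- and slash-separated timestamp
    forms.  Missing samples are written as ``NA``.  The output round-trips
    bit-identically through :func:`read_actigraphy`.
    """
    if date_sep not in ("-", "/"):
        raise ValueError("date_sep must be '-' or '/'")
    sep = {"csv": ",", "tsv": "\t", "whitespace": " "}[dialect]
    fmt = f"%Y{date_sep}%m{date_sep}%d %H:%M:%S"
    times = record.timestamps.strftime(fmt)
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"timestamp{sep}activity\n")
        for t, a in zip(times, record.activity):
            val = "NA" if not np.isfinite(a) else repr(float(a))
            fh.write(f"{t}{sep}{val}\n")
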