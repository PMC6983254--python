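"""Reading and writing triaxial accelerometer tables.

Accepted layouts are a CSV file or the first sheet of an Excel workbook with
either ``timestamp,ax,ay,az`` columns or three bare numeric columns plus an
explicit sampling rate.  Timestamps may be float elapsed seconds or ISO-8601
strings; internally a record is stored as a start time plus a sampling rate,
with per-sample times implied as ``t0 + i/fs``.  All samples are expressed
in units of g (1 g = 9.80665 m/s²) after ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, ParseError, SamplingError

STANDARD_GRAVITY = 9.80665
"""Standard gravity in m/s², used for unit conversion."""

#: median-magnitude window (in raw units) within which a stream is taken
#: to be in m/s²; a resting accelerometer reads ≈1 g or ≈9.81 m/s², so the
#: two unit systems are well separated.
_MS2_MAGNITUDE_WINDOW = (6.0, 16.0)

_DEFAULT_CHANNELS = ("ax", "ay", "az")


@dataclass
class AccelTimeSeries:
    """A uniformly sampled m×3 specific-force record.

    Parameters
    ----------
    t0 : float
        Start time in elapsed seconds (or epoch seconds).
    fs : float
        Sampling rate in Hz, > 0.
    samples : ndarray of shape (m, 3)
        Specific force in g, columns (ax, ay, az).
    channel_names : tuple of str
        Labels for the three axis columns.
    meta : dict
        Free-form provenance information.
    """

    t0: float
    fs: float
    samples: np.ndarray
    channel_names: tuple[str, str, str] = _DEFAULT_CHANNELS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError(
                f"samples must be m×3, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise FormatError("need at least one sample")
        if not np.isfinite(self.samples).all():
            raise FormatError("samples contain non-finite values")
        if not (self.fs > 0):
            raise ParameterError(f"fs must be > 0, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Implied per-sample times, ``t0 + i/fs``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "AccelTimeSeries":
        """Copy of this record with the sample array replaced."""
        return AccelTimeSeries(
            t0=self.t0,
            fs=self.fs,
            samples=samples,
            channel_names=self.channel_names,
            meta=dict(self.meta),
        )


def _coerce_time_column(col: pd.Series) -> np.ndarray:
    """Convert a timestamp column (float seconds or ISO-8601) to elapsed s."""
    numeric = pd.to_numeric(col, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, errors="coerce", format="mixed")
    if parsed.isna().any():
        bad = int(parsed.isna().to_numpy().argmax())
        raise ParseError(f"cannot parse timestamp at data row {bad}: {col.iloc[bad]!r}")
    t = parsed.astype("int64").to_numpy() / 1e9
    return t


def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls", ".xlsm"):
        return pd.read_excel(path, sheet_name=0, header=None)
    # header auto-detection: a first row with a token that is neither numeric
    # nor date-like is taken to be a header row
    df = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    return df


def _first_row_is_header(row) -> bool:
    for cell in row:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            continue
        s = str(cell)
        try:
            float(s)
            continue
        except ValueError:
            pass
        if pd.isna(pd.to_datetime(s, errors="coerce")):
            return True
    return False


def read_accel_table(
    path,
    fs_hint: float | None = None,
    unit_hint: str = "auto",
) -> AccelTimeSeries:
    """Read an accelerometer table from a CSV or Excel file.

    Parameters
    ----------
    path : path-like
        CSV file or Excel workbook (first sheet).  The table must have a
        timestamp column followed by three numeric axis columns, or three
        bare numeric columns with `fs_hint` given.
    fs_hint : float, optional
        Sampling rate in Hz.  Required when the table has no timestamp
        column; when timestamps are present it overrides the inferred rate
        for the uniformity check.
    unit_hint : {"auto", "g", "ms2"}
        Units of the raw values.  With ``"auto"``, a median sample magnitude
        in [6, 16] marks the stream as m/s² and it is divided by 9.80665.

    Returns
    -------
    AccelTimeSeries
        Validated record in g units.
    """
    path = Path(path)
    if unit_hint not in ("auto", "g", "ms2"):
        raise ParameterError(f"unknown unit_hint {unit_hint!r}")
    raw = _read_table(path)
    if raw.shape[0] == 0:
        raise FormatError(f"{path}: empty table")

    channel_names = _DEFAULT_CHANNELS
    if _first_row_is_header(raw.iloc[0]):
        header = [str(c) for c in raw.iloc[0]]
        raw = raw.iloc[1:].reset_index(drop=True)
        if len(header) >= 4:
            channel_names = tuple(header[-3:])
    if raw.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")

    ncol = raw.shape[1]
    if ncol == 4:
        time_col, data = raw.iloc[:, 0], raw.iloc[:, 1:4]
        t = _coerce_time_column(time_col)
    elif ncol == 3:
        if fs_hint is None:
            raise FormatError(
                f"{path}: 3 columns and no timestamps; fs_hint is required"
            )
        t = None
        data = raw
    else:
        raise FormatError(
            f"{path}: expected 3 or 4 columns (timestamp + ax,ay,az), got {ncol}"
        )

    values = data.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        row, col = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: non-numeric cell at data row {row}, axis column {col}"
        )

    if t is not None:
        if len(t) > 1:
            dt = np.diff(t)
            nominal = 1.0 / fs_hint if fs_hint else float(np.median(dt))
            if nominal <= 0:
                raise SamplingError("timestamps are not increasing", index=0)
            bad = np.nonzero(np.abs(dt - nominal) > 0.5 * nominal)[0]
            if bad.size:
                i = int(bad[0]) + 1
                raise SamplingError(
                    f"{path}: non-uniform sampling at row {i}: "
                    f"gap {dt[i - 1]:.6g} s vs nominal {nominal:.6g} s",
                    index=i,
                )
            # snap the estimated rate so write→read round-trips preserve fs
            fs = fs_hint if fs_hint else round((len(t) - 1) / (t[-1] - t[0]), 6)
        else:
            if fs_hint is None:
                raise FormatError(f"{path}: single row needs fs_hint")
            fs = fs_hint
        t0 = float(t[0])
    else:
        fs = float(fs_hint)
        t0 = 0.0

    if unit_hint == "ms2" or (
        unit_hint == "auto"
        and _MS2_MAGNITUDE_WINDOW[0]
        <= float(np.median(np.linalg.norm(values, axis=1)))
        <= _MS2_MAGNITUDE_WINDOW[1]
    ):
        values = values / STANDARD_GRAVITY

    return AccelTimeSeries(
        t0=t0,
        fs=float(fs),
        samples=values,
        channel_names=channel_names,
        meta={"source": str(path), "unit_hint": unit_hint},
    )


def write_accel_table(series: AccelTimeSeries, path, format: str | None = None):
    """Write a record as ``timestamp,ax,ay,az`` to CSV or Excel.

    The format is taken from the file suffix unless given explicitly.
    Values are written at full precision so that
    ``read_accel_table(write_accel_table(s))`` reproduces the samples to
    better than 1e-9 g.
    """
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    if format not in ("csv", "xlsx"):
        raise ParameterError(f"unknown format {format!r}")
    df = pd.DataFrame(
        {
            "timestamp": series.times,
            "ax": series.samples[:, 0],
            "ay": series.samples[:, 1],
            "az": series.samples[:, 2],
        }
    )
    try:
        if format == "csv":
            df.to_csv(path, index=False)
        else:
            df.to_excel(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path
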