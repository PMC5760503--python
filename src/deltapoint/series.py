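"""Univariate, regularly sampled time series: the universal input container.

A :class:`TimeSeries` holds integer time indices (strictly increasing,
contiguous) and real-valued observations.  Series are read from and written to
two-column delimited text; all heavier formats are out of scope.
"""
from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = ["TimeSeries", "read_series", "write_series", "standardize"]


@dataclasses.dataclass(frozen=True)
class TimeSeries:
    """Ordered (time, value) observations.

    ``times`` must be strictly increasing, contiguous integers; ``values`` must
    be finite reals of the same length.  A zero-length series is permitted so
    that an empty conditioning segment (the state right after a change point)
    can be represented.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1:
            raise ParseError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ParseError(
                f"length mismatch: {len(times)} times vs {len(values)} values"
            )
        if len(times) > 1 and not np.all(np.diff(times) == 1):
            raise ParseError("time indices must be strictly increasing and contiguous")
        if len(values) and not np.all(np.isfinite(values)):
            raise ParseError("values must be finite (no NaN/inf)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.times)

    def prefix(self, n: int) -> "TimeSeries":
        """First ``n`` observations."""
        return TimeSeries(self.times[:n], self.values[:n])

    def window(self, start: int, stop: int) -> "TimeSeries":
        """Observations with positional index in ``[start, stop)``."""
        return TimeSeries(self.times[start:stop], self.values[start:stop])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


def read_series(path: str | Path, delimiter: str | None = None) -> TimeSeries:
    """Read a two-column (time, value) delimited text file.

    A single header line is tolerated and skipped if it is non-numeric.
    Malformed rows raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    text = path.read_text()
    try:
        df = pd.read_csv(
            _io.StringIO(text),
            sep=delimiter,
            engine="python",
            comment="#",
            header=None,
            skip_blank_lines=True,
        )
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"{path}: {exc}") from exc

    header_offset = 0
    # Tolerate a single header row of labels.
    first = df.iloc[0] if len(df) else None
    if first is not None and pd.to_numeric(first, errors="coerce").isna().any():
        df = df.iloc[1:].reset_index(drop=True)
        header_offset = 1
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")

    t = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = t.isna() | v.isna()
    if bad.any():
        line = int(bad.idxmax()) + 1 + header_offset
        raise ParseError(f"{path}: non-numeric row at line {line}")
    if len(df) < 5:
        raise ParseError(f"{path}: need at least 5 observations, found {len(df)}")
    if not np.allclose(t.to_numpy(), np.round(t.to_numpy())):
        raise ParseError(f"{path}: time column must be integer indices")
    try:
        return TimeSeries(t.to_numpy().astype(np.int64), v.to_numpy())
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_series(ts: TimeSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write ``time<delim>value`` rows with a header line."""
    ts.to_frame().to_csv(path, sep=delimiter, index=False)


def standardize(ts: TimeSeries, train_len: int | None = None):
    """Z-score a series using the mean/sd of its training prefix.

    Returns ``(standardized_series, mean, sd)``.  The sd uses the population
    convention; a constant prefix falls back to sd=1 so the transform stays
    defined.
    """
    n = len(ts) if train_len is None else int(train_len)
    ref = ts.values[:n]
    if len(ref) == 0:
        raise ParseError("cannot standardize with an empty reference window")
    mean = float(np.mean(ref))
    sd = float(np.std(ref))
    if sd == 0.0:
        sd = 1.0
    return TimeSeries(ts.times, (ts.values - mean) / sd), mean, sd
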