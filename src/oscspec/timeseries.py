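"""Uniformly sampled time series and their delimited-text I/O.

:class:`TimeSeries` is the universal signal currency of the package: a
strictly increasing, uniformly spaced time grid in hours together with
expression values in arbitrary units.  Files are plain delimited text
(tab by default, comma accepted) with a header row whose first column is
``time_h`` and whose remaining columns each hold one labelled series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, SamplingGridError

__all__ = ["TimeSeries", "read_series", "write_series"]

#: relative tolerance on grid uniformity
_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    times
        Sample times in hours; strictly increasing, uniformly spaced
        within a relative tolerance of 1e-9, length >= 4.
    values
        Expression values (arbitrary units), same length as ``times``.
    label
        Optional identifier (probeset-style string).
    """

    times: np.ndarray
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise SamplingGridError("times and values must be 1-D and equally long")
        if t.size < 4:
            raise SamplingGridError(f"need at least 4 samples, got {t.size}")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise SamplingGridError("times must be strictly increasing")
        dt = steps.mean()
        if np.any(np.abs(steps - dt) > _GRID_RTOL * max(abs(dt), 1.0)):
            raise SamplingGridError("times must be uniformly spaced (rtol 1e-9)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise SamplingGridError("non-finite entries in series")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        """Sampling interval in hours."""
        return float((self.times[-1] - self.times[0]) / (self.n - 1))

    @property
    def span(self) -> float:
        """Total record span ``n * dt`` in hours (the implied full period
        of the record, including the closing interval)."""
        return self.n * self.dt

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(self.times, values, label if label is not None else self.label)


def _read_frame(path) -> pd.DataFrame:
    # sniff the delimiter: tab default, comma accepted
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.columns[0] != "time_h":
        raise ConfigError(f"first column must be 'time_h', got {df.columns[0]!r}")
    if df.isna().any().any():
        raise ConfigError("missing values are not permitted in series files")
    return df


def read_series(path) -> dict[str, TimeSeries]:
    """Read a delimited series file into a mapping label -> TimeSeries."""
    df = _read_frame(path)
    t = df["time_h"].to_numpy(dtype=float)
    out: dict[str, TimeSeries] = {}
    for col in df.columns[1:]:
        out[str(col)] = TimeSeries(t, df[col].to_numpy(dtype=float), label=str(col))
    if not out:
        raise ConfigError(f"no series columns in {path}")
    return out


def write_series(path, series: Mapping[str, TimeSeries] | TimeSeries, sep: str = "\t") -> None:
    """Write one or more series sharing a grid to a delimited text file."""
    if isinstance(series, TimeSeries):
        series = {series.label or "series": series}
    items = list(series.items())
    t0 = items[0][1].times
    data = {"time_h": t0}
    for label, ts in items:
        if ts.n != t0.size or not np.allclose(ts.times, t0, rtol=0, atol=1e-9):
            raise ConfigError("all series in one file must share the time grid")
        data[label] = ts.values
    # %.17g round-trips float64 exactly through text
    pd.DataFrame(data).to_csv(
        path, sep=sep, index=False, lineterminator="\n", float_format="%.17g"
    )
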