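"""Temporal alignment of irregular, gappy sensor and image-derived series.

Instruments on a fixed underwater observatory sample at different native rates
(10-min current meters, 60-min hydrography, hourly imaging) and suffer episodic
outages, so series must be mapped onto common time grids before any pairwise
analysis.  The mapping used throughout is bracketed linear interpolation: a value
at target time ``t`` is interpolated between the latest measurement at or before
``t`` and the earliest at or after ``t``; targets without both brackets are
missing.  An optional max-gap guard refuses to bridge outages longer than a
threshold, so week-long sensor failures do not fabricate smooth structure for
the spectral analysis downstream.

Daily averages are computed from the raw (non-interpolated) measurements, and
days without any data are absent from the output rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IrregularSeries",
    "RegularSeries",
    "UndefinedCorrelationError",
    "interpolate_to",
    "to_hourly",
    "pair_series",
    "daily_average",
    "correlation",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation coefficient is undefined (constant input)."""


def _as_utc_index(timestamps) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(timestamps)
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)
    return idx


@dataclass
class IrregularSeries:
    """A series of timestamped measurements with no implied grid.

    The set of stored timestamps is exactly the set of defined measurements;
    gaps are represented by absence, not by sentinel values.

    Parameters
    ----------
    timestamps
        Strictly increasing datetimes (naive datetimes are treated as UTC).
    values
        Measurement per timestamp; must be finite.
    name, unit
        Source label and physical unit, carried through for reporting.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    name: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.timestamps = _as_utc_index(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) == 0:
            raise ValueError("series must contain at least one measurement")
        dt = np.diff(self.timestamps.asi8)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("measurement values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def seconds(self) -> np.ndarray:
        """Timestamps as float seconds since the epoch."""
        return self.timestamps.asi8 / 1e9

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.timestamps, name=self.name or None)

    @classmethod
    def from_pandas(cls, s: pd.Series, unit: str = "") -> "IrregularSeries":
        s = s.dropna()
        return cls(pd.DatetimeIndex(s.index), s.to_numpy(dtype=float),
                   name=str(s.name or ""), unit=unit)


@dataclass
class RegularSeries:
    """An equidistant series with explicit missing markers (NaN).

    Parameters
    ----------
    start
        Timestamp of the first grid point.
    step_hours
        Grid step in hours (> 0).
    values
        One value per grid point; NaN marks a missing grid point.
    """

    start: pd.Timestamp
    step_hours: float
    values: np.ndarray
    name: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if self.start.tz is not None:
            self.start = self.start.tz_convert("UTC").tz_localize(None)
        if self.step_hours <= 0:
            raise ValueError("step_hours must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a non-empty 1-D array")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        offsets = pd.to_timedelta(np.arange(len(self.values)) * self.step_hours, unit="h")
        return self.start + offsets

    @property
    def is_gapless(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.timestamps, name=self.name or None)

    def to_irregular(self) -> IrregularSeries:
        """Drop missing grid points and return the defined measurements."""
        keep = np.isfinite(self.values)
        return IrregularSeries(self.timestamps[keep], self.values[keep],
                               name=self.name, unit=self.unit)


def interpolate_to(series: IrregularSeries, targets) -> np.ndarray:
    """Bracketed linear interpolation of an irregular series at target times.

    For each target ``t`` the interpolant uses the latest measurement time
    ``t_le <= t`` and the earliest ``t_ge >= t``; when ``t`` coincides with a
    measurement the measured value is returned exactly.  Targets before the
    first or after the last measurement have no bracket and come back as NaN —
    the scheme never extrapolates.
    """
    t = series.seconds
    targets = _as_utc_index(targets)
    q = targets.asi8 / 1e9
    out = np.interp(q, t, series.values)
    out[(q < t[0]) | (q > t[-1])] = np.nan
    return out


def _bracket_gaps(series: IrregularSeries, q_seconds: np.ndarray) -> np.ndarray:
    """Length (seconds) of the measurement gap bracketing each target time.

    Targets that coincide with a measurement have gap 0; unbracketed targets
    get +inf.
    """
    t = series.seconds
    gap = np.full(len(q_seconds), np.inf)
    inside = (q_seconds >= t[0]) & (q_seconds <= t[-1])
    qi = q_seconds[inside]
    hi = np.searchsorted(t, qi, side="left")
    lo = np.searchsorted(t, qi, side="right") - 1
    g = np.where(lo == hi, 0.0, t[np.minimum(hi, len(t) - 1)] - t[np.maximum(lo, 0)])
    out = gap
    out[inside] = g
    return out


def to_hourly(series: IrregularSeries, step_hours: float = 1.0,
              max_gap_hours: float | None = 24.0, name: str | None = None) -> RegularSeries:
    """Map an irregular series onto an equidistant grid by linear interpolation.

    The grid starts at the first measurement and steps by ``step_hours`` up to
    the last measurement.  With ``max_gap_hours`` set, grid points whose
    bracketing measurements are further apart than the guard are marked missing
    instead of being bridged; ``None`` disables the guard and interpolates
    across every gap.
    """
    step = pd.to_timedelta(step_hours, unit="h")
    n = int(np.floor((series.timestamps[-1] - series.timestamps[0]) / step)) + 1
    grid = series.timestamps[0] + step * np.arange(n)
    grid = pd.DatetimeIndex(grid)
    values = interpolate_to(series, grid)
    if max_gap_hours is not None:
        gaps = _bracket_gaps(series, grid.asi8 / 1e9)
        values[gaps > max_gap_hours * 3600.0] = np.nan
    return RegularSeries(grid[0], step_hours, values,
                         name=series.name if name is None else name, unit=series.unit)


def pair_series(image_series: IrregularSeries, sensor_series: IrregularSeries,
                max_gap_hours: float | None = None) -> pd.DataFrame:
    """Interpolate a sensor series at the image-series time points.

    Returns a frame with columns ``timestamp, y, x`` (``y`` the image-derived
    value, ``x`` the interpolated sensor value) containing only complete pairs;
    the number of dropped time points is stored in ``frame.attrs['n_dropped']``.
    """
    t0 = max(image_series.timestamps[0], sensor_series.timestamps[0])
    t1 = min(image_series.timestamps[-1], sensor_series.timestamps[-1])
    if t0 > t1:
        raise ValueError("series do not overlap in time")
    x = interpolate_to(sensor_series, image_series.timestamps)
    if max_gap_hours is not None:
        gaps = _bracket_gaps(sensor_series, image_series.seconds)
        x[gaps > max_gap_hours * 3600.0] = np.nan
    keep = np.isfinite(x)
    df = pd.DataFrame({
        "timestamp": image_series.timestamps[keep],
        "y": image_series.values[keep],
        "x": x[keep],
    })
    df.attrs["n_dropped"] = int((~keep).sum())
    return df


def daily_average(series: IrregularSeries | RegularSeries) -> IrregularSeries:
    """Calendar-day (UTC) mean of the available raw measurements.

    No interpolation is applied; a day with no measurements is simply absent
    from the output.  Each output timestamp is the day's midnight UTC.
    """
    if isinstance(series, RegularSeries):
        series = series.to_irregular()
    s = series.to_pandas()
    by_day = s.groupby(s.index.floor("D")).mean()
    return IrregularSeries(pd.DatetimeIndex(by_day.index), by_day.to_numpy(),
                           name=series.name, unit=series.unit)


def correlation(x, y, method: str = "pearson") -> tuple[float, int]:
    """Pearson or Spearman correlation over complete pairs.

    Pairs with a missing value on either side are dropped (no imputation).
    Returns ``(r, n)`` with ``n`` the number of complete pairs used.  Constant
    input raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), n
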