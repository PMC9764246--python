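"""Exposure metrics: hourly station series -> daily metrics -> annual summaries.

Implements the aggregation conventions used by AirQ-family health impact
assessments:

* daily 24-h mean (PM2.5), valid when >= 75% of hours are present;
* daily 1-h maximum (NO2), valid when >= 18 hours are present;
* daily maximum 8-h running mean (O3), computed over the 17 within-day
  windows starting at hours 0..16, each window needing >= 6 valid hours;
* unweighted city-wide daily average over stations with a valid day;
* annual mean with completeness bookkeeping;
* SOMO35 — the annual sum of daily max-8-h ozone exceedances over 35 ppb,
  rescaled by n_total/n_valid to correct for missing days.

Missing hours are represented as NaN and are excluded, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pollutant",
    "StationSeries",
    "DailyMetric",
    "AnnualExposure",
    "daily_mean_24h",
    "daily_max_1h",
    "daily_max_8h_mean",
    "daily_metric_series",
    "city_daily_series",
    "annual_mean",
    "somo35",
    "exceedance_ratio",
    "o3_unit_convert",
    "HOURS_PER_DAY",
    "N_8H_WINDOWS",
    "PPB_TO_UGM3_O3",
]

HOURS_PER_DAY = 24
#: within-day 8-h windows start at hours 0..16 (no cross-midnight windows)
N_8H_WINDOWS = 17
#: ozone ppb -> ug/m3 at 25 degC / 1 atm
PPB_TO_UGM3_O3 = 1.96


class Pollutant(str, Enum):
    PM25 = "PM2.5"
    NO2 = "NO2"
    O3 = "O3"

    @classmethod
    def parse(cls, text) -> "Pollutant":
        """Canonicalize a pollutant name case-insensitively ('pm25' -> PM2.5)."""
        if isinstance(text, cls):
            return text
        key = str(text).strip().lower().replace(".", "").replace("_", "").replace("-", "")
        table = {"pm25": cls.PM25, "no2": cls.NO2, "o3": cls.O3, "ozone": cls.O3}
        if key not in table:
            raise ValueError(f"unknown pollutant {text!r} (expected PM2.5, NO2 or O3)")
        return table[key]


class Metric(str, Enum):
    MEAN_24H = "mean24h"
    MAX_1H = "max1h"
    MAX_8H_MEAN = "max8h_mean"


_UNIT_ALIASES = {
    "ppb": "ppb",
    "ug/m3": "ug/m3",
    "ugm3": "ug/m3",
    "µg/m³": "ug/m3",
    "µg/m3": "ug/m3",
    "ug/m³": "ug/m3",
    "micrograms per cubic meter": "ug/m3",
}


def _canonical_unit(unit: str) -> str:
    key = str(unit).strip().lower()
    if key not in _UNIT_ALIASES:
        raise ValueError(f"unknown concentration unit {unit!r} (expected 'ppb' or 'ug/m3')")
    return _UNIT_ALIASES[key]


@dataclass
class StationSeries:
    """One station's hourly concentrations of one pollutant.

    ``values`` is a pandas Series on an hourly ``DatetimeIndex``; NaN marks a
    missing hour. The index must be strictly increasing and hour-aligned; gaps
    are allowed (they are treated as missing hours).
    """

    station_id: str
    pollutant: Pollutant
    values: pd.Series
    unit: str = "ug/m3"
    period_label: str = ""

    def __post_init__(self) -> None:
        self.pollutant = Pollutant.parse(self.pollutant)
        self.unit = _canonical_unit(self.unit)
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("StationSeries.values must be indexed by a DatetimeIndex")
        if len(idx) and not idx.is_monotonic_increasing:
            raise ValueError(f"station {self.station_id}: timestamps not increasing")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"station {self.station_id}: duplicate timestamp {dup}")
        off_hour = idx[(idx.minute != 0) | (idx.second != 0)]
        if len(off_hour):
            raise ValueError(
                f"station {self.station_id}: non-hourly timestamp {off_hour[0]}"
            )
        vals = self.values.to_numpy(dtype=float)
        neg = np.flatnonzero(vals < 0)
        if neg.size:
            raise ValueError(
                f"station {self.station_id}: negative concentration "
                f"{vals[neg[0]]} at {idx[neg[0]]}"
            )

    def hourly_matrix(self) -> tuple[pd.DatetimeIndex, np.ndarray]:
        """Reindex onto complete days and reshape to (n_days, 24), NaN-filled."""
        if self.values.empty:
            return pd.DatetimeIndex([]), np.empty((0, HOURS_PER_DAY))
        start = self.values.index[0].normalize()
        end = self.values.index[-1].normalize() + pd.Timedelta(hours=HOURS_PER_DAY - 1)
        full = pd.date_range(start, end, freq="h")
        filled = self.values.reindex(full)
        days = pd.DatetimeIndex(full[::HOURS_PER_DAY].normalize())
        return days, filled.to_numpy(dtype=float).reshape(-1, HOURS_PER_DAY)


@dataclass(frozen=True)
class DailyMetric:
    """One day's exposure metric with its validity flag.

    Invariant: ``valid`` implies ``n_valid_hours`` meets the metric's
    completeness threshold; an invalid day carries no value (NaN).
    """

    date: pd.Timestamp
    metric: Metric
    value: float
    n_valid_hours: int
    valid: bool

    def __post_init__(self) -> None:
        if not self.valid and not math.isnan(self.value):
            raise ValueError("invalid day must not carry a value")


@dataclass(frozen=True)
class AnnualExposure:
    """Period-level exposure summary for one pollutant."""

    period_label: str
    annual_mean: float
    n_total: int
    n_valid: int
    somo35: float | None = None  # ppb*days, O3 only
    pollutant: Pollutant | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_valid <= self.n_total:
            raise ValueError(
                f"{self.period_label}: n_valid {self.n_valid} outside [0, {self.n_total}]"
            )
        if self.somo35 is not None and self.somo35 < 0:
            raise ValueError(f"{self.period_label}: negative SOMO35 {self.somo35}")

    @property
    def completeness(self) -> float:
        return self.n_valid / self.n_total if self.n_total else float("nan")


def _check_day(hours: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(hours, dtype=float)
    if arr.ndim != 1 or arr.size != HOURS_PER_DAY:
        raise ValueError(f"expected one calendar day of {HOURS_PER_DAY} hourly slots, got {arr.size}")
    neg = np.flatnonzero(arr < 0)
    if neg.size:
        raise ValueError(f"negative concentration {arr[neg[0]]} at hour slot {neg[0]}")
    return arr


def daily_mean_24h(
    hours: Sequence[float],
    min_fraction: float = 0.75,
    date: pd.Timestamp | None = None,
) -> DailyMetric:
    """24-h mean of one day; valid when the share of present hours >= ``min_fraction``."""
    arr = _check_day(hours)
    n_valid = int(np.sum(~np.isnan(arr)))
    ok = n_valid / HOURS_PER_DAY >= min_fraction and n_valid > 0
    value = float(np.nanmean(arr)) if ok else float("nan")
    return DailyMetric(pd.Timestamp(date) if date is not None else pd.NaT,
                       Metric.MEAN_24H, value, n_valid, ok)


def daily_max_1h(
    hours: Sequence[float],
    min_hours: int = 18,
    date: pd.Timestamp | None = None,
) -> DailyMetric:
    """Maximum 1-h value of one day; valid when >= ``min_hours`` hours are present."""
    arr = _check_day(hours)
    n_valid = int(np.sum(~np.isnan(arr)))
    ok = n_valid >= min_hours and n_valid > 0
    value = float(np.nanmax(arr)) if ok else float("nan")
    return DailyMetric(pd.Timestamp(date) if date is not None else pd.NaT,
                       Metric.MAX_1H, value, n_valid, ok)


def _max8h_from_matrix(
    mat: np.ndarray, min_hours_per_window: int, min_hours_per_day: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised daily max-8-h mean over a (n_days, 24) matrix.

    Returns (values, n_valid_hours, valid). A window (start hour 0..16)
    qualifies with >= min_hours_per_window present hours; the day is valid if
    any window qualifies and the day has >= min_hours_per_day present hours.
    """
    present = ~np.isnan(mat)
    n_valid = present.sum(axis=1)
    win = np.lib.stride_tricks.sliding_window_view(mat, 8, axis=1)  # (days, 17, 8)
    win_n = (~np.isnan(win)).sum(axis=2)
    win_sum = np.nansum(win, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        win_mean = np.where(win_n >= min_hours_per_window, win_sum / win_n, -np.inf)
    any_window = (win_n >= min_hours_per_window).any(axis=1)
    value = win_mean.max(axis=1)
    valid = any_window & (n_valid >= min_hours_per_day)
    value = np.where(valid, value, np.nan)
    return value, n_valid, valid


def daily_max_8h_mean(
    hours: Sequence[float],
    min_hours_per_window: int = 6,
    min_hours_per_day: int = 18,
    date: pd.Timestamp | None = None,
) -> DailyMetric:
    """Maximum over the 17 within-day 8-h window means.

    A window counts only with >= ``min_hours_per_window`` present hours; the
    day is invalid if no window qualifies or fewer than ``min_hours_per_day``
    hours are present in total.
    """
    arr = _check_day(hours)
    value, n_valid, valid = _max8h_from_matrix(
        arr[None, :], min_hours_per_window, min_hours_per_day
    )
    return DailyMetric(pd.Timestamp(date) if date is not None else pd.NaT,
                       Metric.MAX_8H_MEAN, float(value[0]), int(n_valid[0]), bool(valid[0]))


def daily_metric_series(
    series: StationSeries,
    metric: Metric | str,
    *,
    min_fraction: float = 0.75,
    min_hours: int = 18,
    min_hours_per_window: int = 6,
) -> pd.DataFrame:
    """Apply a daily metric to every day of a station series.

    Returns a DataFrame indexed by date with columns ``value``,
    ``n_valid_hours`` and ``valid``.
    """
    metric = Metric(metric)
    days, mat = series.hourly_matrix()
    if mat.size == 0:
        return pd.DataFrame(columns=["value", "n_valid_hours", "valid"],
                            index=pd.DatetimeIndex([], name="date"))
    present = ~np.isnan(mat)
    n_valid = present.sum(axis=1)
    if metric is Metric.MEAN_24H:
        valid = (n_valid / HOURS_PER_DAY >= min_fraction) & (n_valid > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(valid, np.nansum(mat, axis=1) / n_valid, np.nan)
    elif metric is Metric.MAX_1H:
        valid = (n_valid >= min_hours) & (n_valid > 0)
        value = np.where(valid, np.where(present, mat, -np.inf).max(axis=1), np.nan)
    else:
        value, n_valid, valid = _max8h_from_matrix(mat, min_hours_per_window, min_hours)
    out = pd.DataFrame(
        {"value": value, "n_valid_hours": n_valid.astype(int), "valid": valid},
        index=pd.DatetimeIndex(days, name="date"),
    )
    return out


def city_daily_series(per_station: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted daily mean over stations with a valid value that day.

    Input frames follow the ``daily_metric_series`` layout. A day is invalid
    only when no station has a valid value. ``n_valid_hours`` becomes
    ``n_stations`` (contributing stations) in the result.
    """
    if not per_station:
        raise ValueError("city_daily_series needs at least one station")
    values = []
    for i, df in enumerate(per_station):
        v = df["value"].where(df["valid"].astype(bool))
        values.append(v.rename(i))
    joined = pd.concat(values, axis=1).sort_index()
    n_stations = joined.notna().sum(axis=1)
    out = pd.DataFrame(
        {
            "value": joined.mean(axis=1, skipna=True),
            "n_stations": n_stations.astype(int),
            "valid": n_stations > 0,
        }
    )
    out.index.name = "date"
    return out


def annual_mean(daily: pd.DataFrame, period_label: str, **extra) -> AnnualExposure:
    """Mean over valid days of a daily series, with completeness bookkeeping.

    ``n_total`` is the number of days spanned by the series; raises on zero
    valid days.
    """
    valid = daily["valid"].astype(bool)
    n_total = len(daily)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(f"period {period_label!r}: no valid days to average")
    mean = float(daily.loc[valid, "value"].mean())
    return AnnualExposure(period_label=period_label, annual_mean=mean,
                          n_total=n_total, n_valid=n_valid, **extra)


def somo35(
    daily_max8h_ppb: Iterable[float],
    n_total: int,
    n_valid: int | None = None,
    threshold_ppb: float = 35.0,
) -> float:
    """SOMO35 in ppb*days: sum of max(0, C_i - 35 ppb) over valid days,
    scaled by n_total/n_valid to correct for missing days.

    ``daily_max8h_ppb`` must already be in ppb (convert first with
    :func:`o3_unit_convert`); NaN entries are dropped.
    """
    arr = np.asarray(list(daily_max8h_ppb), dtype=float)
    arr = arr[~np.isnan(arr)]
    if n_valid is None:
        n_valid = arr.size
    if n_valid < 1:
        raise ValueError("SOMO35 undefined with zero valid days")
    if arr.size != n_valid:
        raise ValueError(f"n_valid {n_valid} does not match {arr.size} non-missing days")
    uncorrected = float(np.sum(np.maximum(0.0, arr - threshold_ppb)))
    return uncorrected * n_total / n_valid


def exceedance_ratio(annual_mean_value: float, guideline: float) -> float:
    """Ratio of an annual mean to an air-quality guideline concentration."""
    if guideline <= 0:
        raise ValueError(f"guideline must be positive, got {guideline}")
    return annual_mean_value / guideline


def o3_unit_convert(
    value: float | np.ndarray,
    from_unit: str,
    to_unit: str,
    factor: float = PPB_TO_UGM3_O3,
) -> float | np.ndarray:
    """Convert ozone between ppb and ug/m3 (default 1.96 ug/m3 per ppb at 25 degC)."""
    src, dst = _canonical_unit(from_unit), _canonical_unit(to_unit)
    if src == dst:
        return value
    if src == "ppb":  # -> ug/m3
        return value * factor
    return value / factor
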