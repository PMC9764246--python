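"""Readers and writers for the pipeline's CSV dialects.

Hourly input is long-format CSV ``station,timestamp,pollutant,unit,value``
with ISO-8601 timestamps; an empty value marks a missing hour. Malformed
rows are reported with their file line number (header = line 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exposure import Pollutant, StationSeries

__all__ = ["read_hourly", "write_hourly", "write_daily_metrics", "write_annual_summary"]

_HOURLY_COLUMNS = ("station", "timestamp", "pollutant", "value")


def read_hourly(path) -> list[StationSeries]:
    """Parse an hourly long-format CSV into per-(station, pollutant) series.

    Rejects unparseable timestamps, unknown pollutants, negative values and
    duplicate (station, timestamp, pollutant) keys, naming the offending
    line. Returns one StationSeries per (station, pollutant) group, sorted by
    station then pollutant.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _HOURLY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: hourly CSV missing columns {missing}")
    if raw.empty:
        return []
    lines = raw.index.to_numpy() + 2  # header is line 1

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise ValueError(
            f"{path}: line {lines[bad[0]]}: unparseable timestamp {raw['timestamp'].iloc[bad[0]]!r}"
        )
    try:
        pollutants = raw["pollutant"].map(Pollutant.parse)
    except ValueError as exc:
        ok = raw["pollutant"].map(lambda p: _is_known(p))
        line = lines[np.flatnonzero(~ok.to_numpy())[0]]
        raise ValueError(f"{path}: line {line}: {exc}") from exc

    value = pd.to_numeric(raw["value"].mask(raw["value"] == ""), errors="coerce")
    unconvertible = np.flatnonzero((raw["value"] != "").to_numpy() & value.isna().to_numpy())
    if unconvertible.size:
        i = unconvertible[0]
        raise ValueError(f"{path}: line {lines[i]}: non-numeric value {raw['value'].iloc[i]!r}")
    neg = np.flatnonzero((value < 0).to_numpy())
    if neg.size:
        raise ValueError(
            f"{path}: line {lines[neg[0]]}: negative concentration {value.iloc[neg[0]]}"
        )

    frame = pd.DataFrame(
        {
            "station": raw["station"],
            "timestamp": ts,
            "pollutant": pollutants,
            "unit": raw["unit"] if "unit" in raw.columns else "ug/m3",
            "value": value,
            "line": lines,
        }
    )
    dup = frame.duplicated(subset=["station", "timestamp", "pollutant"], keep=False)
    if dup.any():
        pair = frame.loc[dup, "line"].iloc[:2].tolist()
        key = frame.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate ({key['station']}, {key['timestamp']}, "
            f"{key['pollutant'].value}) on lines {pair}"
        )

    out = []
    for (station, pollutant), grp in frame.groupby(["station", "pollutant"], sort=True):
        units = grp["unit"].unique()
        if len(units) > 1:
            raise ValueError(
                f"{path}: station {station} / {pollutant.value}: mixed units {sorted(units)}"
            )
        values = pd.Series(
            grp["value"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(grp["timestamp"]),
        ).sort_index()
        out.append(StationSeries(station_id=str(station), pollutant=pollutant,
                                 values=values, unit=str(units[0])))
    return out


def write_hourly(series: list[StationSeries], path) -> None:
    """Write station series back to the long-format hourly CSV dialect."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "station": s.station_id,
                    "timestamp": s.values.index.strftime("%Y-%m-%dT%H:%M:%S"),
                    "pollutant": s.pollutant.value,
                    "unit": s.unit,
                    "value": s.values.to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.6g")


def write_daily_metrics(tables: dict, path) -> None:
    """Write city daily metrics keyed by (period, pollutant, metric) to one CSV."""
    rows = []
    for (period, pollutant, metric), df in sorted(
        tables.items(), key=lambda kv: (kv[0][0], str(kv[0][1]), str(kv[0][2]))
    ):
        body = df.reset_index()
        body.insert(0, "metric", getattr(metric, "value", metric))
        body.insert(0, "pollutant", getattr(pollutant, "value", pollutant))
        body.insert(0, "period", period)
        rows.append(body)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def write_annual_summary(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g")


def _is_known(p: str) -> bool:
    try:
        Pollutant.parse(p)
        return True
    except ValueError:
        return False
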