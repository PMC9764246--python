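"""End-to-end health-impact pipeline: hourly CSV -> exposure -> risk -> burden.

The pipeline mirrors the AirQ+ workflow: per-station daily metrics with
completeness filtering, unweighted city averaging, annual means and SOMO35,
log-linear / IER relative risks above counterfactual cut-offs, attributable
proportions with CI propagation, and attributable cases against per-period
baseline rates. Every threshold and parameter of a run is captured in a run
log sufficient to re-execute it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .exposure import (
    AnnualExposure,
    Pollutant,
    PPB_TO_UGM3_O3,
    StationSeries,
    annual_mean,
    city_daily_series,
    daily_metric_series,
    exceedance_ratio,
    o3_unit_convert,
    somo35,
)
from .impact import ImpactResult, RatesTable, Totals, assess_year, round_half_up, total_over_years
from .risk import RiskSpec, default_risk_specs, load_risk_config
from .synthetic import METRIC_FOR

__all__ = ["PeriodSpec", "PipelineConfig", "ReportBundle", "run_pipeline"]

logger = logging.getLogger("airhia")


@dataclass(frozen=True)
class PeriodSpec:
    """One labelled study period: [start, end) in local time."""

    label: str
    start: str
    end: str


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serialisable to/from YAML."""

    hourly_csv: str
    rates_csv: str
    periods: list[PeriodSpec]
    risk_config: str | None = None
    out_dir: str | None = None
    guidelines: dict = field(
        default_factory=lambda: {"PM2.5": 10.0, "NO2": 40.0, "O3": 100.0}
    )
    somo35_threshold_ppb: float = 35.0
    min_fraction_24h: float = 0.75
    min_hours_daily_max: int = 18
    min_hours_per_8h_window: int = 6
    annual_completeness_flag: float = 0.75
    o3_conversion_factor: float = PPB_TO_UGM3_O3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.periods = [p if isinstance(p, PeriodSpec) else PeriodSpec(**p) for p in self.periods]
        if not self.periods:
            raise ValueError("pipeline config needs at least one period")
        for name in ("somo35_threshold_ppb", "min_fraction_24h", "o3_conversion_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for pol, g in self.guidelines.items():
            if g <= 0:
                raise ValueError(f"guideline for {pol} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: pipeline config must be a mapping")
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    annual_exposure: pd.DataFrame
    ap_table: pd.DataFrame
    cases_table: pd.DataFrame
    totals_table: pd.DataFrame
    daily_tables: dict
    results: list[ImpactResult]
    run_log: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_annual_summary(self.annual_exposure, out / "annual_exposure.csv")
        self.ap_table.to_csv(out / "attributable_proportion.csv", index=False)
        self.cases_table.to_csv(out / "attributable_cases.csv", index=False)
        self.totals_table.to_csv(out / "totals.csv", index=False)
        hio.write_daily_metrics(self.daily_tables, out / "daily_metrics.csv")
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.run_log, fh, indent=2, sort_keys=True)


def _slice_period(series: StationSeries, period: PeriodSpec) -> StationSeries | None:
    start, end = pd.Timestamp(period.start), pd.Timestamp(period.end)
    window = series.values.loc[(series.values.index >= start) & (series.values.index < end)]
    if window.empty:
        return None
    return StationSeries(series.station_id, series.pollutant, window,
                         unit=series.unit, period_label=period.label)


def compute_exposures(
    series: list[StationSeries], config: PipelineConfig
) -> tuple[list[AnnualExposure], dict]:
    """Stage 1: daily metrics, city series, annual means and SOMO35 per period."""
    exposures: list[AnnualExposure] = []
    daily_tables: dict = {}
    pollutants = sorted({s.pollutant for s in series}, key=lambda p: p.value)
    for period in config.periods:
        for pol in pollutants:
            members = [
                sliced
                for s in series
                if s.pollutant is pol and (sliced := _slice_period(s, period)) is not None
            ]
            if not members:
                continue
            metric = METRIC_FOR[pol]
            unit = members[0].unit
            per_station = [
                daily_metric_series(
                    m,
                    metric,
                    min_fraction=config.min_fraction_24h,
                    min_hours=config.min_hours_daily_max,
                    min_hours_per_window=config.min_hours_per_8h_window,
                )
                for m in members
            ]
            city = city_daily_series(per_station)
            daily_tables[(period.label, pol, metric)] = city
            if not city["valid"].any():
                logger.warning("%s/%s: no valid days, skipped", period.label, pol.value)
                continue
            exp = annual_mean(city, period.label, pollutant=pol, unit=unit)
            if pol is Pollutant.O3:
                vals = city.loc[city["valid"], "value"].to_numpy(dtype=float)
                ppb = (
                    vals
                    if unit == "ppb"
                    else np.asarray(
                        o3_unit_convert(vals, unit, "ppb", config.o3_conversion_factor)
                    )
                )
                s35 = somo35(ppb, n_total=exp.n_total, n_valid=exp.n_valid,
                             threshold_ppb=config.somo35_threshold_ppb)
                exp = AnnualExposure(exp.period_label, exp.annual_mean, exp.n_total,
                                     exp.n_valid, somo35=s35, pollutant=pol, unit=unit)
            if exp.completeness < config.annual_completeness_flag:
                logger.warning(
                    "%s/%s: completeness %.2f below %.2f",
                    period.label, pol.value, exp.completeness, config.annual_completeness_flag,
                )
            exposures.append(exp)
    return exposures, daily_tables


def _exposure_input(spec: RiskSpec, exp: AnnualExposure, daily: pd.DataFrame,
                    config: PipelineConfig):
    if spec.exposure_basis == "annual_mean":
        return exp
    values = daily.loc[daily["valid"], "value"].to_numpy(dtype=float)
    if spec.pollutant is Pollutant.O3 and exp.unit != "ppb":
        values = np.asarray(
            o3_unit_convert(values, exp.unit, "ppb", config.o3_conversion_factor)
        )
    return values


def run_pipeline(
    config: PipelineConfig,
    series: list[StationSeries] | None = None,
    rates: RatesTable | None = None,
    specs: list[RiskSpec] | None = None,
) -> ReportBundle:
    """Execute metrics -> risk -> impact and assemble the report bundle.

    Inputs are read from the configured paths unless passed in-memory.
    Output tables render AP as percent (2 decimals) and cases as whole
    persons (half-up), with full precision kept in ``results``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if series is None:
        series = hio.read_hourly(config.hourly_csv)
    if rates is None:
        rates = RatesTable.from_csv(config.rates_csv)
    if specs is None:
        specs = load_risk_config(config.risk_config) if config.risk_config else default_risk_specs()

    exposures, daily_tables = compute_exposures(series, config)
    by_key = {(e.period_label, e.pollutant): e for e in exposures}

    annual_rows = []
    for e in exposures:
        guideline = config.guidelines.get(e.pollutant.value)
        annual_rows.append(
            {
                "period": e.period_label,
                "pollutant": e.pollutant.value,
                "unit": e.unit,
                "annual_mean": round(e.annual_mean, 4),
                "somo35_ppb_days": round(e.somo35, 4) if e.somo35 is not None else "",
                "n_total_days": e.n_total,
                "n_valid_days": e.n_valid,
                "completeness": round(e.completeness, 4),
                "exceedance_ratio": (
                    round(exceedance_ratio(e.annual_mean, guideline), 4) if guideline else ""
                ),
            }
        )
    annual_table = pd.DataFrame(annual_rows)

    results: list[ImpactResult] = []
    failures: list[str] = []
    for spec in specs:
        for period in config.periods:
            key = (period.label, spec.pollutant)
            if key not in by_key:
                continue
            exp = by_key[key]
            daily = daily_tables[(period.label, spec.pollutant, METRIC_FOR[spec.pollutant])]
            try:
                exposure = _exposure_input(spec, exp, daily, config)
                results.append(assess_year(exposure, spec, rates, period_label=period.label))
            except (KeyError, ValueError) as exc:
                failures.append(
                    f"impact stage, period {period.label}, outcome {spec.outcome}: {exc}"
                )
    if failures:
        raise RuntimeError("; ".join(failures))

    ap_rows, case_rows = [], []
    for r in results:
        base = {
            "period": r.period_label,
            "pollutant": r.pollutant.value,
            "outcome": r.outcome,
            "exposure_basis": r.exposure_basis,
        }
        ap_rows.append(
            base
            | {
                "ap_percent": f"{100 * r.ap_central:.2f}",
                "ap_low_percent": f"{100 * r.ap_low:.2f}",
                "ap_high_percent": f"{100 * r.ap_high:.2f}",
            }
        )
        case_rows.append(
            base
            | {
                "cases": round_half_up(r.cases_central),
                "cases_low": round_half_up(r.cases_low),
                "cases_high": round_half_up(r.cases_high),
                "expected_cases": round_half_up(r.expected_cases),
            }
        )
    ap_table = pd.DataFrame(ap_rows)
    cases_table = pd.DataFrame(case_rows)

    totals_rows = []
    for (pol, outcome, basis) in sorted(
        {(r.pollutant, r.outcome, r.exposure_basis) for r in results},
        key=lambda k: (k[0].value, k[1], k[2]),
    ):
        group = [
            r for r in results
            if r.pollutant is pol and r.outcome == outcome and r.exposure_basis == basis
        ]
        t: Totals = total_over_years(group)
        totals_rows.append(
            {
                "pollutant": pol.value,
                "outcome": outcome,
                "exposure_basis": basis,
                "n_periods": t.n_periods,
                "cases_total": t.cases_central_rounded,
                "cases_total_unrounded": round(t.cases_central, 4),
                "cases_total_low": round(t.cases_low, 4),
                "cases_total_high": round(t.cases_high, 4),
            }
        )
    totals_table = pd.DataFrame(totals_rows)

    run_log = {
        "config": config.to_dict(),
        "n_station_series": len(series),
        "n_rates_rows": len(rates),
        "risk_specs": [
            {
                "pollutant": s.pollutant.value,
                "outcome": s.outcome,
                "form": s.form,
                "rr": [s.rr_low, s.rr_central, s.rr_high],
                "increment": s.increment,
                "cutoff": s.cutoff,
                "exposure_basis": s.exposure_basis,
                "ier": dataclasses.asdict(s.ier) if s.ier else None,
            }
            for s in specs
        ],
    }
    bundle = ReportBundle(
        annual_exposure=annual_table,
        ap_table=ap_table,
        cases_table=cases_table,
        totals_table=totals_table,
        daily_tables=daily_tables,
        results=results,
        run_log=run_log,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
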