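"""Attributable-burden arithmetic.

Combines an attributable proportion (AP) with a baseline incidence B
(cases per 100,000 persons per period) and an at-risk population P into
attributable cases::

    AC = AP * B * P / 100_000

Values stay real-valued internally; rounding to whole persons (half-up, the
convention of rendered burden tables) happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .exposure import AnnualExposure, Pollutant
from .risk import RiskSpec, ap_interval

__all__ = [
    "RatesTable",
    "ImpactResult",
    "Totals",
    "attributable_cases",
    "assess_year",
    "total_over_years",
    "round_half_up",
]

PER = 100_000.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero upward (0.5 -> 1)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


class RatesTable:
    """Per-period at-risk population and baseline incidence for each outcome.

    Wraps a DataFrame with columns ``period``, ``outcome``, ``population``,
    ``baseline_incidence_per_100k``; one row per (period, outcome).
    """

    COLUMNS = ("period", "outcome", "population", "baseline_incidence_per_100k")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"rates table missing columns {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        dup = frame.duplicated(subset=["period", "outcome"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValueError(
                f"duplicate rates row for period={row['period']!r} outcome={row['outcome']!r}"
            )
        if (frame["population"] <= 0).any():
            bad = frame[frame["population"] <= 0].iloc[0]
            raise ValueError(f"non-positive population in period {bad['period']!r}")
        if (frame["baseline_incidence_per_100k"] < 0).any():
            bad = frame[frame["baseline_incidence_per_100k"] < 0].iloc[0]
            raise ValueError(f"negative incidence in period {bad['period']!r}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "RatesTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def get(self, period: str, outcome: str) -> tuple[float, float]:
        """Return (population, baseline incidence per 100k) for one cell."""
        sel = self.frame[(self.frame["period"] == period) & (self.frame["outcome"] == outcome)]
        if sel.empty:
            raise KeyError(f"no rates row for period={period!r} outcome={outcome!r}")
        row = sel.iloc[0]
        return float(row["population"]), float(row["baseline_incidence_per_100k"])

    def periods(self) -> list[str]:
        return list(dict.fromkeys(self.frame["period"]))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ImpactResult:
    """AP and attributable cases (central + CI bounds) for one cell."""

    period_label: str
    pollutant: Pollutant
    outcome: str
    exposure_basis: str
    ap_low: float
    ap_central: float
    ap_high: float
    cases_low: float
    cases_central: float
    cases_high: float
    expected_cases: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pollutant", Pollutant.parse(self.pollutant))
        if not (0 <= self.cases_low <= self.cases_central <= self.cases_high):
            raise ValueError(
                f"{self.period_label}/{self.outcome}: case bounds out of order "
                f"({self.cases_low}, {self.cases_central}, {self.cases_high})"
            )


def attributable_cases(ap: float, incidence_per_100k: float, population: float) -> float:
    """Excess cases: AP x B x P / 100,000 (real-valued)."""
    if not 0 <= ap < 1:
        raise ValueError(f"attributable proportion must lie in [0, 1), got {ap}")
    if incidence_per_100k < 0:
        raise ValueError(f"baseline incidence must be >= 0, got {incidence_per_100k}")
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    return ap * incidence_per_100k * population / PER


def assess_year(
    exposure,
    spec: RiskSpec,
    rates: RatesTable,
    period_label: str | None = None,
) -> ImpactResult:
    """Evaluate one (period, pollutant, outcome) cell.

    ``exposure`` is an :class:`AnnualExposure` or a daily series, matching the
    spec's ``exposure_basis``; rates are looked up by (period, outcome).
    Exposure entirely at or below the cut-off yields an all-zero result.
    """
    if period_label is None:
        if not isinstance(exposure, AnnualExposure):
            raise ValueError("period_label required when exposure is not an AnnualExposure")
        period_label = exposure.period_label
    population, incidence = rates.get(period_label, spec.outcome)
    ap_low, ap_central, ap_high = ap_interval(spec, exposure)
    expected = incidence * population / PER
    return ImpactResult(
        period_label=period_label,
        pollutant=spec.pollutant,
        outcome=spec.outcome,
        exposure_basis=spec.exposure_basis,
        ap_low=ap_low,
        ap_central=ap_central,
        ap_high=ap_high,
        cases_low=attributable_cases(ap_low, incidence, population),
        cases_central=attributable_cases(ap_central, incidence, population),
        cases_high=attributable_cases(ap_high, incidence, population),
        expected_cases=expected,
    )


@dataclass(frozen=True)
class Totals:
    """Multi-year totals for one pollutant/outcome/basis triple."""

    pollutant: Pollutant
    outcome: str
    exposure_basis: str
    n_periods: int
    cases_low: float
    cases_central: float
    cases_high: float

    @property
    def cases_central_rounded(self) -> int:
        return round_half_up(self.cases_central)


def total_over_years(results: Sequence[ImpactResult]) -> Totals:
    """Sum central cases (and bounds) over the years of one pollutant/outcome.

    Raises on mixed pollutant, outcome or exposure basis (short- and
    long-term burdens must not be pooled); an empty list totals to zero.
    """
    results = list(results)
    if not results:
        return Totals(Pollutant.PM25, "", "", 0, 0.0, 0.0, 0.0)
    keys = {(r.pollutant, r.outcome, r.exposure_basis) for r in results}
    if len(keys) > 1:
        raise ValueError(f"mixed pollutant/outcome/basis in totals: {sorted(keys)}")
    pollutant, outcome, basis = next(iter(keys))
    return Totals(
        pollutant=pollutant,
        outcome=outcome,
        exposure_basis=basis,
        n_periods=len(results),
        cases_low=float(sum(r.cases_low for r in results)),
        cases_central=float(sum(r.cases_central for r in results)),
        cases_high=float(sum(r.cases_high for r in results)),
    )
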