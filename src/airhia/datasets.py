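"""Bundled reference dataset: a published seven-period (2012-2019) urban
health-impact assessment of PM2.5, NO2 and O3 for a mid-sized Iranian city,
as rendered by the AirQ+ workflow.

The tables carry, per period:

* at-risk populations and baseline incidences (per 100,000) for each outcome;
* city annual-mean concentrations (ug/m3);
* attributable proportions (%) and attributable cases for short-term
  (daily-distribution) and long-term (annual-mean) exposure.

These are report-level figures, useful as worked inputs for the totals
arithmetic and the guideline-exceedance computation; the underlying hourly
concentration records were never published, so per-cell AP values cannot be
re-derived from them.
"""

from __future__ import annotations

import pandas as pd

from .exposure import Pollutant
from .impact import ImpactResult, RatesTable

__all__ = [
    "PERIODS",
    "WHO_ANNUAL_GUIDELINES",
    "load_rates",
    "annual_means",
    "reported_attributable_proportions",
    "reported_attributable_cases",
    "reported_impacts",
]

PERIODS = (
    "2012-2013", "2013-2014", "2014-2015", "2015-2016",
    "2016-2017", "2017-2018", "2018-2019",
)

WHO_ANNUAL_GUIDELINES = {Pollutant.PM25: 10.0, Pollutant.NO2: 40.0, Pollutant.O3: 100.0}

# (pollutant, outcome) -> per-period at-risk population
_POPULATION = {
    ("PM2.5", "natural_mortality"): (55200, 72425, 85710, 104642, 115942, 143830, 178730),
    ("PM2.5", "alri"): (4570, 6991, 9351, 12642, 16835, 20876, 25885),
    ("PM2.5", "copd"): (55200, 72425, 85710, 104642, 115942, 143830, 178730),
    ("PM2.5", "lung_cancer"): (55200, 72425, 85710, 104642, 115942, 143830, 178730),
    ("PM2.5", "ihd"): (60800, 76425, 89710, 104642, 120942, 139830, 174350),
    ("PM2.5", "stroke"): (60800, 76425, 89710, 106642, 120942, 139830, 174350),
    ("NO2", "total_mortality"): (55200, 72425, 85710, 104642, 115942, 143830, 178730),
    ("O3", "respiratory_mortality"): (55200, 72425, 85710, 104642, 115942, 143830, 178730),
}

# (pollutant, outcome) -> baseline incidence per 100,000 per period.
# The first two respiratory entries are a best-effort split of a run-together
# figure in the printed table; every O3 burden in the dataset is zero, so the
# split does not propagate into any result.
_INCIDENCE = {
    ("PM2.5", "natural_mortality"): (1091, 1024, 1001, 987, 1010, 980, 995),
    ("PM2.5", "alri"): (10, 10, 12, 11, 12, 10, 13),
    ("PM2.5", "copd"): (9, 4.1, 5.9, 5.5, 4.1, 4.8, 4.1),
    ("PM2.5", "lung_cancer"): (12, 11.7, 9.5, 8, 8.8, 12.1, 16.1),
    ("PM2.5", "ihd"): (165, 161, 115, 135, 104, 118.6, 221),
    ("PM2.5", "stroke"): (62, 60, 85, 99, 113, 120, 121),
    ("NO2", "total_mortality"): (1081, 1029, 1011, 975, 1020, 985, 997),
    ("O3", "respiratory_mortality"): (6, 8.3, 11.1, 12.1, 9.5, 11.8, 10.2),
}

# city annual means, ug/m3
_ANNUAL_MEANS = {
    "PM2.5": (48.8, 36.37, 58.6, 29.5, 41.2, 24.5, 19.7),
    "NO2": (36.9, 35.50, 34.50, 59.42, 48.6, 44.7, 32.7),
    "O3": (15.6, 17.56, 14.22, 12.23, 11.85, 14.75, 15.3),
}

_ZEROS = (0.0,) * 7

# attributable proportion (%), short-term (daily distribution) exposure
_AP_SHORT = {
    ("PM2.5", "natural_mortality"): (2.87, 1.38, 4.02, 0.55, 1.96, 0, 0),
    ("NO2", "total_mortality"): (0.72, 0.69, 0.66, 1.32, 1.04, 0.93, 0.61),
    ("O3", "respiratory_mortality"): _ZEROS,
}

# attributable cases, short-term exposure
_CASES_SHORT = {
    ("PM2.5", "natural_mortality"): (16, 10, 35, 6, 28, 0, 0),
    ("NO2", "total_mortality"): (6, 7, 0, 22, 23, 25, 17),
    ("O3", "respiratory_mortality"): _ZEROS,
}

# attributable proportion (%), long-term (annual mean) exposure
_AP_LONG = {
    ("PM2.5", "natural_mortality"): (20.82, 14.67, 25.35, 11.07, 17.11, 8.35, 5.67),
    ("PM2.5", "alri"): (24.62, 19.23, 28.09, 28.97, 21.05, 21.5, 9.05),
    ("PM2.5", "copd"): (20.41, 16.04, 23.27, 13.11, 17.86, 10.64, 7.86),
    ("PM2.5", "lung_cancer"): (18.01, 13.65, 20.97, 10.85, 15.44, 8.57, 6.14),
    ("PM2.5", "ihd"): (21.40, 17.61, 23.85, 14.85, 19.25, 12.39, 9.48),
    ("PM2.5", "stroke"): (19.34, 15.47, 21.82, 12.82, 17.09, 10.52, 7.9),
    ("NO2", "total_mortality"): (10.25, 9.74, 9.38, 18.01, 14.33, 13.01, 8.72),
    ("O3", "respiratory_mortality"): _ZEROS,
}

# attributable cases, long-term exposure
_CASES_LONG = {
    ("PM2.5", "natural_mortality"): (117, 109, 217, 117, 200, 118, 101),
    ("PM2.5", "alri"): _ZEROS,
    ("PM2.5", "copd"): (1, 1, 1, 1, 1, 1, 1),
    ("PM2.5", "lung_cancer"): (1, 1, 1, 1, 1, 1, 1),
    ("PM2.5", "ihd"): (23, 22, 25, 21, 24, 22, 39),
    ("PM2.5", "stroke"): (7, 8, 17, 13, 23, 19, 18),
    ("NO2", "total_mortality"): (86, 95, 124, 303, 322, 351, 250),
    ("O3", "respiratory_mortality"): _ZEROS,
}


def load_rates() -> RatesTable:
    """Population and baseline-incidence rows for every period/outcome."""
    rows = []
    for (pollutant, outcome), pops in _POPULATION.items():
        incs = _INCIDENCE[(pollutant, outcome)]
        for period, pop, inc in zip(PERIODS, pops, incs):
            rows.append((period, outcome, pop, inc))
    frame = pd.DataFrame(rows, columns=list(RatesTable.COLUMNS))
    return RatesTable(frame)


def annual_means(pollutant) -> pd.Series:
    """City annual-mean concentrations (ug/m3) indexed by period label."""
    key = Pollutant.parse(pollutant).value
    return pd.Series(_ANNUAL_MEANS[key], index=list(PERIODS), name=key)


def _table(source: dict, pollutant, outcome: str) -> pd.Series:
    key = (Pollutant.parse(pollutant).value, outcome)
    if key not in source:
        raise KeyError(f"no reported values for {key}")
    return pd.Series(source[key], index=list(PERIODS), dtype=float)


def reported_attributable_proportions(pollutant, outcome: str, term: str) -> pd.Series:
    """Reported AP (%) per period; ``term`` is 'short' or 'long'."""
    src = {"short": _AP_SHORT, "long": _AP_LONG}[term]
    return _table(src, pollutant, outcome)


def reported_attributable_cases(pollutant, outcome: str, term: str) -> pd.Series:
    """Reported attributable cases per period; ``term`` is 'short' or 'long'."""
    src = {"short": _CASES_SHORT, "long": _CASES_LONG}[term]
    return _table(src, pollutant, outcome)


def reported_impacts(pollutant, outcome: str, term: str) -> list[ImpactResult]:
    """The reported per-period AP/cases as ImpactResult records.

    Confidence bounds were not published per cell, so low = central = high.
    """
    pollutant = Pollutant.parse(pollutant)
    ap = reported_attributable_proportions(pollutant, outcome, term) / 100.0
    cases = reported_attributable_cases(pollutant, outcome, term)
    rates = load_rates()
    out = []
    basis = "daily_series" if term == "short" else "annual_mean"
    for period in PERIODS:
        population, incidence = rates.get(period, outcome)
        out.append(
            ImpactResult(
                period_label=period,
                pollutant=pollutant,
                outcome=outcome,
                exposure_basis=basis,
                ap_low=float(ap[period]), ap_central=float(ap[period]),
                ap_high=float(ap[period]),
                cases_low=float(cases[period]), cases_central=float(cases[period]),
                cases_high=float(cases[period]),
                expected_cases=incidence * population / 100_000.0,
            )
        )
    return out
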