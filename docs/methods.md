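# Methods

## Scope and model

`airhia` implements the computation chain of an AirQ-family health impact
assessment: hourly station concentrations → validity-filtered daily exposure
metrics → city-wide daily series → annual summaries (mean, SOMO35) →
relative risks from concentration–response functions → attributable
proportions → attributable cases against per-period baseline rates. The
method is deliberately an aggregation-and-arithmetic pipeline, not a fitted
statistical model: nothing is estimated from the health data, and all
uncertainty enters through the published confidence interval of the relative
risk.

Assumptions inherited from that framework:

- the monitoring network's city average represents population exposure
  (no spatial weighting; stations enter an unweighted mean);
- risk transfers from the meta-analytic studies behind the RR values
  (log-linear in concentration above a counterfactual cut-off);
- exposures at or below the cut-off carry no excess risk (RR truncated at 1,
  never protective);
- baseline incidence and population are exact inputs; only the RR interval
  is propagated (no Monte Carlo over B or P, no age standardisation, no
  life-table years-of-life-lost).

## Exposure metrics and completeness rules

Per-pollutant daily metrics follow monitoring convention: PM2.5 uses the
24-h mean, NO2 the daily 1-h maximum, O3 the daily maximum 8-h running mean.
Completeness rules, all configurable:

| rule | default | rationale |
| --- | --- | --- |
| 24-h mean valid | ≥ 75 % of hours present | the 75 %-completeness convention of multi-city air-quality protocols |
| 1-h max valid | ≥ 18 h present | same 0.75 fraction expressed in hours |
| 8-h window counts | ≥ 6 of 8 hours present | 75 % at window level |
| max-8-h day valid | ≥ 1 qualifying window and ≥ 18 h in the day | avoids a day being carried by a sparse window |
| annual completeness | flagged (not rejected) below 75 % valid days | the exclusion rule operates at station selection, not period level |

8-h windows are the 17 within-day windows starting at hours 0–16; windows do
not cross midnight. Days are local calendar days. Missing hours are excluded,
never imputed. A day invalid for a station simply drops that station from the
city average for that day; the day is invalid city-wide only when no station
qualifies.

SOMO35 is computed from the valid daily max-8-h values in ppb,
`Σ max(0, C_i − 35)`, rescaled by `N_total/N_valid` so that missing days do
not deflate the annual sum; the correction factor is ≥ 1 with equality only
for complete years. Ozone units convert at 1.96 µg/m³ per ppb (25 °C, 1 atm),
configurable for other temperature/pressure conventions.

## Concentration–response and attributable burden

β is derived from a published RR per increment as `ln(RR)/increment`
(increment 10 µg/m³ by default). The default configuration applies RR 1.065
(1.04–1.083) to total/natural mortality for PM2.5 and NO2 on both the
annual-mean (long-term) and daily-distribution (short-term) bases, with
cut-offs at the WHO annual guidelines (10 and 40 µg/m³), and RR 1.014
(1.005–1.024) per 10 ppb to O3 respiratory mortality on the SOMO35 basis
with the 35 ppb threshold as cut-off.

For a daily series the attributable proportion is the RR-weighted day sum
`Σ(RR_d − 1)/Σ RR_d`, which reduces to `(RR−1)/RR` for a constant series.
For the SOMO35 basis the same day-sum machinery is applied to the daily
max-8-h series above 35 ppb; when only the annual SOMO35 scalar is
available, the mean daily exceedance `SOMO35/N_total` is pushed through the
log-linear form instead. How a SOMO35 value maps to an RR argument is a
genuinely open design point in this assessment family; both routes agree on
the one behaviour that is externally pinned down — SOMO35 = 0 implies a
zero attributable burden — and the day-sum route is preferred because it
uses the full distribution.

The IER curve `1 + α(1 − e^{−γ(z−z_cf)^δ})` is implemented with
config-supplied parameters. The shipped values are illustrative placeholders
with GBD-style magnitudes: results computed from them exercise the pathway
but are not reproductions of any published cause-specific burden, and real
analyses should supply fitted parameter sets via the risk-configuration
file. The published CI machinery applies to the log-linear specs; IER specs
evaluate at their central curve for all three bounds.

Attributable cases are `AP × B × P / 100,000`, kept real-valued internally;
rendered tables round AP to 2 decimal percent and cases half-up to whole
persons, matching burden-table convention. Multi-year totals sum unrounded
central values (and bounds) and round once at the end; totals refuse to pool
across pollutant, outcome or exposure basis.

## Bundled reference tables

`airhia.datasets` carries the report-level tables of a published seven-period
(2012–2019) assessment for a mid-sized city: populations, baseline
incidences, annual means, and per-year AP/cases for short- and long-term
exposure. Two caveats are inherent to such report-level data. First, the
underlying daily distributions and the exact β/X0 used are not recoverable
from the report, so per-cell AP values cannot be re-derived — the tables
serve totals arithmetic and the exceedance computation, and per-cell values
are only checked qualitatively. Second, one incidence row (O3 respiratory)
prints seven values run together; the bundled split is a best effort and is
inert because every O3 burden in the dataset is exactly zero.

## Synthetic data generator

The generator emulates the study design the reference tables come from:
3 stations, 7 year-long periods (365 days from 1 March), hourly sampling.
The station signal is

```
c_s(t) = max(0, base · (1 + A_y sin(2πt/8766)) · (1 + A_d sin(2πh/24)) · ε(t) + offset_s)
```

with mean-one lognormal noise ε (log-sd σ) and MCAR missing hours
(optionally consecutive-hour outage bursts). Mean-one noise — rather than
median-one — is chosen so that the expectation of the noisy signal equals
the deterministic signal and "generator truth" is well defined as the
noise-free pipeline output. Defaults (baselines 40 / 42 / 15 µg/m³ for
PM2.5 / NO2 / O3, seasonal amplitude 0.3, diurnal 0.2, σ = 0.1, 5 % missing,
small additive station offsets) reproduce the concentration regime of the
bundled tables: PM2.5 several-fold above its guideline, NO2 near its
guideline, and O3 low enough that the daily max-8-h mean never reaches
35 ppb, hence SOMO35 = 0 in every period. Lognormal multiplicative noise
keeps concentrations positive and right-skewed, the stylised shape of
ambient series.

What the generator does **not** emulate: meteorology-driven covariance
between pollutants, temporally autocorrelated noise (beyond the burst
option), spatial structure beyond constant offsets, instrument drift, and
informative missingness. Passing the recovery experiment therefore shows the
pipeline's arithmetic and filtering are correct under realistic magnitudes —
not that the assessment model is unbiased for any particular real network.

Rates tables are generated with geometrically growing populations (12 % per
period), an under-5 population slice for ALRI, and per-outcome incidence
ranges matching the order of magnitude of the bundled tables.

## Recovery experiment

`recovery_experiment` runs the full pipeline on one generated realisation
and checks, per period and pollutant, that the estimated annual mean falls
within `n_se` (default 3) standard errors — SE estimated from the realised
daily values — of the *expected value of the estimator*, and that each AP
falls inside the band obtained by shifting the estimated exposure to the
edges of that annual-mean band and re-running the response function.

The expected value is the noise-free truth adjusted for metric noise bias:
the 24-h mean of mean-one noise is unbiased, but max-type metrics (1-h max,
max 8-h mean) are upward-biased under noise because the expectation of a
maximum exceeds the maximum of expectations. The bias factor is
scale-free for a multiplicative signal and is estimated once per pollutant
by Monte Carlo (4000 replicate days of the configured diurnal profile,
noise, and missingness, with the same validity conditioning as the real
metric); additive station offsets commute with every metric and are handled
exactly. Without this adjustment the 3-SE criterion would be structurally
unmeetable for NO2 at σ = 0.1 (the bias is ~8 %, an order of magnitude
larger than the standard error) for reasons that have nothing to do with
implementation correctness.

## Numerical and design choices

- Rounding: half-up via `decimal` (banker's rounding would under-count the
  0.5 ties burden tables conventionally round up).
- Zero valid days in a period: an error, not a silent NaN; zero valid
  stations on a day: the day is invalid and excluded from the annual mean.
- Duplicate (station, timestamp, pollutant) rows, negative concentrations,
  non-hourly timestamps and unknown pollutants are rejected at parse time
  with the offending line or slot named.
- Period labels are opaque join keys between exposure and rates; calendars
  are only used to slice hourly data into periods.
- Determinism: one `numpy` Generator seeded from the config seed drives the
  hourly stream; rates and the bias Monte Carlo use child seeds
  (`SeedSequence([seed, k])`) so adding stations or periods does not
  reshuffle unrelated draws between runs of the same config.
- Report sizes: the default generator produces 3 stations × 3 pollutants ×
  7 × 8760 hours (~550 k values), which the vectorised daily aggregation
  processes in about a second; tests use 1–2 period configurations where
  full scale adds nothing.

## Known limitations

- Short- and long-term estimates from the same RR are not additive in any
  strict epidemiological sense; the package reports them separately and
  never pools bases in totals, but the grand "short + long" figure some
  reports quote should be interpreted with that caveat.
- The IER placeholders are not fitted parameters (see above).
- CI propagation treats the RR interval as the only uncertainty source;
  sampling error in exposure, incidence and population is out of scope.
- The mean-exceedance fallback for a scalar SOMO35 underestimates AP
  relative to the day-sum route when exceedances are concentrated in few
  days (Jensen), which is why the daily series is preferred whenever
  available.
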