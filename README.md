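# airhia

Health impact assessment of ambient air pollution: from hourly multi-station
monitoring data to attributable mortality.

`airhia` is for environmental-health analysts who have hourly PM2.5, NO2 and
O3 concentrations from a city's monitoring network, per-year at-risk
populations and baseline incidence rates, and want the burden estimates an
AirQ-family assessment produces — validity-filtered daily exposure metrics,
annual means and SOMO35, concentration–response relative risks, attributable
proportions with confidence bounds, and attributable cases per
year/pollutant/outcome — as a scripted, tested, reproducible pipeline instead
of a spreadsheet-and-GUI workflow.

## The model

**Exposure metrics.** Hourly station series are aggregated to daily metrics
with completeness filtering: the 24-h mean (PM2.5; valid when ≥ 75 % of hours
are present), the daily 1-h maximum (NO2; ≥ 18 h), and the daily maximum
8-h running mean (O3; 17 within-day windows, ≥ 6 valid hours per window).
Stations are averaged unweighted into a city-wide daily series. Ozone
exposure is summarised by

```
SOMO35 = [ Σ_i max(0, C_i − 35 ppb) ] · N_total / N_valid
```

the annual sum of daily max-8-h exceedances over 35 ppb, rescaled for missing
days.

**Concentration–response.** Relative risk at exposure X versus a
counterfactual cut-off X0 (the WHO annual guideline by default: 10 / 40 /
100 µg/m³ for PM2.5 / NO2 / O3) follows the log-linear form

```
RR(X) = exp(β · max(0, X − X0)),   β = ln(RR_per_increment) / increment
```

with published increments of 10 µg/m³ (e.g. RR 1.065, 95 % CI 1.04–1.083 per
10 µg/m³ for total mortality; 1.014, 1.005–1.024 for respiratory mortality).
Cause-specific PM2.5 mortality (IHD, stroke, COPD, lung cancer, ALRI) can use
the integrated exposure–response (IER) curve
`RR(z) = 1 + α(1 − e^{−γ(z−z_cf)^δ})`.

**Attributable burden.** For a uniformly exposed population the attributable
proportion is the population attributable fraction `AP = (RR − 1)/RR`; for a
daily exposure distribution it is the RR-weighted day sum
`Σ_d (RR_d − 1) / Σ_d RR_d`. Attributable cases combine AP with the baseline
incidence B (per 100,000 per period) and at-risk population P:

```
AC = AP × B × P / 100,000
```

Confidence bounds on published RRs propagate through the whole chain
(every step is monotone in RR, so interval ordering is preserved).

## Worked example

Simulate a three-station, seven-period network (seasonal/diurnal structure,
lognormal noise, 5 % missing hours), then run the full assessment:

```
$ airhia simulate --seed 3 --out-dir sim
wrote 63 station series, 56 rates rows to sim

$ airhia hia --config sim/pipeline.yaml
pollutant               outcome exposure_basis  n_periods  cases_total  cases_total_unrounded  cases_total_low  cases_total_high
      NO2       total_mortality    annual_mean          7          569               569.3281         361.5110          711.1222
      NO2       total_mortality   daily_series          7          587               586.8718         369.2336          737.5962
       O3 respiratory_mortality         somo35          7            0                 0.0000           0.0000            0.0000
    PM2.5                  alri    annual_mean          7            2                 2.0164           2.0164            2.0164
    PM2.5                  copd    annual_mean          7            8                 8.4489           8.4489            8.4489
    PM2.5                   ihd    annual_mean          7          275               274.7668         274.7668          274.7668
    PM2.5           lung_cancer    annual_mean          7           23                22.9161          22.9161           22.9161
    PM2.5     natural_mortality    annual_mean          7          977               976.7474         629.8258         1207.0579
    PM2.5     natural_mortality   daily_series          7          983               983.4943         632.6381         1217.3368
    PM2.5                stroke    annual_mean          7          111               111.4010         111.4010          111.4010
report written to sim/report
```

Each row is a seven-year total of attributable deaths for one
pollutant/outcome pair on one exposure basis (`annual_mean` = long-term,
`daily_series` = short-term distribution, `somo35` = ozone exceedance sum).
`cases_total_low/high` carry the RR confidence interval through the chain;
the IER rows have no published CI and collapse to the central curve. The O3
row is exactly zero because the simulated daily max-8-h ozone never exceeds
35 ppb, so SOMO35 — and hence the attributable respiratory burden — is zero.
Per-period tables (annual exposure, AP in percent, cases, daily metrics) and
a `run_log.json` capturing every threshold land in `sim/report/`.

The package also bundles the report-level tables of a published seven-period
urban assessment, usable directly with the same machinery:

```python
from airhia import datasets, total_over_years, exceedance_ratio

short = datasets.reported_impacts("NO2", "total_mortality", "short")
long = datasets.reported_impacts("NO2", "total_mortality", "long")
print("NO2 short-term deaths:", total_over_years(short).cases_central_rounded)
print("NO2 long-term deaths: ", total_over_years(long).cases_central_rounded)
mean = float(datasets.annual_means("PM2.5")["2015-2016"])
print("PM2.5 2015-2016 exceedance:", exceedance_ratio(mean, 10.0))
```

```
NO2 short-term deaths: 100
NO2 long-term deaths:  1531
PM2.5 2015-2016 exceedance: 2.95
```

The exceedance ratio says the 2015–2016 PM2.5 annual mean (29.5 µg/m³) was
2.95 times the 10 µg/m³ WHO guideline.

## Layout

- `airhia.exposure` — station series, daily metrics, city averaging, annual
  means, SOMO35, unit conversion.
- `airhia.risk` — RR forms (log-linear, IER), AP algebra, CI propagation,
  risk-configuration files.
- `airhia.impact` — rates tables, attributable cases, per-year assessment,
  multi-year totals.
- `airhia.synthetic` — seed-reproducible generator with ground truth and the
  recovery experiment.
- `airhia.io` / `airhia.pipeline` / `airhia.cli` — CSV dialects, the
  orchestrated pipeline, and the `airhia` command
  (`simulate | metrics | hia | report`).
- `airhia.datasets` — the bundled published tables.

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
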