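"""Concentration-response machinery.

Relative risk (RR) of a health outcome at exposure X relative to a
counterfactual concentration X0:

* log-linear form: ``RR(X) = exp(beta * max(0, X - X0))`` with
  ``beta = ln(RR_per_increment) / increment`` (published RRs are typically
  per 10 ug/m3);
* integrated exposure-response (IER) form:
  ``RR(z) = 1 + alpha * (1 - exp(-gamma * (z - zcf)**delta))`` for z > zcf,
  else 1 — the bounded-saturation curve used for PM2.5 cause-specific
  mortality (IHD, stroke, COPD, lung cancer, ALRI).

Attributable proportion (AP) for a uniformly exposed population is the
population attributable fraction ``(RR - 1) / RR``; for a daily exposure
distribution it is the RR-weighted day-sum
``sum_d (RR_d - 1) / sum_d RR_d``. Exposures below the counterfactual
cut-off contribute RR = 1 exactly (truncation, never a protective RR < 1).

Confidence intervals on published RRs are propagated by evaluating the whole
chain at the low/central/high RR; every transformation involved is monotone
in RR, so interval ordering is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .exposure import AnnualExposure, Pollutant

__all__ = [
    "RiskSpec",
    "IERParams",
    "beta_from_rr",
    "rr_loglinear",
    "rr_ier",
    "ap_from_rr",
    "ap_short_term",
    "ap_interval",
    "load_risk_config",
    "default_risk_specs",
]

_FORMS = ("loglinear", "ier")
_BASES = ("annual_mean", "daily_series", "somo35")


@dataclass(frozen=True)
class IERParams:
    """Shape parameters of the integrated exposure-response curve."""

    alpha: float
    gamma: float
    delta: float
    zcf: float

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"IER parameter {name} must be positive, got {getattr(self, name)}")
        if self.zcf < 0:
            raise ValueError(f"IER counterfactual zcf must be >= 0, got {self.zcf}")


@dataclass(frozen=True)
class RiskSpec:
    """A concentration-response definition for one pollutant/outcome pair.

    ``rr_central`` (with ``rr_low``/``rr_high`` confidence bounds) is the
    relative risk per ``increment`` of concentration; ``cutoff`` is the
    counterfactual concentration X0 below which no excess risk is attributed.
    ``exposure_basis`` selects what the RR is applied to: the annual mean
    (long-term), the daily metric distribution (short-term), or the daily
    max-8-h ozone series above 35 ppb (SOMO35).
    """

    pollutant: Pollutant
    outcome: str
    form: str = "loglinear"
    rr_central: float = 1.0
    rr_low: float = 1.0
    rr_high: float = 1.0
    increment: float = 10.0
    cutoff: float = 0.0
    exposure_basis: str = "annual_mean"
    ier: IERParams | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pollutant", Pollutant.parse(self.pollutant))
        if self.form not in _FORMS:
            raise ValueError(f"unknown form {self.form!r}, expected one of {_FORMS}")
        if self.exposure_basis not in _BASES:
            raise ValueError(
                f"unknown exposure_basis {self.exposure_basis!r}, expected one of {_BASES}"
            )
        if self.form == "loglinear":
            if not (0 < self.rr_low <= self.rr_central <= self.rr_high):
                raise ValueError(
                    f"{self.outcome}: RR bounds must satisfy 0 < low <= central <= high, "
                    f"got ({self.rr_low}, {self.rr_central}, {self.rr_high})"
                )
            if self.increment <= 0:
                raise ValueError(f"{self.outcome}: increment must be positive")
        if self.form == "ier" and self.ier is None:
            raise ValueError(f"{self.outcome}: IER form requires ier parameters")
        if self.cutoff < 0:
            raise ValueError(f"{self.outcome}: cutoff must be >= 0")

    def beta(self, which: str = "central") -> float:
        rr = {"low": self.rr_low, "central": self.rr_central, "high": self.rr_high}[which]
        return beta_from_rr(rr, self.increment)


def beta_from_rr(rr: float, increment: float = 10.0) -> float:
    """Log-relative-risk per unit concentration: ln(rr) / increment."""
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if increment <= 0:
        raise ValueError(f"increment must be positive, got {increment}")
    return math.log(rr) / increment


def rr_loglinear(x, x0: float, beta: float):
    """``exp(beta * max(0, x - x0))``; exposures at or below the cut-off give exactly 1."""
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    excess = np.maximum(0.0, np.asarray(x, dtype=float) - x0)
    out = np.exp(beta * excess)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def rr_ier(z, params: IERParams):
    """Integrated exposure-response RR, continuous at zcf and bounded by 1 + alpha."""
    excess = np.maximum(0.0, np.asarray(z, dtype=float) - params.zcf)
    out = 1.0 + params.alpha * (1.0 - np.exp(-params.gamma * excess ** params.delta))
    return float(out) if np.isscalar(z) or np.ndim(z) == 0 else out


def ap_from_rr(rr: float) -> float:
    """Population attributable fraction (RR - 1)/RR for a uniformly exposed population."""
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(rr_arr < 1):
        raise ValueError(f"protective RR < 1 out of scope, got {float(np.min(rr_arr))}")
    out = (rr_arr - 1.0) / rr_arr
    return float(out) if np.ndim(rr) == 0 else out


def ap_short_term(daily_values: Iterable[float], x0: float, beta: float) -> float:
    """Distribution-weighted AP over a daily exposure series.

    With ``RR_d = exp(beta * max(0, c_d - x0))`` per valid day, returns
    ``sum_d (RR_d - 1) / sum_d RR_d``.
    """
    arr = np.asarray(list(daily_values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("ap_short_term needs at least one valid day")
    rr = rr_loglinear(arr, x0, beta)
    return float(np.sum(rr - 1.0) / np.sum(rr))


def _ap_one(spec: RiskSpec, exposure, which: str) -> float:
    if spec.form == "ier":
        # the printed CI applies to the log-linear specs; IER is evaluated
        # at its central curve for every bound
        x = _scalar_exposure(spec, exposure)
        return ap_from_rr(rr_ier(x, spec.ier))
    beta = spec.beta(which)
    if spec.exposure_basis in ("daily_series", "somo35") and np.ndim(exposure) == 1:
        return ap_short_term(np.asarray(exposure, dtype=float), spec.cutoff, beta)
    x = _scalar_exposure(spec, exposure)
    return ap_from_rr(rr_loglinear(x, spec.cutoff, beta))


def _scalar_exposure(spec: RiskSpec, exposure) -> float:
    """Reduce an exposure input to the scalar concentration the spec's basis needs."""
    if isinstance(exposure, AnnualExposure):
        if spec.exposure_basis == "somo35":
            if exposure.somo35 is None:
                raise ValueError(f"{spec.outcome}: SOMO35 basis needs a SOMO35 value")
            # mean daily exceedance above the cut-off, expressed as cutoff + mean
            # so the log-linear machinery sees the average excess concentration
            return spec.cutoff + exposure.somo35 / exposure.n_total
        return exposure.annual_mean
    if np.ndim(exposure) == 0:
        return float(exposure)
    arr = np.asarray(exposure, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"{spec.outcome}: empty exposure series")
    return float(arr.mean())


def ap_interval(spec: RiskSpec, exposure) -> tuple[float, float, float]:
    """AP evaluated at the low/central/high RR; ordering is preserved.

    ``exposure`` may be an :class:`AnnualExposure`, a scalar concentration, or
    a 1-D array of daily values (required for the ``daily_series`` basis; for
    the ``somo35`` basis a daily max-8-h series in ppb is preferred, with the
    annual SOMO35 scalar as fallback).
    """
    return (
        _ap_one(spec, exposure, "low"),
        _ap_one(spec, exposure, "central"),
        _ap_one(spec, exposure, "high"),
    )


# WHO guideline counterfactuals (annual, ug/m3) and the SOMO35 threshold (ppb)
WHO_GUIDELINES = {Pollutant.PM25: 10.0, Pollutant.NO2: 40.0, Pollutant.O3: 100.0}
SOMO35_THRESHOLD_PPB = 35.0

#: Illustrative IER shape parameters (GBD-style magnitudes). The curve shapes
#: for cause-specific PM2.5 mortality are study-supplied in real use; these
#: placeholders exist so the IER pathway is exercised end to end and are
#: expected to be overridden via the risk configuration file.
_PLACEHOLDER_IER = {
    "alri": IERParams(alpha=2.0, gamma=0.011, delta=1.0, zcf=7.3),
    "copd": IERParams(alpha=30.0, gamma=0.00067, delta=0.81, zcf=7.3),
    "lung_cancer": IERParams(alpha=30.0, gamma=0.00075, delta=0.93, zcf=7.3),
    "ihd": IERParams(alpha=1.3, gamma=0.042, delta=0.74, zcf=7.3),
    "stroke": IERParams(alpha=1.0, gamma=0.038, delta=0.62, zcf=7.3),
}


def default_risk_specs() -> list[RiskSpec]:
    """The assessment's default concentration-response configuration.

    Log-linear RR 1.065 (1.04-1.083) per 10 ug/m3 for total/natural mortality
    (PM2.5 and NO2, both the annual-mean and daily-distribution bases) and
    RR 1.014 (1.005-1.024) per 10 ppb for O3 respiratory mortality on the
    SOMO35 basis; IER curves for PM2.5 cause-specific mortality.
    """
    mort = dict(rr_central=1.065, rr_low=1.04, rr_high=1.083, increment=10.0)
    resp = dict(rr_central=1.014, rr_low=1.005, rr_high=1.024, increment=10.0)
    specs = [
        RiskSpec(Pollutant.PM25, "natural_mortality", cutoff=10.0,
                 exposure_basis="annual_mean", **mort),
        RiskSpec(Pollutant.PM25, "natural_mortality", cutoff=10.0,
                 exposure_basis="daily_series", **mort),
        RiskSpec(Pollutant.NO2, "total_mortality", cutoff=40.0,
                 exposure_basis="annual_mean", **mort),
        RiskSpec(Pollutant.NO2, "total_mortality", cutoff=40.0,
                 exposure_basis="daily_series", **mort),
        RiskSpec(Pollutant.O3, "respiratory_mortality", cutoff=SOMO35_THRESHOLD_PPB,
                 exposure_basis="somo35", **resp),
    ]
    for outcome, params in _PLACEHOLDER_IER.items():
        specs.append(
            RiskSpec(Pollutant.PM25, outcome, form="ier", cutoff=params.zcf,
                     exposure_basis="annual_mean", ier=params)
        )
    return specs


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"risk config: {context} is missing required field {key!r}")
    return mapping[key]


def load_risk_config(path) -> list[RiskSpec]:
    """Read a YAML/JSON risk configuration into validated RiskSpec records.

    Layout::

        risks:
          - pollutant: PM2.5
            outcome: natural_mortality
            form: loglinear            # or "ier"
            rr: {central: 1.065, low: 1.04, high: 1.083}
            increment: 10.0
            cutoff: 10.0
            exposure_basis: annual_mean
          - pollutant: PM2.5
            outcome: ihd
            form: ier
            ier: {alpha: 1.3, gamma: 0.042, delta: 0.74, zcf: 7.3}
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "risks" not in doc:
        raise ValueError("risk config: top level must be a mapping with a 'risks' list")
    specs = []
    for i, entry in enumerate(doc["risks"]):
        ctx = f"risks[{i}]"
        if not isinstance(entry, dict):
            raise ValueError(f"risk config: {ctx} must be a mapping")
        kwargs = dict(
            pollutant=_require(entry, "pollutant", ctx),
            outcome=_require(entry, "outcome", ctx),
            form=entry.get("form", "loglinear"),
            increment=float(entry.get("increment", 10.0)),
            cutoff=float(entry.get("cutoff", 0.0)),
            exposure_basis=entry.get("exposure_basis", "annual_mean"),
        )
        if kwargs["form"] == "loglinear":
            rr = _require(entry, "rr", ctx)
            kwargs.update(
                rr_central=float(_require(rr, "central", f"{ctx}.rr")),
                rr_low=float(rr.get("low", rr["central"])),
                rr_high=float(rr.get("high", rr["central"])),
            )
        if "ier" in entry:
            p = entry["ier"]
            kwargs["ier"] = IERParams(
                alpha=float(_require(p, "alpha", f"{ctx}.ier")),
                gamma=float(_require(p, "gamma", f"{ctx}.ier")),
                delta=float(_require(p, "delta", f"{ctx}.ier")),
                zcf=float(p.get("zcf", kwargs["cutoff"])),
            )
        try:
            specs.append(RiskSpec(**kwargs))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"risk config: {ctx}: {exc}") from exc
    return specs
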