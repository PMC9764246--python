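"""Concentration-response functions, attributable-proportion algebra, CI order."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from airhia.exposure import Pollutant
from airhia.risk import (
    IERParams,
    RiskSpec,
    ap_from_rr,
    ap_interval,
    ap_short_term,
    beta_from_rr,
    default_risk_specs,
    load_risk_config,
    rr_ier,
    rr_loglinear,
)


class TestBeta:
    def test_unit_rr_gives_zero(self):
        assert beta_from_rr(1.0, 10.0) == 0.0

    def test_published_mortality_rr(self):
        assert beta_from_rr(1.065, 10.0) == pytest.approx(0.0062975, abs=5e-8)

    @given(st.floats(1.001, 3.0), st.floats(1.0, 50.0))
    def test_round_trip(self, rr, inc):
        assert math.exp(beta_from_rr(rr, inc) * inc) == pytest.approx(rr)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            beta_from_rr(0.0)


class TestLogLinearRR:
    def test_identity_at_counterfactual(self):
        assert rr_loglinear(10.0, 10.0, 0.0063) == 1.0

    def test_below_cutoff_truncated_to_one(self):
        assert rr_loglinear(5.0, 10.0, 0.0063) == 1.0

    def test_direct_evaluation(self):
        assert rr_loglinear(36.9, 10.0, 0.0062975) == pytest.approx(1.18459, abs=1e-5)

    def test_one_increment_recovers_rr(self):
        beta = beta_from_rr(1.065, 10.0)
        assert rr_loglinear(20.0, 10.0, beta) == pytest.approx(1.065)

    @given(st.floats(0, 300), st.floats(0, 300))
    def test_multiplicative_over_increments(self, a, b):
        x0, beta = 10.0, 0.006
        lo, hi = sorted([max(a, x0), max(b, x0)])
        assert rr_loglinear(hi, x0, beta) == pytest.approx(
            rr_loglinear(lo, x0, beta) * math.exp(beta * (hi - lo))
        )

    @given(st.lists(st.floats(0, 300), min_size=2, max_size=20))
    def test_non_decreasing_in_x(self, xs):
        rr = rr_loglinear(np.sort(np.asarray(xs)), 25.0, 0.004)
        assert np.all(np.diff(rr) >= -1e-12)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            rr_loglinear(10.0, 0.0, float("inf"))


class TestIER:
    P = IERParams(alpha=1.0, gamma=0.1, delta=1.0, zcf=10.0)

    def test_continuity_at_counterfactual(self):
        assert rr_ier(10.0, self.P) == 1.0
        assert rr_ier(10.0 + 1e-9, self.P) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_point(self):
        assert rr_ier(20.0, self.P) == pytest.approx(1 + (1 - math.exp(-1)), abs=1e-9)

    def test_asymptote(self):
        assert rr_ier(1e6, self.P) == pytest.approx(1 + self.P.alpha)

    @given(st.lists(st.floats(0, 1000), min_size=2, max_size=20))
    def test_monotone_and_bounded(self, zs):
        rr = rr_ier(np.sort(np.asarray(zs)), self.P)
        assert np.all(np.diff(rr) >= -1e-12)
        assert np.all((rr >= 1.0) & (rr <= 1 + self.P.alpha + 1e-12))

    @pytest.mark.parametrize("bad", [dict(alpha=0), dict(gamma=-1), dict(delta=0), dict(zcf=-1)])
    def test_invalid_params_rejected(self, bad):
        kwargs = dict(alpha=1.0, gamma=0.1, delta=1.0, zcf=10.0) | bad
        with pytest.raises(ValueError):
            IERParams(**kwargs)


class TestAttributableProportion:
    @pytest.mark.parametrize("rr,ap", [(1.0, 0.0), (2.0, 0.5), (1.18459, 0.15583)])
    def test_paf_values(self, rr, ap):
        assert ap_from_rr(rr) == pytest.approx(ap, abs=1e-5)

    def test_protective_rr_rejected(self):
        with pytest.raises(ValueError, match="protective"):
            ap_from_rr(0.9)

    @given(st.floats(1.0, 50.0), st.floats(1.0, 50.0))
    def test_strictly_increasing_bounded(self, r1, r2):
        lo, hi = sorted([r1, r2])
        a_lo, a_hi = ap_from_rr(lo), ap_from_rr(hi)
        assert 0 <= a_lo <= a_hi < 1
        if hi > lo:
            assert a_hi > a_lo

    def test_short_term_all_below_cutoff(self):
        assert ap_short_term([5.0, 8.0, 10.0], x0=10.0, beta=0.006) == 0.0

    def test_short_term_single_day_reduces_to_paf(self):
        ap = ap_short_term([36.9], x0=10.0, beta=0.0062975)
        assert ap == pytest.approx(ap_from_rr(rr_loglinear(36.9, 10.0, 0.0062975)))

    def test_short_term_matches_enumeration(self):
        x0, beta = 10.0, 0.0062975
        days = [x0, x0 + 10, x0 + 20]
        rr = [math.exp(beta * max(0, d - x0)) for d in days]
        expect = sum(r - 1 for r in rr) / sum(rr)
        assert ap_short_term(days, x0, beta) == pytest.approx(expect)

    def test_short_term_constant_series_equals_paf(self):
        ap = ap_short_term([40.0] * 30, x0=10.0, beta=0.005)
        assert ap == pytest.approx(ap_from_rr(rr_loglinear(40.0, 10.0, 0.005)))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ap_short_term([], 10.0, 0.006)


class TestApInterval:
    def spec(self, rr=(1.04, 1.065, 1.083), basis="annual_mean"):
        return RiskSpec(
            Pollutant.PM25, "natural_mortality", rr_low=rr[0], rr_central=rr[1],
            rr_high=rr[2], increment=10.0, cutoff=10.0, exposure_basis=basis,
        )

    def test_unit_rr_triple(self):
        spec = self.spec(rr=(1.0, 1.0, 1.0))
        assert ap_interval(spec, 50.0) == (0.0, 0.0, 0.0)

    def test_central_value_one_increment_above_cutoff(self):
        lo, mid, hi = ap_interval(self.spec(), 20.0)
        assert mid == pytest.approx(0.065 / 1.065, abs=1e-5)
        assert lo <= mid <= hi

    @given(st.floats(0, 300))
    def test_ordering_preserved(self, x):
        lo, mid, hi = ap_interval(self.spec(), x)
        assert lo <= mid <= hi

    def test_daily_series_basis_uses_distribution(self):
        spec = self.spec(basis="daily_series")
        days = np.array([5.0, 20.0, 40.0])
        _, mid, _ = ap_interval(spec, days)
        assert mid == pytest.approx(ap_short_term(days, 10.0, spec.beta("central")))


class TestSpecValidationAndConfig:
    def test_rr_ordering_enforced(self):
        with pytest.raises(ValueError, match="RR bounds"):
            RiskSpec(Pollutant.PM25, "x", rr_low=1.1, rr_central=1.0, rr_high=1.2)

    def test_ier_form_requires_params(self):
        with pytest.raises(ValueError, match="IER"):
            RiskSpec(Pollutant.PM25, "ihd", form="ier")

    def test_default_specs_cover_study_outcomes(self):
        specs = default_risk_specs()
        outcomes = {(s.pollutant, s.outcome, s.exposure_basis) for s in specs}
        assert (Pollutant.O3, "respiratory_mortality", "somo35") in outcomes
        assert (Pollutant.NO2, "total_mortality", "daily_series") in outcomes
        assert any(s.form == "ier" for s in specs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "risk.yaml"
        cfg.write_text(
            "risks:\n"
            "  - pollutant: no2\n"
            "    outcome: total_mortality\n"
            "    rr: {central: 1.065, low: 1.04, high: 1.083}\n"
            "    cutoff: 40\n"
            "    exposure_basis: daily_series\n"
            "  - pollutant: PM2.5\n"
            "    outcome: ihd\n"
            "    form: ier\n"
            "    ier: {alpha: 1.3, gamma: 0.042, delta: 0.74, zcf: 7.3}\n"
        )
        specs = load_risk_config(cfg)
        assert specs[0].pollutant is Pollutant.NO2
        assert specs[0].beta("central") == pytest.approx(math.log(1.065) / 10)
        assert specs[1].form == "ier" and specs[1].ier.zcf == 7.3

    def test_config_errors_name_the_entry(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("risks:\n  - pollutant: PM2.5\n    outcome: x\n")
        with pytest.raises(ValueError, match=r"risks\[0\]"):
            load_risk_config(cfg)
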