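"""Daily metrics, city averaging, annual summaries and SOMO35."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from airhia.exposure import (
    Metric,
    Pollutant,
    StationSeries,
    annual_mean,
    city_daily_series,
    daily_max_1h,
    daily_max_8h_mean,
    daily_mean_24h,
    daily_metric_series,
    exceedance_ratio,
    o3_unit_convert,
    somo35,
)

NAN = float("nan")


def day(values):
    return np.asarray(values, dtype=float)


class TestDailyMean24h:
    def test_constant_day(self):
        m = daily_mean_24h(day([30.0] * 24))
        assert m.valid and m.value == 30.0 and m.n_valid_hours == 24

    def test_arithmetic_mean(self):
        assert daily_mean_24h(day(range(1, 25))).value == pytest.approx(12.5)

    @pytest.mark.parametrize("n_valid,expect_valid", [(18, True), (17, False)])
    def test_75_percent_rule(self, n_valid, expect_valid):
        hours = [NAN] * (24 - n_valid) + [10.0] * n_valid
        m = daily_mean_24h(day(hours), min_fraction=0.75)
        assert m.valid is expect_valid
        assert m.n_valid_hours == n_valid
        if not expect_valid:
            assert np.isnan(m.value)

    def test_rejects_wrong_length_and_negative(self):
        with pytest.raises(ValueError, match="24 hourly slots"):
            daily_mean_24h(day([1.0] * 23))
        with pytest.raises(ValueError, match="slot 3"):
            daily_mean_24h(day([1.0, 1.0, 1.0, -5.0] + [1.0] * 20))


class TestDailyMax1h:
    def test_max_of_full_day(self):
        hours = [20.0] * 23 + [80.0]
        m = daily_max_1h(day(hours))
        assert m.valid and m.value == 80.0

    def test_17_hours_invalid(self):
        m = daily_max_1h(day([NAN] * 7 + [30.0] * 17), min_hours=18)
        assert not m.valid

    def test_spike_with_gaps(self):
        hours = [10.0] * 8 + [120.0] + [10.0] * 11 + [NAN] * 4
        m = daily_max_1h(day(hours))
        assert m.valid and m.value == 120.0 and m.n_valid_hours == 20


class TestDailyMax8hMean:
    def test_constant_day(self):
        m = daily_max_8h_mean(day([40.0] * 24))
        assert m.valid and m.value == pytest.approx(40.0)

    def test_linear_ramp_picks_last_window(self):
        # max window is hours 17..24 -> mean 20.5
        assert daily_max_8h_mean(day(range(1, 25))).value == pytest.approx(20.5)

    def test_all_missing_invalid(self):
        m = daily_max_8h_mean(day([NAN] * 24))
        assert not m.valid and np.isnan(m.value)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            hours = rng.uniform(0, 100, 24)
            hours[rng.random(24) < 0.3] = NAN
            got = daily_max_8h_mean(hours)
            # exhaustive enumeration over the 17 window starts
            best = -np.inf
            any_window = False
            for s in range(17):
                w = hours[s : s + 8]
                if np.sum(~np.isnan(w)) >= 6:
                    any_window = True
                    best = max(best, np.nanmean(w))
            n_valid = int(np.sum(~np.isnan(hours)))
            if any_window and n_valid >= 18:
                assert got.valid and got.value == pytest.approx(best)
            else:
                assert not got.valid

    @given(st.lists(st.floats(0, 500), min_size=24, max_size=24))
    def test_max8h_below_max1h_on_full_day(self, hours):
        m8 = daily_max_8h_mean(day(hours))
        m1 = daily_max_1h(day(hours))
        assert m8.value <= m1.value + 1e-9


class TestCitySeries:
    @staticmethod
    def daily(dates, values, valid):
        return pd.DataFrame(
            {"value": values, "n_valid_hours": 24, "valid": valid},
            index=pd.DatetimeIndex(dates, name="date"),
        )

    def test_single_station_identity(self):
        dates = pd.date_range("2015-03-01", periods=3)
        df = self.daily(dates, [20.0, 30.0, 40.0], [True] * 3)
        city = city_daily_series([df])
        assert np.allclose(city["value"], [20, 30, 40])

    def test_two_stations_midpoint_and_valid_subset(self):
        dates = pd.date_range("2015-03-01", periods=2)
        a = self.daily(dates, [20.0, 25.0], [True, True])
        b = self.daily(dates, [40.0, np.nan], [True, False])
        city = city_daily_series([a, b])
        assert city["value"].tolist() == [30.0, 25.0]
        assert city["n_stations"].tolist() == [2, 1]

    def test_day_invalid_when_no_station_valid(self):
        dates = pd.date_range("2015-03-01", periods=1)
        a = self.daily(dates, [np.nan], [False])
        city = city_daily_series([a])
        assert not city["valid"].iloc[0]

    def test_empty_station_list_rejected(self):
        with pytest.raises(ValueError):
            city_daily_series([])

    def test_city_within_station_envelope(self):
        rng = np.random.default_rng(0)
        dates = pd.date_range("2015-03-01", periods=30)
        frames = [
            self.daily(dates, rng.uniform(10, 90, 30), rng.random(30) > 0.2)
            for _ in range(3)
        ]
        city = city_daily_series(frames)
        stacked = pd.concat(
            [f["value"].where(f["valid"]) for f in frames], axis=1
        )
        lo, hi = stacked.min(axis=1), stacked.max(axis=1)
        ok = city["valid"]
        assert ((city.loc[ok, "value"] >= lo[ok] - 1e-9)
                & (city.loc[ok, "value"] <= hi[ok] + 1e-9)).all()

    def test_dropping_invalid_station_changes_nothing(self):
        dates = pd.date_range("2015-03-01", periods=5)
        rng = np.random.default_rng(1)
        a = self.daily(dates, rng.uniform(10, 50, 5), [True] * 5)
        dead = self.daily(dates, [np.nan] * 5, [False] * 5)
        with_dead = city_daily_series([a, dead])
        without = city_daily_series([a])
        pd.testing.assert_series_equal(with_dead["value"], without["value"])


class TestAnnualAndSomo35:
    def make_daily(self, values, valid=None):
        n = len(values)
        valid = [True] * n if valid is None else valid
        return pd.DataFrame(
            {"value": values, "valid": valid},
            index=pd.date_range("2015-03-01", periods=n, name="date"),
        )

    def test_constant_year(self):
        exp = annual_mean(self.make_daily([29.5] * 365), "P")
        assert exp.annual_mean == pytest.approx(29.5)
        assert exp.n_valid == exp.n_total == 365

    def test_completeness_fraction(self):
        valid = [True] * 200 + [False] * 165
        vals = [10.0] * 200 + [np.nan] * 165
        exp = annual_mean(self.make_daily(vals, valid), "P")
        assert exp.completeness == pytest.approx(200 / 365)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(5, 80, 100)
        exp = annual_mean(self.make_daily(list(vals)), "P")
        assert exp.annual_mean == pytest.approx(vals.sum() / 100)

    def test_zero_valid_days_rejected(self):
        with pytest.raises(ValueError, match="no valid days"):
            annual_mean(self.make_daily([np.nan] * 10, [False] * 10), "P")

    def test_somo35_no_exceedance_is_zero(self):
        assert somo35([10, 20, 34.9], n_total=365, n_valid=3) == 0.0

    def test_somo35_single_term(self):
        assert somo35([40.0] + [30.0] * 364, n_total=365, n_valid=365) == pytest.approx(5.0)

    def test_somo35_missing_day_correction(self):
        got = somo35([30.0, 40.0, 50.0], n_total=365, n_valid=3)
        assert got == pytest.approx((0 + 5 + 15) * 365 / 3)

    def test_somo35_correction_at_least_one(self):
        full = somo35([40.0] * 300, n_total=300, n_valid=300)
        gappy = somo35([40.0] * 250, n_total=300, n_valid=250)
        assert gappy >= full > 0

    def test_somo35_zero_valid_rejected(self):
        with pytest.raises(ValueError):
            somo35([], n_total=365, n_valid=0)


class TestUnitsAndRatios:
    @pytest.mark.parametrize("mean,guide,expect", [(29.5, 10, 2.95), (58.6, 10, 5.86), (10, 10, 1.0)])
    def test_exceedance_ratio(self, mean, guide, expect):
        assert exceedance_ratio(mean, guide) == pytest.approx(expect)

    def test_exceedance_rejects_nonpositive_guideline(self):
        with pytest.raises(ValueError):
            exceedance_ratio(10.0, 0.0)

    def test_ppb_to_ugm3(self):
        assert o3_unit_convert(35.0, "ppb", "ug/m3") == pytest.approx(68.6)

    def test_same_unit_identity_and_round_trip(self):
        assert o3_unit_convert(12.3, "ppb", "ppb") == 12.3
        back = o3_unit_convert(o3_unit_convert(12.3, "ppb", "ug/m3"), "ug/m3", "ppb")
        assert back == pytest.approx(12.3)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            o3_unit_convert(1.0, "ppm", "ppb")


class TestStationSeriesValidation:
    def test_rejects_negative_value_naming_slot(self, day_index):
        vals = pd.Series([1.0] * 24, index=day_index)
        vals.iloc[5] = -2.0
        with pytest.raises(ValueError, match="negative concentration"):
            StationSeries("S1", "PM2.5", vals)

    def test_rejects_non_hourly_timestamps(self):
        idx = pd.DatetimeIndex(["2015-03-01 00:00", "2015-03-01 00:30"])
        with pytest.raises(ValueError, match="non-hourly"):
            StationSeries("S1", "NO2", pd.Series([1.0, 2.0], index=idx))

    def test_rejects_duplicate_timestamps(self):
        idx = pd.DatetimeIndex(["2015-03-01 00:00"] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            StationSeries("S1", "NO2", pd.Series([1.0, 2.0], index=idx))

    def test_daily_metric_series_matches_per_day_function(self):
        rng = np.random.default_rng(9)
        idx = pd.date_range("2015-03-01", periods=5 * 24, freq="h")
        vals = rng.uniform(0, 60, len(idx))
        vals[rng.random(len(idx)) < 0.2] = np.nan
        s = StationSeries("S1", "O3", pd.Series(vals, index=idx), unit="ppb")
        table = daily_metric_series(s, Metric.MAX_8H_MEAN)
        for d in range(5):
            expect = daily_max_8h_mean(vals[d * 24 : (d + 1) * 24])
            row = table.iloc[d]
            assert row["valid"] == expect.valid
            if expect.valid:
                assert row["value"] == pytest.approx(expect.value)

    @given(st.floats(1, 200), st.integers(0, 23))
    def test_constant_day_every_metric_equals_constant(self, level, missing_at):
        hours = np.full(24, level)
        hours[missing_at] = np.nan  # one missing hour keeps every metric valid
        for fn in (daily_mean_24h, daily_max_1h, daily_max_8h_mean):
            m = fn(hours)
            assert m.valid and m.value == pytest.approx(level)
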