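"""Ratio-method exposure assessment: extrapolation, weekly and long-term."""

import numpy as np
import pandas as pd
import pytest

import airdfc as a
from airdfc import exposure as expo


def _panel(records):
    return pd.DataFrame(records, columns=["site", "date", "pollutant", "concentration"]).assign(
        date=lambda d: pd.to_datetime(d["date"])
    )


def _days(start, n):
    return pd.date_range(start, periods=n, freq="D")


class TestReferencePeriodMean:
    def test_constant_series(self):
        days = _days("2009-01-01", 365)
        panel = _panel([("s1", d, "NO2", 20.0) for d in days])
        assert expo.reference_period_mean(panel, "s1", "NO2", (days[0], days[-1])) == 20.0

    def test_alternating_series_hand_mean(self):
        days = _days("2009-01-01", 364)
        panel = _panel([("s1", d, "NO2", 10.0 if i % 2 == 0 else 30.0) for i, d in enumerate(days)])
        assert expo.reference_period_mean(panel, "s1", "NO2", (days[0], days[-1])) == pytest.approx(20.0)

    def test_half_coverage_errors_with_fraction(self):
        days = _days("2009-01-01", 365)
        panel = _panel([("s1", d, "NO2", 20.0) for d in days[::2]])
        with pytest.raises(expo.CoverageError) as err:
            expo.reference_period_mean(panel, "s1", "NO2", (days[0], days[-1]))
        assert err.value.coverage == pytest.approx(0.5, abs=0.01)


class TestDailyRatio:
    def test_two_site_hand_arithmetic(self):
        """Site A daily 30 / annual 20 (r=1.5); site B 10/10 (r=1.0) -> 1.25."""
        panel = _panel([("A", "2010-06-01", "NOX", 30.0), ("B", "2010-06-01", "NOX", 10.0)])
        annual = pd.DataFrame(
            {"site": ["A", "B"], "pollutant": ["NOX", "NOX"], "annual": [20.0, 10.0]}
        )
        r, substituted = expo.daily_ratio(panel, annual, "2010-06-01", "NOX")
        assert r == pytest.approx(1.25)
        assert not substituted

    def test_identity_when_daily_equals_annual(self):
        panel = _panel([("A", "2010-06-01", "NO2", 22.0), ("B", "2010-06-01", "NO2", 17.0)])
        annual = pd.DataFrame({"site": ["A", "B"], "pollutant": ["NO2"] * 2, "annual": [22.0, 17.0]})
        assert expo.daily_ratio(panel, annual, "2010-06-01", "NO2")[0] == pytest.approx(1.0)

    def test_surrogate_substitution_pm25_to_pm10(self):
        """PM25 absent everywhere that day: PM10's ratio returned, flagged."""
        panel = _panel([("A", "2010-06-01", "PM10", 36.0)])
        annual = pd.DataFrame({"site": ["A"], "pollutant": ["PM10"], "annual": [18.0]})
        r, substituted = expo.daily_ratio(panel, annual, "2010-06-01", "PM25")
        assert r == pytest.approx(2.0)
        assert substituted

    def test_no_data_at_all_errors(self):
        panel = _panel([("A", "2010-06-01", "NO2", 20.0)])
        annual = pd.DataFrame({"site": ["A"], "pollutant": ["NO2"], "annual": [20.0]})
        with pytest.raises(ValueError, match="surrogate"):
            expo.daily_ratio(panel, annual, "2010-06-02", "PM25")

    def test_substitution_rule_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            expo.check_substitution_rule({"A": "B", "B": "A"})
        with pytest.raises(ValueError, match="itself"):
            expo.check_substitution_rule({"A": "A"})

    def test_series_matches_single_day_calls(self, world, ratio_series):
        annual = expo.annual_site_means(world.panel, world.reference_period)
        for date in [world.dates[400], world.dates[800]]:
            for pollutant in ["NOX", "PM25"]:
                r, substituted = expo.daily_ratio(world.panel, annual, date, pollutant)
                row = ratio_series[(ratio_series["date"] == date) & (ratio_series["pollutant"] == pollutant)]
                assert r == pytest.approx(row["ratio"].iloc[0])
                assert substituted == bool(row["substituted"].iloc[0])


class TestExtrapolateAndWeekly:
    def test_extrapolation_hand_values(self):
        assert expo.extrapolate_daily(40.0, 1.25) == pytest.approx(50.0)
        assert expo.extrapolate_daily(40.0, 1.0) == pytest.approx(40.0)
        assert expo.extrapolate_daily(40.0, 0.5) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            expo.extrapolate_daily(-1.0, 1.0)

    def _ratio_frame(self, values, start="2010-06-01"):
        days = _days(start, len(values))
        return pd.DataFrame(
            {"date": days, "pollutant": "NO2", "ratio": values, "substituted": False}
        )

    def test_identity_week(self):
        ratios = self._ratio_frame([1.0] * 7)
        week = expo.weekly_exposure(40.0, ratios, "2010-06-08", "NO2")
        assert week.mean == pytest.approx(40.0)
        assert week.n_days_used == 7 and not week.substituted

    def test_one_elevated_day_hand_mean(self):
        """Ratios (1,1,1,1,1,1,2) on annual 35 -> 35 * 8/7 = 40."""
        ratios = self._ratio_frame([1, 1, 1, 1, 1, 1, 2])
        week = expo.weekly_exposure(35.0, ratios, "2010-06-08", "NO2")
        assert week.mean == pytest.approx(40.0)

    def test_too_few_days_errors(self):
        ratios = self._ratio_frame([1.0, 1.0, 1.0])
        with pytest.raises(expo.CoverageError):
            expo.weekly_exposure(40.0, ratios, "2010-06-08", "NO2")

    def test_include_scan_day_extends_window(self):
        ratios = self._ratio_frame([1.0] * 7 + [2.0])
        strict = expo.weekly_exposure(40.0, ratios, "2010-06-08", "NO2")
        wide = expo.weekly_exposure(40.0, ratios, "2010-06-08", "NO2", include_scan_day=True)
        assert strict.mean == pytest.approx(40.0)
        assert wide.mean == pytest.approx(45.0)
        assert wide.n_days_used == 8

    def test_substitution_flag_propagates_to_week(self):
        """Flag set iff the target pollutant was substituted on >= 1 used day."""
        days = _days("2010-06-01", 7)
        ratios = pd.DataFrame(
            {
                "date": days,
                "pollutant": "PM25",
                "ratio": 1.0,
                "substituted": [False] * 6 + [True],
            }
        )
        week = expo.weekly_exposure(10.0, ratios, "2010-06-08", "PM25")
        assert week.substituted
        clean = expo.weekly_exposure(10.0, ratios, "2010-06-07", "PM25", min_days=5)
        assert not clean.substituted

    def test_exact_recovery_when_daily_is_annual_times_ratio(self, world, ratio_series):
        """When address dailies are constructed as annual x shared ratio,
        the weekly exposure reproduces the constructed mean to 1e-10."""
        annual_addr = 33.7
        scan = world.dates[500]
        days = pd.date_range(scan - pd.Timedelta(days=7), scan - pd.Timedelta(days=1))
        sel = ratio_series[(ratio_series["pollutant"] == "NOX") & (ratio_series["date"].isin(days))]
        constructed = (annual_addr * sel["ratio"]).mean()
        week = expo.weekly_exposure(annual_addr, ratio_series, scan, "NOX")
        assert abs(week.mean - constructed) < 1e-10

    def test_weekly_table_matches_per_session_calls(self, world, ratio_series):
        surface = a.simulate_annual_surface(4, seed=9)
        sessions = pd.DataFrame(
            {
                "participant": ["p1", "p2", "p3"],
                "visit": [1, 1, 2],
                "address": ["addr1", "addr2", "addr4"],
                "scan_date": [world.dates[450], world.dates[900], world.dates[1500]],
            }
        )
        table = expo.weekly_exposure_table(surface, ratio_series, sessions, ("NOX", "PM25ABS"))
        assert len(table) == 6
        for _, row in table.iterrows():
            sess = sessions[sessions["participant"] == row["participant"]].iloc[0]
            week = expo.weekly_exposure(
                float(surface.loc[sess["address"], row["pollutant"]]),
                ratio_series, sess["scan_date"], row["pollutant"],
            )
            assert row["weekly_mean"] == pytest.approx(week.mean, abs=1e-10)
            assert row["n_days_used"] == week.n_days_used


class TestLongterm:
    def _surface(self):
        return pd.DataFrame({"NO2": [20.0, 40.0, 25.0]}, index=pd.Index(["a", "b", "c"], name="address"))

    def test_single_address(self):
        history = [("c", "2002-01-01", "2012-01-01")]
        val = expo.longterm_exposure(history, self._surface(), ("2002-01-01", "2012-01-01"), "NO2")
        assert val == pytest.approx(25.0)

    def test_time_weighted_two_addresses(self):
        """100 days at 20 then 300 days at 40 -> (100*20 + 300*40)/400 = 35."""
        history = [("a", "2010-01-01", "2010-04-10"), ("b", "2010-04-11", "2011-02-04")]
        val = expo.longterm_exposure(history, self._surface(), ("2010-01-01", "2011-02-04"), "NO2")
        assert val == pytest.approx(35.0)

    def test_overlapping_intervals_rejected(self):
        history = [("a", "2010-01-01", "2010-06-01"), ("b", "2010-05-01", "2010-12-31")]
        with pytest.raises(ValueError, match="overlap"):
            expo.longterm_exposure(history, self._surface(), ("2010-01-01", "2010-12-31"), "NO2")

    def test_coverage_gap_rejected(self):
        history = [("a", "2010-01-01", "2010-03-01")]
        with pytest.raises(expo.CoverageError):
            expo.longterm_exposure(history, self._surface(), ("2010-01-01", "2010-12-31"), "NO2")

    def test_invariant_to_splitting_interval(self):
        whole = [("a", "2010-01-01", "2010-12-31")]
        split = [("a", "2010-01-01", "2010-05-15"), ("a", "2010-05-16", "2010-12-31")]
        period = ("2010-01-01", "2010-12-31")
        assert expo.longterm_exposure(whole, self._surface(), period, "NO2") == pytest.approx(
            expo.longterm_exposure(split, self._surface(), period, "NO2")
        )


class TestIncrements:
    def test_default_table_values(self):
        assert expo.DEFAULT_INCREMENTS == {
            "NO2": 10.0, "NOX": 20.0, "PM25": 5.0, "PM10": 10.0, "PMCOARSE": 5.0, "PM25ABS": 1.0,
        }

    def test_scaling(self):
        beta, ci = expo.scale_to_increment(0.002, (-0.001, 0.003), "NOX")
        assert beta == pytest.approx(0.04)
        assert ci == (pytest.approx(-0.02), pytest.approx(0.06))
        beta10, ci10 = expo.scale_to_increment(0.0, (-0.001, 0.003), "NO2")
        assert beta10 == 0.0
        assert ci10 == (pytest.approx(-0.01), pytest.approx(0.03))

    def test_unknown_pollutant(self):
        with pytest.raises(KeyError):
            expo.scale_to_increment(1.0, (0.0, 2.0), "O3")
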