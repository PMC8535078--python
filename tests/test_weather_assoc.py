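"""Weather-window aggregation and trait-climate correlation grids."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oatmet import (
    DailyWeather,
    DegenerateInputError,
    EnvironmentRecord,
    IntegrityError,
    WeatherCovariate,
    WindowSpec,
    aggregate_weather,
    correlation_table,
    pearson,
    significance_stars,
)


def constant_series(start, end, rain=2.0, tmin=4.0, tmax=12.0):
    days = pd.date_range(start, end, freq="D")
    return DailyWeather(
        pd.DataFrame({"date": days, "rain": rain, "tmin": tmin, "tmax": tmax})
    )


def env(harvest=date(2013, 8, 20)):
    return EnvironmentRecord("e1", "X", 52.0, -4.0, date(2012, 10, 1), harvest)


class TestDailyWeatherValidation:
    def test_duplicate_dates_rejected(self):
        df = pd.DataFrame({"date": ["2013-01-01", "2013-01-01"], "rain": [1.0, 2.0]})
        with pytest.raises(IntegrityError):
            DailyWeather(df)

    @pytest.mark.parametrize(
        "col,val", [("rain", -1.0), ("rh", 150.0), ("radiation", -0.5)]
    )
    def test_out_of_range_values_rejected(self, col, val):
        df = pd.DataFrame({"date": ["2013-01-01"], col: [val]})
        with pytest.raises(IntegrityError):
            DailyWeather(df)

    def test_tmin_above_tmax_rejected(self):
        df = pd.DataFrame({"date": ["2013-01-01"], "tmin": [10.0], "tmax": [5.0]})
        with pytest.raises(IntegrityError):
            DailyWeather(df)


class TestAggregateWeather:
    def test_winter_rain_window_sums_151_days(self):
        """Dec 1 - Apr 30 before an autumn-sown 2013 harvest spans a
        non-leap year: 151 days of 2 mm -> 302 mm."""
        series = constant_series("2012-11-01", "2013-09-01")
        cov = WeatherCovariate(
            "rain_dec_apr", "rain", "sum", WindowSpec(12, 1, 4, 30)
        )
        assert aggregate_weather(series, env(), cov) == pytest.approx(302.0)

    def test_july_temperature_is_mean_midrange(self):
        series = constant_series("2013-06-01", "2013-08-31")
        cov = WeatherCovariate("temp_jul", "temperature", "mean", WindowSpec(7))
        assert aggregate_weather(series, env(), cov) == pytest.approx(8.0)

    def test_empty_overlap_gives_missing(self):
        series = constant_series("2013-06-01", "2013-08-31")
        cov = WeatherCovariate("rain_dec_apr", "rain", "sum", WindowSpec(12, 1, 4, 30))
        with pytest.warns(UserWarning, match="absent"):
            assert np.isnan(aggregate_weather(series, env(), cov))

    def test_small_gaps_tolerated_large_gaps_missing(self):
        days = pd.date_range("2013-07-01", "2013-07-31", freq="D")
        frame = pd.DataFrame({"date": days, "rain": 1.0})
        cov = WeatherCovariate("rain_jul", "rain", "sum", WindowSpec(7))
        ok = DailyWeather(frame.drop(index=[3, 10]))        # 2/31 missing < 10%
        assert aggregate_weather(ok, env(), cov) == pytest.approx(29.0)
        sparse = DailyWeather(frame.iloc[::3])              # ~2/3 missing
        with pytest.warns(UserWarning):
            assert np.isnan(aggregate_weather(sparse, env(), cov))

    def test_autumn_months_anchor_to_year_before_harvest(self):
        w = WindowSpec(11)
        start, end = w.resolve(2013)
        assert (start, end) == (date(2012, 11, 1), date(2012, 11, 30))
        start, end = WindowSpec(6, 1, 7, 31).resolve(2013)
        assert (start, end) == (date(2013, 6, 1), date(2013, 7, 31))


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.df == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_reference_beta_glucan_vs_summer_rain(self, trial_environments, env_dimensions):
        keep = trial_environments.index != 8
        res = pearson(
            trial_environments.loc[keep, "rain_jun_jul"],
            env_dimensions.loc[keep, "beta_glucan"],
        )
        assert res.r == pytest.approx(-0.846, abs=0.02)
        assert res.stars == "***"

    def test_reference_hullability_vs_summer_rain(self, trial_environments, env_quality):
        keep = trial_environments.index != 8
        res = pearson(
            trial_environments.loc[keep, "rain_jun_jul"],
            env_quality.loc[keep, "hullability"],
        )
        assert res.r == pytest.approx(0.803, abs=0.02)

    @given(
        st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=4, max_size=30,
        ),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_symmetry_and_affine_invariance(self, pairs, scale, shift):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        r_xy = pearson(x, y).r
        assert abs(r_xy) <= 1.0 + 1e-12
        assert pearson(y, x).r == pytest.approx(r_xy, abs=1e-12)
        assert pearson(scale * x + shift, y).r == pytest.approx(r_xy, abs=1e-9)


class TestCorrelationTable:
    def test_pairwise_deletion_yields_mixed_df(self, trial_environments, env_means):
        """Traits with unrecorded environments lose only their own df:
        hectoliter weight (2 na sites) drops to df 17 while complete
        traits keep df 19, after the spring-sown exclusion."""
        covs = trial_environments[["rain_dec_apr", "rain_jun_jul"]]
        grid = correlation_table(env_means, covs, exclude={8})
        cell = grid[(grid.trait == "hectoliter_weight") & (grid.covariate == "rain_jun_jul")]
        assert cell["df"].iloc[0] == 17
        yld = grid[(grid.trait == "yield") & (grid.covariate == "rain_jun_jul")]
        assert yld["df"].iloc[0] == 19

    def test_all_environments_excluded_is_error(self, trial_environments, env_means):
        covs = trial_environments[["rain_jun_jul"]]
        with pytest.raises(DegenerateInputError):
            correlation_table(env_means, covs, exclude=set(env_means.index))

    def test_identical_trait_rows_get_identical_r(self, trial_environments, env_quality):
        em = env_quality[["yield"]].copy()
        em["yield_copy"] = em["yield"]
        covs = trial_environments[["rain_jun_jul"]]
        grid = correlation_table(em, covs, exclude={8})
        r = grid.set_index("trait")["r"]
        assert r["yield"] == pytest.approx(r["yield_copy"], abs=0)

    def test_undefined_cells_carry_reason_not_crash(self, trial_environments):
        em = pd.DataFrame(
            {"flat": 1.0, "ok": np.arange(22.0)}, index=trial_environments.index
        )
        grid = correlation_table(em, trial_environments[["rain_jun_jul"]])
        flat = grid[grid.trait == "flat"].iloc[0]
        assert np.isnan(flat["r"]) and "variance" in flat["reason"]


@pytest.mark.parametrize(
    "p,stars", [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, "")]
)
def test_star_thresholds(p, stars):
    assert significance_stars(p) == stars
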