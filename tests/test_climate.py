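import numpy as np
import pandas as pd
import pytest

from wingallometry.climate import (
    CovariateTerm, ModelSpec, aggregate_window, build_covariate_table,
    mean_daily_temperature, migration_window, prebreeding_window,
    season_windows,
)


def daily_series(year=2005, tmin=None, tmax=None, precip=None, n=365,
                 species="sp", range_label="breeding"):
    dates = pd.date_range(f"{year}-01-01", periods=n, freq="D")
    rng = np.random.default_rng(0)
    if tmin is None:
        tmin = rng.normal(5, 3, n)
    if tmax is None:
        tmax = np.asarray(tmin) + np.abs(rng.normal(8, 2, n))
    if precip is None:
        precip = np.abs(rng.normal(2, 1, n))
    return pd.DataFrame({
        "species": species, "range": range_label, "date": dates,
        "tmin": tmin, "tmax": tmax, "precip": precip,
    })


class TestMigrationWindow:
    @pytest.mark.parametrize("dates,expected", [
        ([100, 110, 120], (100, 120)),      # mean 110, sample sd 10
        ([50, 50, 50], (50, 50)),           # degenerate zero-spread window
        ([1, 5], (1, 6)),                   # lower bound clamped to day 1
    ])
    def test_examples(self, dates, expected):
        assert migration_window(dates) == expected

    def test_insufficient_phenology(self):
        with pytest.raises(ValueError, match="insufficient phenology"):
            migration_window([100])

    def test_fractional_bounds_round_to_whole_days(self):
        # mean 100, sample sd ~3.536 -> bounds 96.46 / 103.54 -> (96, 104)
        dates = [97.5, 102.5]
        assert np.std(dates, ddof=1) == pytest.approx(3.5355339)
        assert migration_window(dates) == (96, 104)


class TestPrebreedingWindow:
    @pytest.mark.parametrize("spring,expected", [
        ((100, 140), (141, 170)),
        ((1, 1), (2, 31)),
    ])
    def test_examples(self, spring, expected):
        assert prebreeding_window(spring) == expected

    def test_year_boundary_is_an_error(self):
        with pytest.raises(ValueError, match="year boundary"):
            prebreeding_window((330, 340))

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            prebreeding_window((140, 100))


class TestMeanDailyTemperature:
    @pytest.mark.parametrize("tmax,tmin,expected", [
        (20, 10, 15), (0, 0, 0), (5, -5, 0),
    ])
    def test_examples(self, tmax, tmin, expected):
        assert mean_daily_temperature(tmax, tmin) == expected

    def test_inverted_pair_rejected(self):
        with pytest.raises(ValueError):
            mean_daily_temperature(5, 10)


class TestAggregateWindow:
    def test_small_window_mean(self):
        s = daily_series(n=10)
        s["tmin"] = np.arange(1.0, 11.0)
        s["tmax"] = np.arange(1.0, 11.0)
        assert aggregate_window(s, (3, 5), 2005, "mean_tmean") == \
            pytest.approx(4.0)

    def test_constant_series(self):
        s = daily_series()
        s["precip"] = 3.25
        assert aggregate_window(s, (40, 360), 2005, "mean_precip") == \
            pytest.approx(3.25)

    def test_invalid_window(self):
        with pytest.raises(ValueError, match="invalid window"):
            aggregate_window(daily_series(), (5, 4), 2005, "mean_tmin")

    def test_partial_coverage_lists_missing_days(self):
        s = daily_series(n=100)
        s = s[s["date"].dt.dayofyear != 50]
        with pytest.raises(ValueError, match="partially covered"):
            aggregate_window(s, (45, 55), 2005, "mean_tmin")

    def test_matches_bruteforce_on_random_windows(self, rng):
        """Window means equal a day-by-day loop on 500 random windows."""
        s = daily_series(n=365)
        doy = s["date"].dt.dayofyear.to_numpy()
        for _ in range(500):
            a = int(rng.integers(1, 360))
            b = int(rng.integers(a, 366))
            stat, col = rng.choice([("mean_tmin", "tmin"),
                                    ("mean_precip", "precip")])
            got = aggregate_window(s, (a, b), 2005, stat)
            expected = np.mean([
                s[col].to_numpy()[i]
                for i in range(len(s)) if a <= doy[i] <= b
            ])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_tmean_prefers_explicit_column(self):
        s = daily_series(n=20)
        s["tmean"] = 99.0
        assert aggregate_window(s, (5, 10), 2005, "mean_tmean") == 99.0

    def test_leap_day_participates(self):
        s = daily_series(year=2004, n=366)
        s["tmin"] = 1.0
        # window spanning Feb 29 (doy 60 in 2004)
        assert aggregate_window(s, (59, 61), 2004, "mean_tmin") == 1.0


class TestSeasonWindows:
    def test_windows_derived_from_pooled_phenology(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "species": "sp",
            "season": ["spring"] * 40 + ["autumn"] * 40,
            "ordinal_date": np.r_[rng.normal(130, 5, 40).round(),
                                  rng.normal(280, 8, 40).round()],
        })
        win = season_windows(df)["sp"]
        s0, s1 = win.spring_window
        assert 115 < s0 < 130 < s1 < 145
        assert win.prebreeding_window == (s1 + 1, s1 + 30)
        a0, a1 = win.autumn_window
        assert 260 < a0 < 280 < a1 < 300

    def test_autumn_only_species_has_no_spring_window(self):
        df = pd.DataFrame({"species": "sp", "season": ["autumn"] * 5,
                           "ordinal_date": [270, 275, 280, 285, 290]})
        win = season_windows(df)["sp"]
        assert win.spring_window is None
        assert win.prebreeding_window is None
        assert win.autumn_window is not None


class TestBuildCovariateTable:
    def seasonal(self, values, species="sp", term="breeding_temp"):
        return pd.DataFrame([
            (species, year, term, v) for year, v in values.items()
        ], columns=["species", "year", "term", "value"])

    def test_two_year_scaling(self):
        sv = self.seasonal({2000: 0.0, 2001: 2.0})
        spec = ModelSpec("HY", [CovariateTerm("breeding_temp")])
        G = build_covariate_table(sv, spec, [2000, 2001])
        col = G.table["breeding_temp"].to_numpy()
        np.testing.assert_allclose(col, [-1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_constant_column_and_year_monotone(self):
        sv = self.seasonal({y: float(y % 7) for y in range(2000, 2010)})
        spec = ModelSpec("HY", [CovariateTerm("breeding_temp")])
        G = build_covariate_table(sv, spec, range(2000, 2010))
        assert (G.table["const"] == 1.0).all()
        years = G.table["year"].to_numpy()
        assert (np.diff(years) > 0).all()

    def test_per_species_standardization(self):
        rng = np.random.default_rng(5)
        frames = [self.seasonal({y: rng.normal() for y in range(2000, 2012)},
                                species=s) for s in ("a", "b")]
        sv = pd.concat(frames, ignore_index=True)
        spec = ModelSpec("HY", [CovariateTerm("breeding_temp")])
        G = build_covariate_table(sv, spec, range(2000, 2012))
        for sp in ("a", "b"):
            block = G.table.loc[sp]
            for col in ("breeding_temp", "year"):
                assert abs(block[col].mean()) < 1e-8
                assert abs(block[col].std(ddof=1) - 1) < 1e-8

    def test_unresolvable_lag_names_the_row(self):
        sv = self.seasonal({2000: 1.0, 2001: 2.0})
        spec = ModelSpec("HY", [CovariateTerm("breeding_temp", lag=1)])
        with pytest.raises(ValueError, match="breeding_temp_lag1"):
            build_covariate_table(sv, spec, [2000, 2001])

    def test_lag_shift_invariance(self):
        """Shifting the climate series one year forward while adding one to
        every lag leaves G bitwise unchanged."""
        rng = np.random.default_rng(6)
        vals = {y: rng.normal() for y in range(1999, 2012)}
        sv0 = self.seasonal(vals)
        # moving the series one year earlier while deepening the lag by one
        # reads exactly the same raw values
        sv_shift = self.seasonal({y - 1: v for y, v in vals.items()})
        years = range(2002, 2011)
        g0 = build_covariate_table(
            sv0, ModelSpec("HY", [CovariateTerm("breeding_temp", lag=1)]),
            years).matrix()
        g1 = build_covariate_table(
            sv_shift, ModelSpec("HY", [CovariateTerm("breeding_temp", lag=2)]),
            years).matrix()
        assert np.array_equal(g0, g1)

    def test_default_specs_resolve(self):
        for pop in ("HY", "AHY_spring", "AHY_autumn"):
            spec = ModelSpec.default(pop)
            assert spec.column_names[0] == "const"
            assert spec.column_names[-1] == "year"
            assert spec.max_lag >= 1
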