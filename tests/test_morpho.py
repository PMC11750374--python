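import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wingallometry.morpho import (
    ScalingParams, log_and_scale, mad_outlier_mask, prepare_dataset,
)

from _oracles import mad_keep_mask_bruteforce


def make_records(n, species="junco", season="autumn", age="HY", rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "species": species,
        "year": rng.integers(1990, 2010, n),
        "ordinal_date": rng.integers(250, 300, n),
        "season": season,
        "age_class": age,
        "sex": rng.choice(["female", "male"], n),
        "tarsus_mm": 20 + rng.normal(0, 0.5, n),
        "wing_mm": 68 + rng.normal(0, 1.5, n),
    })


class TestMadOutlierMask:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4, 100], [True, True, True, True, False]),
        ([5, 5, 5, 5], [True, True, True, True]),
        ([0], [True]),
    ])
    def test_examples(self, values, expected):
        assert mad_outlier_mask(values).tolist() == expected

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mad_outlier_mask([])
        with pytest.raises(ValueError, match="indices"):
            mad_outlier_mask([1.0, np.nan, 3.0])
        with pytest.raises(ValueError):
            mad_outlier_mask([1.0, 2.0], k=0)

    def test_matches_bruteforce_on_random_vectors(self, rng):
        """The vectorized mask agrees with an independent loop-and-sort
        recomputation on 1,000 random vectors."""
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            vals = rng.normal(0, rng.uniform(0.5, 10), n)
            if rng.random() < 0.3:  # occasionally inject gross outliers
                vals[rng.integers(n)] *= 50
            assert mad_outlier_mask(vals).tolist() == \
                mad_keep_mask_bruteforce(vals)

    def test_scaled_variant_is_wider(self, rng):
        vals = rng.normal(size=200)
        raw = mad_outlier_mask(vals, k=2)
        scaled = mad_outlier_mask(vals, k=2, scaled=True)
        assert scaled.sum() >= raw.sum()


class TestLogAndScale:
    def test_single_group_symmetric(self):
        scaled, params = log_and_scale(np.exp([1.0, 2.0, 3.0]),
                                       ["a"] * 3, "tarsus")
        np.testing.assert_allclose(scaled, [-1, 0, 1], atol=1e-12)
        assert params[0].log_mean == pytest.approx(2.0)
        assert params[0].log_sd == pytest.approx(1.0)

    def test_two_groups_scaled_separately(self):
        vals = np.exp([1.0, 3.0, 1.0, 3.0])
        scaled, params = log_and_scale(vals, ["a", "a", "b", "b"])
        expected = 1 / np.sqrt(2)
        np.testing.assert_allclose(scaled, [-expected, expected] * 2,
                                   atol=1e-12)
        assert [p.species_id for p in params] == ["a", "b"]

    def test_errors(self):
        with pytest.raises(ValueError, match="degenerate group"):
            log_and_scale([2.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError, match="non-positive"):
            log_and_scale([1.0, -1.0], ["a", "a"])
        with pytest.raises(ValueError, match="fewer than 2"):
            log_and_scale([1.0], ["a"])

    @given(st.lists(st.floats(min_value=1.0, max_value=1e3), min_size=2,
                    max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovers_log_values(self, values):
        scaled, (p,) = log_and_scale(values, ["g"] * len(values))
        np.testing.assert_allclose(p.inverse_log(scaled), np.log(values),
                                   atol=1e-12)

    def test_scaling_params_reject_nonpositive_sd(self):
        with pytest.raises(ValueError):
            ScalingParams("a", "wing", 4.0, 0.0)


class TestPrepareDataset:
    def test_outlier_dropped_per_species_on_raw_tarsus(self):
        df = make_records(5)
        df["tarsus_mm"] = [20, 21, 22, 21, 80]
        df["wing_mm"] = [68, 67, 69, 68, 68.5]
        out = prepare_dataset(df)
        assert out.n_dropped_outliers == 1
        assert len(out.records) == 4
        # oracle agreement on the raw tarsus vector
        assert mad_keep_mask_bruteforce(df["tarsus_mm"]) == \
            [True, True, True, True, False]

    def test_spring_hy_record_rejected(self):
        df = make_records(3, season="spring", age="HY")
        with pytest.raises(ValueError, match="spring"):
            prepare_dataset(df)

    def test_clean_input_passes_through(self):
        df = make_records(50)
        out = prepare_dataset(df)
        assert out.n_dropped_outliers == 0
        assert out.n_dropped_missing == 0
        assert len(out.records) == 50

    def test_missing_fields_counted(self):
        df = make_records(10)
        df.loc[0, "sex"] = np.nan
        df.loc[1, "wing_mm"] = np.nan
        out = prepare_dataset(df)
        assert out.n_dropped_missing == 2
        assert len(out.records) == 8

    def test_population_assignment(self):
        rng = np.random.default_rng(1)
        df = pd.concat([
            make_records(10, season="autumn", age="HY", rng=rng),
            make_records(10, season="spring", age="AHY", rng=rng),
            make_records(10, season="autumn", age="AHY", rng=rng),
        ], ignore_index=True)
        out = prepare_dataset(df)
        assert set(out.records["population"]) == {"HY", "AHY_spring",
                                                  "AHY_autumn"}
        counts = out.records["population"].value_counts()
        assert counts.eq(10).all()

    def test_per_species_standardization_invariant(self):
        rng = np.random.default_rng(2)
        df = pd.concat([make_records(80, species=s, rng=rng)
                        for s in ("a", "b", "c")], ignore_index=True)
        out = prepare_dataset(df)
        for _, grp in out.records.groupby("species"):
            for col in ("z", "w"):
                assert abs(grp[col].mean()) < 1e-8
                assert abs(grp[col].std(ddof=1) - 1) < 1e-8

    def test_single_pass_filter_keeps_survivors(self):
        """The MAD filter is single-pass: re-preparing the survivors (on the
        original mm scale) drops nothing when they sit inside their own
        recomputed window."""
        rng = np.random.default_rng(3)
        df = make_records(200, rng=rng)
        # bounded (uniform) measurements cannot trip the 5-MAD screen ...
        df["tarsus_mm"] = 20 + rng.uniform(-1, 1, len(df))
        df["wing_mm"] = 68 + rng.uniform(-2, 2, len(df))
        # ... except the one gross outlier we inject
        df.loc[0, "tarsus_mm"] = 80.0
        first = prepare_dataset(df)
        survivors = df[df["tarsus_mm"] < 80.0]
        second = prepare_dataset(survivors)
        assert first.n_dropped_outliers == 1
        assert second.n_dropped_outliers == 0
        assert len(second.records) == len(first.records)

    def test_tiny_species_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        df = pd.concat([make_records(30, species="big", rng=rng),
                        make_records(1, species="lone", rng=rng)],
                       ignore_index=True)
        with caplog.at_level("WARNING"):
            out = prepare_dataset(df)
        assert set(out.records["species"]) == {"big"}
        assert "lone" in caplog.text

    def test_scaling_roundtrip_through_params(self):
        df = make_records(40)
        out = prepare_dataset(df)
        p = out.scaling_for("junco", "tarsus")
        logs = p.inverse_log(out.records["z"].to_numpy())
        np.testing.assert_allclose(np.sort(np.exp(logs)),
                                   np.sort(df["tarsus_mm"].to_numpy()),
                                   rtol=1e-10)
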