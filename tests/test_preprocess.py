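"""Scoring, encoding, filter and standardization tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lockwell as lw
from lockwell.preprocess import (
    TIME_COLUMN,
    design_from_arrays,
    encode_predictors,
)


class TestWemwbsScoring:
    @pytest.mark.parametrize(
        "items,total",
        [
            ([1] * 14, 14),
            ([5] * 14, 70),
            ((3, 3, 3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4, 4), 49),
        ],
    )
    def test_sum_scoring(self, items, total):
        assert lw.score_wemwbs(items) == total

    def test_wrong_item_count(self):
        with pytest.raises(lw.ValidationError, match="14"):
            lw.score_wemwbs([3] * 13)

    def test_out_of_range_item_names_index(self):
        items = [3] * 14
        items[6] = 6
        with pytest.raises(lw.ValidationError, match="item 6"):
            lw.score_wemwbs(items)

    @given(st.lists(st.integers(1, 5), min_size=14, max_size=14))
    @settings(max_examples=50, deadline=None)
    def test_total_always_in_scale_range(self, items):
        assert 14 <= lw.score_wemwbs(items) <= 70


class TestEncoding:
    def test_categorical_reference_coding_drops_reference(self):
        schema = lw.PredictorSchema((
            lw.Predictor("education", "categorical",
                         ("up to 12y", "12-14y", "14y-bach", "bach-masters",
                          "masters+")),
        ))
        table = pd.DataFrame({
            "education": ["up to 12y", "12-14y", "masters+"],
            "days": [0, 1, 2],
            "wemwbs": [40, 50, 60],
        })
        d = lw.encode_design(table, schema)
        edu_cols = [c for c in d.columns if c.startswith("education")]
        assert len(edu_cols) == 4
        assert "education[up to 12y]" not in d.columns
        # reference-level row encodes as all zeros
        assert d.X.loc[0, edu_cols].sum() == 0

    def test_all_no_binary_gives_zero_column(self):
        schema = lw.PredictorSchema((lw.Predictor("pet", "binary"),))
        table = pd.DataFrame({"pet": ["no"] * 5, "days": range(5),
                              "wemwbs": [50] * 5})
        d = lw.encode_design(table, schema)
        assert (d.X["pet"] == 0).all()

    def test_three_level_dummy_matrix_matches_hand_enumeration(self):
        schema = lw.PredictorSchema((
            lw.Predictor("area", "categorical", ("urban", "semi", "rural")),
        ))
        table = pd.DataFrame({"area": ["semi", "urban", "rural"],
                              "days": [0, 0, 0], "wemwbs": [50, 50, 50]})
        d = lw.encode_design(table, schema)
        expected = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(
            d.X[["area[semi]", "area[rural]"]].to_numpy(), expected
        )

    def test_unseen_level_error_names_predictor_and_level(self):
        schema = lw.PredictorSchema((lw.Predictor("pet", "binary"),))
        table = pd.DataFrame({"pet": ["maybe"], "days": [0], "wemwbs": [50]})
        with pytest.raises(lw.SchemaError, match="pet.*maybe"):
            lw.encode_design(table, schema)

    def test_column_order_follows_schema_order(self, toy_survey):
        schema = lw.PredictorSchema((
            lw.Predictor("mood", "likert"), lw.Predictor("flag", "binary"),
        ))
        d = lw.encode_design(toy_survey, schema)
        assert d.columns == [TIME_COLUMN, "mood", "flag"]


class TestInteractions:
    def schema(self):
        return lw.PredictorSchema((
            lw.Predictor("flag", "binary"), lw.Predictor("mood", "likert"),
        ))

    def test_one_interaction_per_main_and_none_for_time(self, toy_survey):
        d = lw.add_time_interactions(lw.encode_design(toy_survey, self.schema()))
        inter = d.meta.index[d.meta["role"] == "interaction"]
        assert list(inter) == ["flag:days", "mood:days"]
        assert "days:days" not in d.columns

    def test_zero_time_gives_zero_interactions(self, toy_survey):
        t = toy_survey.copy()
        t["days"] = 0
        d = lw.add_time_interactions(lw.encode_design(t, self.schema()))
        assert (d.X[["flag:days", "mood:days"]] == 0).all().all()

    def test_products_match_brute_force_recomputation(self, toy_survey, rng):
        d = lw.add_time_interactions(lw.encode_design(toy_survey, self.schema()))
        for c in ("flag", "mood"):
            np.testing.assert_array_equal(
                d.X[f"{c}:days"].to_numpy(),
                d.X[c].to_numpy() * d.X["days"].to_numpy(),
            )

    def test_missing_time_column_is_structural_error(self, rng):
        d = design_from_arrays(rng.normal(size=(10, 2)), rng.normal(size=10))
        with pytest.raises(lw.SchemaError):
            lw.add_time_interactions(d)


class TestNearZeroVariance:
    def make(self, col):
        X = pd.DataFrame({"days": np.arange(len(col)) % 7, "v": col})
        d = design_from_arrays(X, np.zeros(len(col)), time_column="days")
        return d

    def test_constant_column_removed(self):
        filtered, log = lw.filter_near_zero_variance(self.make([3.0] * 50))
        assert "v" not in filtered.columns
        assert log.iloc[0]["reason"] == "constant"

    def test_rare_binary_removed_with_both_statistics_logged(self):
        col = np.r_[np.zeros(990), np.ones(10)]
        filtered, log = lw.filter_near_zero_variance(self.make(col))
        assert "v" not in filtered.columns
        row = log.set_index("column").loc["v"]
        assert row["freq_ratio"] == pytest.approx(99.0)
        assert row["unique_pct"] == pytest.approx(0.2)

    def test_balanced_binary_retained(self):
        col = np.r_[np.zeros(500), np.ones(500)]
        filtered, log = lw.filter_near_zero_variance(self.make(col))
        assert "v" in filtered.columns and log.empty

    def test_filter_is_idempotent(self, rng):
        col = np.r_[np.zeros(990), np.ones(10)]
        X = pd.DataFrame({
            "days": np.arange(1000) % 7,
            "v": col,
            "w": rng.integers(0, 2, 1000).astype(float),
        })
        d = design_from_arrays(X, np.zeros(1000), time_column="days")
        once, _ = lw.filter_near_zero_variance(d)
        twice, log2 = lw.filter_near_zero_variance(once)
        assert once.columns == twice.columns and log2.empty


class TestCorrelationFilter:
    def test_duplicated_column_loses_exactly_one(self, rng):
        x = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        d = design_from_arrays(X, np.zeros(200))
        filtered, log = lw.filter_correlated(d)
        assert len(filtered.columns) == 2 and len(log) == 1
        assert log.iloc[0]["column"] in ("a", "b")

    def test_member_with_larger_mean_abs_correlation_removed(self, rng):
        """corr(A,B)~0.95, corr(A,C)~0.5, corr(B,C)~0.25: A has the larger
        mean absolute correlation (~0.725 vs ~0.6) and is removed."""
        n = 4000
        target = np.array([[1.0, 0.95, 0.5], [0.95, 1.0, 0.25], [0.5, 0.25, 1.0]])
        L = np.linalg.cholesky(target)
        Z = rng.normal(size=(n, 3)) @ L.T
        d = design_from_arrays(pd.DataFrame(Z, columns=["A", "B", "C"]),
                               np.zeros(n))
        filtered, log = lw.filter_correlated(d, threshold=0.9)
        assert list(log["column"]) == ["A"]
        assert filtered.columns == ["B", "C"]

    def test_uncorrelated_design_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        d = design_from_arrays(X, np.zeros(300))
        filtered, log = lw.filter_correlated(d)
        assert filtered.columns == list("abcd") and log.empty

    def test_time_column_survives_and_partner_is_dropped(self, rng):
        t = rng.integers(0, 49, 500).astype(float)
        X = pd.DataFrame({"days": t, "shadow": t + rng.normal(0, 0.1, 500)})
        d = design_from_arrays(X, np.zeros(500), time_column="days")
        filtered, log = lw.filter_correlated(d)
        assert "days" in filtered.columns and "shadow" not in filtered.columns

    def test_filter_is_idempotent(self, rng):
        x = rng.normal(size=300)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.05, 300),
                          "c": rng.normal(size=300)})
        d = design_from_arrays(X, np.zeros(300))
        once, _ = lw.filter_correlated(d)
        twice, log2 = lw.filter_correlated(once)
        assert once.columns == twice.columns and log2.empty


class TestStandardize:
    def test_unit_scale_and_centered_outcome(self, toy_survey):
        schema = lw.PredictorSchema((
            lw.Predictor("flag", "binary"), lw.Predictor("mood", "likert"),
        ))
        d = lw.standardize(lw.add_time_interactions(
            lw.encode_design(toy_survey, schema)))
        arr = d.X.to_numpy()
        assert np.abs(arr.mean(axis=0)).max() < 1e-10
        non_time = d.meta["role"] != "time"
        assert np.abs(arr[:, non_time.to_numpy()].std(axis=0) - 1).max() < 1e-10
        assert abs(d.y.mean()) < 1e-10
        assert d.meta.loc["days", "scale"] == 1.0  # per-day units preserved

    def test_round_trip_destandardize(self, toy_survey):
        schema = lw.PredictorSchema((lw.Predictor("mood", "likert"),))
        d0 = lw.encode_design(toy_survey, schema)
        d1 = lw.destandardize(lw.standardize(d0))
        np.testing.assert_allclose(d1.X.to_numpy(), d0.X.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(d1.y, d0.y, atol=1e-12)

    def test_zero_variance_column_is_structural_error(self):
        X = pd.DataFrame({"days": [0.0, 1, 2, 3], "v": [1.0, 1, 1, 1]})
        d = design_from_arrays(X, np.arange(4.0), time_column="days")
        with pytest.raises(lw.ValidationError, match="zero-variance"):
            lw.standardize(d)
        lenient = lw.standardize(d, strict=False)
        assert (lenient.X["v"] == 0).all()

def test_penalty_scale_sensitivity(rng):
    """Ridge on standardized columns differs from ridge on raw columns
    unless the raw scales are 1: the penalty is not scale-equivariant."""
    n = 200
    x_raw = rng.normal(scale=5.0, size=n)
    y = 2.0 * x_raw + rng.normal(size=n)
    d = design_from_arrays(pd.DataFrame({"x": x_raw}), y)
    fit = lw.fit_ridge(lw.standardize(d), lam=50.0)
    xc = x_raw - x_raw.mean()
    yc = y - y.mean()
    beta_raw_penalty = float(xc @ yc / (xc @ xc + 50.0))
    assert abs(fit.coef["x"] - beta_raw_penalty) > 1e-3

    x_unit = (x_raw - x_raw.mean()) / x_raw.std()
    y2 = 2.0 * x_unit + rng.normal(size=n)
    d2 = design_from_arrays(pd.DataFrame({"x": x_unit}), y2)
    fit2 = lw.fit_ridge(lw.standardize(d2), lam=50.0)
    xc2, yc2 = x_unit - x_unit.mean(), y2 - y2.mean()
    expected = float(xc2 @ yc2 / (xc2 @ xc2 + 50.0))
    assert fit2.coef["x"] == pytest.approx(expected, abs=1e-10)
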