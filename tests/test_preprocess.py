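import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cardiopso.exceptions import DomainError, SchemaError
from cardiopso.preprocess import (
    OutlierBounds,
    drop_duplicates,
    impute_outliers_median,
    iqr_bounds,
    pad_interpolate,
    pearson_correlation,
    robust_scale,
    run_pipeline,
)


def _col_df(values):
    return pd.DataFrame({"x": values})


class TestPadInterpolate:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([3, np.nan, 5], [3, 3, 5]),
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
            ([7, np.nan, np.nan, 2], [7, 7, 7, 2]),  # forward scan fills runs
        ],
    )
    def test_forward_fill(self, values, expected):
        out = pad_interpolate(_col_df(values))
        assert out["x"].tolist() == expected

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=50)
        mask = rng.uniform(size=50) < 0.3
        mask[0] = False
        values[mask] = np.nan
        out = pad_interpolate(_col_df(values))["x"].to_numpy()
        # independent forward-scan oracle
        expected = values.copy()
        last = expected[0]
        for i in range(len(expected)):
            if np.isnan(expected[i]):
                expected[i] = last
            else:
                last = expected[i]
        np.testing.assert_array_equal(out, expected)

    def test_leading_missing_names_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "chol": [np.nan, 3.0]})
        with pytest.raises(SchemaError, match="chol"):
            pad_interpolate(df)

    def test_idempotent(self):
        df = _col_df([1.0, np.nan, 4.0, np.nan])
        once = pad_interpolate(df)
        pd.testing.assert_frame_equal(pad_interpolate(once), once)


class TestDropDuplicates:
    def test_two_identical_rows(self):
        df = pd.DataFrame({"a": [1, 1], "b": [2, 2]})
        out, removed = drop_duplicates(df)
        assert len(out) == 1 and removed == 1

    def test_all_distinct_unchanged(self):
        df = pd.DataFrame({"a": range(5)})
        out, removed = drop_duplicates(df)
        assert removed == 0
        pd.testing.assert_frame_equal(out, df)

    def test_triplicated_base(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        stacked = pd.concat([base] * 3, ignore_index=True)
        out, removed = drop_duplicates(stacked)
        assert len(out) == 10 and removed == 20
        # set-based oracle: the distinct row tuples
        assert {tuple(r) for r in out.itertuples(index=False)} == {
            tuple(r) for r in base.itertuples(index=False)
        }

    def test_keeps_first_occurrence_order(self):
        df = pd.DataFrame({"a": [3, 1, 3, 2, 1]})
        out, removed = drop_duplicates(df)
        assert out["a"].tolist() == [3, 1, 2] and removed == 2


class TestIqrBounds:
    def test_direct_substitution(self):
        b = OutlierBounds.from_quartiles(10.0, 20.0)
        assert b.lower == -5.0 and b.upper == 35.0

    def test_constant_column(self):
        b = iqr_bounds([4.0] * 7)
        assert b.q1 == b.q3 == b.lower == b.upper == 4.0 and b.iqr == 0.0

    def test_type7_quartiles(self):
        # sorted-order oracle: [1,2,3,4,100] -> Q1 = 2, Q3 = 4 under
        # linear interpolation between order statistics
        b = iqr_bounds([1, 2, 3, 4, 100])
        assert (b.q1, b.q3, b.lower, b.upper) == (2.0, 4.0, -1.0, 7.0)

    def test_fence_width_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            b = iqr_bounds(rng.normal(size=rng.integers(2, 40)))
            assert b.lower <= b.q1 <= b.q3 <= b.upper
            assert b.upper - b.lower == pytest.approx(4.0 * b.iqr)

    def test_empty_column_rejected(self):
        with pytest.raises(DomainError):
            iqr_bounds([])


class TestImputeOutliersMedian:
    def test_single_outlier(self):
        out, n = impute_outliers_median([1, 2, 3, 4, 100])
        assert out.tolist() == [1, 2, 3, 4, 3] and n == 1

    @pytest.mark.parametrize("values", [[1, 2, 3, 4, 5], [5.0] * 6])
    def test_inliers_untouched(self, values):
        out, n = impute_outliers_median(values)
        assert n == 0
        np.testing.assert_array_equal(out, np.asarray(values, dtype=float))

    def test_idempotent_and_counts_outside(self):
        # gross outliers well beyond the fence of a bounded bulk: the
        # regime median imputation targets, where a second pass is a
        # no-op because the fence stays clear of the bulk
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.uniform(0, 10, size=200), [40.0, -40.0, 55.0]])
        bounds = iqr_bounds(values)
        out, n = impute_outliers_median(values)
        assert n == int((~bounds.contains(values)).sum())
        assert bounds.contains(out).all()
        # in-bound values unchanged
        inside = bounds.contains(values)
        np.testing.assert_array_equal(out[inside], values[inside])
        out2, n2 = impute_outliers_median(out)
        assert n2 == 0
        np.testing.assert_array_equal(out2, out)


class TestRobustScale:
    def test_linear_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0], "target": [0.0] * 5})
        out, params = robust_scale(df)
        assert out["x"].tolist() == [-1.0, -0.5, 0.0, 0.5, 1.0]
        assert params.median["x"] == 3.0 and params.iqr["x"] == 2.0

    def test_median_value_maps_to_zero(self):
        df = pd.DataFrame({"x": [10.0, 20.0, 30.0], "target": [0.0, 1.0, 0.0]})
        out, _ = robust_scale(df)
        assert out["x"].iloc[1] == 0.0

    def test_constant_column_flagged_not_scaled(self):
        df = pd.DataFrame({"x": [7.0] * 4, "target": [0.0, 1.0, 0.0, 1.0]})
        out, params = robust_scale(df)
        assert params.degenerate == ("x",)
        assert out["x"].tolist() == [7.0] * 4

    def test_target_never_scaled(self):
        df = pd.DataFrame({"x": [1.0, 5.0, 9.0], "target": [0.0, 1.0, 1.0]})
        out, params = robust_scale(df, columns=["x", "target"])
        assert out["target"].tolist() == [0.0, 1.0, 1.0]
        assert "target" not in params.columns

    def test_fit_subset_has_median0_iqr1(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(10, 3, 60), "target": rng.integers(0, 2, 60).astype(float)})
        fit_rows = df.index[:40]
        out, params = robust_scale(df, fit_on=fit_rows)
        fitted = out.loc[fit_rows, "x"].to_numpy()
        assert abs(np.median(fitted)) < 1e-9
        q1, q3 = np.quantile(fitted, [0.25, 0.75])
        assert abs((q3 - q1) - 1.0) < 1e-9


class TestPearsonCorrelation:
    def test_perfect_linear_relations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        arrays(np.float64, st.integers(3, 30), elements=st.floats(-100, 100)),
        st.randoms(use_true_random=False),
    )
    def test_symmetry_and_bounds(self, x, rnd):
        y = np.array([v + rnd.uniform(-50, 50) for v in x])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r = pearson_correlation(x, y)
        assert r == pytest.approx(pearson_correlation(y, x))
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = pearson_correlation(x, y)
        assert pearson_correlation(3.5 * x + 2.0, y) == pytest.approx(r)


class TestRunPipeline:
    def test_clean_table_only_scaling(self, tiny_table):
        table, _ = drop_duplicates(tiny_table)  # tiny_table has one duplicate pair
        out, log = run_pipeline(table)
        assert log.n_missing_filled == 0
        assert log.n_duplicates_removed == 0
        assert log.n_outliers_imputed == 0
        assert len(log.columns_scaled) + len(log.degenerate_columns) == 13

    def test_pipeline_counts_match_construction(self, tiny_table):
        table, _ = drop_duplicates(tiny_table)
        corrupted = table.copy()
        corrupted.iloc[2, corrupted.columns.get_loc("chol")] = np.nan
        corrupted.iloc[3, corrupted.columns.get_loc("thalach")] = np.nan
        corrupted = pd.concat([corrupted, corrupted.iloc[[0]]], ignore_index=True)
        out, log = run_pipeline(corrupted)
        assert log.n_missing_filled == 2
        assert log.n_duplicates_removed == 1

    def test_output_has_no_missing_or_duplicates(self, tiny_table):
        out, _ = run_pipeline(tiny_table)
        assert out.isna().sum().sum() == 0
        assert out.duplicated().sum() == 0

    def test_conserves_columns_and_target(self, tiny_table):
        table, _ = drop_duplicates(tiny_table)
        out, _ = run_pipeline(table)
        assert list(out.columns) == list(table.columns)
        assert out["target"].tolist() == table["target"].tolist()
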