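import numpy as np
import pytest

from cellrplr import (
    CellRPLR,
    GroupedDataMatrix,
    OutlyingnessFunctionSpec,
    get_function,
    logratio_slice,
    outlyingness_array_full,
    outlyingness_matrix,
    standardize_slice,
)
from conftest import random_grouped_matrix
from naive_oracle import naive_outlyingness_matrix


class TestLogratioSlice:
    def test_direct_values_and_diagonal(self, small_matrix):
        Y = logratio_slice(small_matrix, 2)
        assert np.all(Y[:, 2] == 0.0)
        i, k = 3, 0
        expected = np.log(small_matrix.values[i, 2] / small_matrix.values[i, k])
        assert Y[i, k] == pytest.approx(expected, abs=1e-12)

    def test_known_ratio(self):
        X = GroupedDataMatrix(values=[[8.0, 2.0], [3.0, 3.0], [1.0, 1.0], [2.0, 2.0]],
                              groups=["a", "a", "a", "b"])
        Y = logratio_slice(X, 0)
        assert Y[0, 1] == pytest.approx(np.log(4.0), abs=1e-12)
        assert Y[1, 1] == 0.0  # equal abundances

    def test_cross_slice_antisymmetry(self, small_matrix):
        Yj = logratio_slice(small_matrix, 1)
        Yk = logratio_slice(small_matrix, 3)
        np.testing.assert_array_equal(Yj[:, 3], -Yk[:, 1])

    def test_row_scaling_invariance(self, small_matrix):
        s = np.linspace(0.1, 9.0, small_matrix.n_samples)[:, None]
        scaled = GroupedDataMatrix(values=small_matrix.values * s,
                                   groups=small_matrix.groups)
        np.testing.assert_allclose(logratio_slice(scaled, 1),
                                   logratio_slice(small_matrix, 1), atol=1e-10)

    def test_out_of_range(self, small_matrix):
        with pytest.raises(IndexError):
            logratio_slice(small_matrix, 99)


class TestStandardizeSlice:
    def test_reference_column_mapping(self):
        # reference values (1..5): center 3, scale 1.483
        Y = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [3.0], [4.483]])
        groups = np.array(["r"] * 5 + ["c"] * 2)
        out = standardize_slice(Y, groups, reference="r")
        assert out.values[5, 0] == pytest.approx(0.0, abs=1e-12)
        assert out.values[6, 0] == pytest.approx(1.0, abs=1e-9)
        assert not out.degenerate_mask[0]

    def test_own_feature_column_forced_to_zero(self):
        Y = np.zeros((4, 3))
        Y[:, 0] = [1.0, 2.0, 3.0, 4.0]
        groups = np.array(["r", "r", "r", "c"])
        out = standardize_slice(Y, groups, reference="r", j=1)
        assert np.all(out.values[:, 1] == 0.0)
        assert not out.degenerate_mask[1]

    def test_degenerate_column_flagged_and_saturated(self):
        Y = np.array([[1.0], [1.0], [1.0], [5.0]])
        groups = np.array(["r", "r", "r", "c"])
        out = standardize_slice(Y, groups, reference="r")
        assert out.degenerate_mask[0]
        assert out.values[0, 0] == 0.0        # equals the center
        assert out.values[3, 0] == np.inf     # saturates downstream at +1

    def test_absent_reference(self):
        with pytest.raises(ValueError, match="absent"):
            standardize_slice(np.ones((3, 2)), ["a", "a", "b"], reference="z")


class TestOutlyingnessMatrix:
    def test_constant_matrix_gives_all_zeros(self):
        X = GroupedDataMatrix(values=np.full((6, 4), 3.7),
                              groups=["a"] * 4 + ["b"] * 2)
        W = outlyingness_matrix(X)
        np.testing.assert_array_equal(W.values, np.zeros((6, 4)))

    def test_two_features_median_halves_offdiagonal(self, ):
        X = random_grouped_matrix(n=7, d=2, n_ref=4, seed=3)
        est = CellRPLR(function="tukey").fit(X.values, X.groups)
        W = est.transform(X.values)
        slice0 = est.outlyingness_slice(X.values, 0)
        # median of (0, w*_i12) is their midpoint
        np.testing.assert_allclose(W[:, 0], slice0[:, 1] / 2.0, atol=1e-15)

    def test_matches_naive_oracle(self):
        for seed in (0, 7):
            X = random_grouped_matrix(n=8, d=5, n_ref=5, seed=seed)
            for family in ("tukey", "huber", "hampel"):
                spec = OutlyingnessFunctionSpec(family=family)
                W = outlyingness_matrix(X, spec, reference="ctrl")
                expected = naive_outlyingness_matrix(
                    X.values, X.groups, "ctrl", get_function(spec))
                np.testing.assert_array_equal(W.values, expected)

    def test_huge_cell_saturates_under_hampel(self):
        X = random_grouped_matrix(n=6, d=5, n_ref=4, seed=5)
        values = X.values.copy()
        values[4, 2] *= 1e6
        Xc = GroupedDataMatrix(values=values, groups=X.groups)
        spec = OutlyingnessFunctionSpec(family="hampel")
        W = outlyingness_matrix(Xc, spec, reference="ctrl").values
        assert W[4, 2] == 1.0
        expected = naive_outlyingness_matrix(values, X.groups, "ctrl",
                                             get_function(spec))
        np.testing.assert_array_equal(W, expected)

    def test_size_effect_invariance(self):
        X = random_grouped_matrix(n=9, d=6, n_ref=5, seed=1)
        rng = np.random.default_rng(2)
        s = rng.uniform(0.05, 20.0, size=(9, 1))
        Xs = GroupedDataMatrix(values=X.values * s, groups=X.groups)
        for family in ("tukey", "huber", "hampel"):
            spec = OutlyingnessFunctionSpec(family=family)
            W0 = outlyingness_matrix(X, spec).values
            W1 = outlyingness_matrix(Xs, spec).values
            np.testing.assert_allclose(W1, W0, atol=1e-10)

    def test_entries_bounded(self, small_matrix):
        for family in ("tukey", "huber", "hampel"):
            W = outlyingness_matrix(
                small_matrix, OutlyingnessFunctionSpec(family=family)).values
            assert np.all(W >= -1.0) and np.all(W <= 1.0)

    def test_exclude_diagonal_option(self, small_matrix):
        est = CellRPLR(include_diagonal=False).fit(small_matrix.values,
                                                   small_matrix.groups)
        W_no = est.transform(small_matrix.values)
        full = est.outlyingness_array(small_matrix.values)
        n, d = small_matrix.values.shape
        expected = np.empty((n, d))
        for j in range(d):
            expected[:, j] = np.median(np.delete(full[:, j, :], j, axis=1), axis=1)
        np.testing.assert_array_equal(W_no, expected)


class TestFullArray:
    def test_consistency_antisymmetry_diagonal(self, small_matrix):
        spec = OutlyingnessFunctionSpec(family="huber")
        A = outlyingness_array_full(small_matrix, spec)
        W = outlyingness_matrix(small_matrix, spec).values
        # aggregate(full array) == streaming output, elementwise
        np.testing.assert_array_equal(np.median(A, axis=2), W)
        # w*_ijk = -w*_ikj
        np.testing.assert_array_equal(A, -np.transpose(A, (0, 2, 1)))
        # diagonal slice j = k all zero
        n, d, _ = A.shape
        assert np.all(A[:, np.arange(d), np.arange(d)] == 0.0)

    def test_aggregating_second_index_reverses_sign(self, small_matrix):
        spec = OutlyingnessFunctionSpec(family="tukey")
        A = outlyingness_array_full(small_matrix, spec)
        W = outlyingness_matrix(small_matrix, spec).values
        np.testing.assert_array_equal(np.median(A, axis=1), -W)

    def test_element_budget_enforced(self, small_matrix):
        est = CellRPLR().fit(small_matrix.values, small_matrix.groups)
        with pytest.raises(MemoryError, match="streams"):
            est.outlyingness_array(small_matrix.values, element_budget=10)


class TestHuberCommutation:
    def test_median_and_monotone_function_commute(self):
        # with an odd number of aggregated values the median is an order
        # statistic, so a monotone function may be applied before or after
        X = random_grouped_matrix(n=8, d=5, n_ref=5, seed=13)
        est = CellRPLR(function="huber").fit(X.values, X.groups)
        W_standard = est.transform(X.values)  # function, then median
        func = get_function(OutlyingnessFunctionSpec(family="huber"))
        L = np.log(X.values)
        W_swapped = np.empty_like(W_standard)
        for j in range(X.n_features):
            U = est.standardized_slice(X.values, j).values
            W_swapped[:, j] = func(np.median(U, axis=1))  # median, then function
        np.testing.assert_array_equal(W_standard, W_swapped)


class TestSupervisionContract:
    def test_sample_permutation_permutes_rows(self, small_matrix):
        perm = np.random.default_rng(0).permutation(small_matrix.n_samples)
        Xp = GroupedDataMatrix(values=small_matrix.values[perm],
                               groups=small_matrix.groups[perm])
        W = outlyingness_matrix(small_matrix).values
        Wp = outlyingness_matrix(Xp).values
        # reference rows are summed in their (permuted) order, so agreement
        # is up to floating-point addition order
        np.testing.assert_allclose(Wp, W[perm], atol=1e-12)

    def test_relabeling_non_reference_sample_keeps_w(self, small_matrix):
        groups2 = small_matrix.groups.copy()
        groups2[-1] = "other"  # splits the non-reference group only
        X2 = GroupedDataMatrix(values=small_matrix.values, groups=groups2)
        np.testing.assert_array_equal(outlyingness_matrix(X2).values,
                                      outlyingness_matrix(small_matrix).values)

    def test_explicit_reference_group(self, small_matrix):
        W_auto = outlyingness_matrix(small_matrix)  # majority = ctrl
        W_ctrl = outlyingness_matrix(small_matrix, reference="ctrl")
        assert W_auto.reference_group == "ctrl"
        np.testing.assert_array_equal(W_auto.values, W_ctrl.values)
        W_case = outlyingness_matrix(small_matrix, reference="case")
        assert not np.array_equal(W_case.values, W_ctrl.values)


class TestEstimatorContract:
    def test_fit_validates_inputs(self, small_matrix):
        est = CellRPLR()
        with pytest.raises(ValueError, match="positive"):
            est.fit(small_matrix.values - 100.0, small_matrix.groups)
        with pytest.raises(ValueError, match="group label per sample"):
            est.fit(small_matrix.values, small_matrix.groups[:-1])

    def test_transform_checks_feature_count(self, small_matrix):
        est = CellRPLR().fit(small_matrix.values, small_matrix.groups)
        with pytest.raises(ValueError, match="features"):
            est.transform(small_matrix.values[:, :3])

    def test_get_set_params_roundtrip(self):
        est = CellRPLR(function="hampel", c1=1.5)
        params = est.get_params()
        est2 = CellRPLR().set_params(**params)
        assert est2.get_params() == params

    def test_fitted_attributes(self, small_matrix):
        est = CellRPLR().fit(small_matrix.values, small_matrix.groups)
        d = small_matrix.n_features
        assert est.centers_.shape == (d, d)
        np.testing.assert_array_equal(est.centers_, -est.centers_.T)
        np.testing.assert_array_equal(est.scales_, est.scales_.T)
        assert est.reference_group_ == "ctrl"
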