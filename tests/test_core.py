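"""Exact PLSC: standardization, cross-products, SVD fit, component selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from plscrp import (
    DataBlock,
    cross_product,
    cross_product_operator,
    explained_variance,
    plsc_fit,
    select_component,
    standardize,
)
from plscrp.core import DegenerateBlockError

from conftest import make_block, random_std_pair


class TestStandardize:
    def test_symmetric_column(self):
        out = standardize(make_block([[1, 5], [2, 5.5], [3, 7]]))
        np.testing.assert_allclose(out.values[:, 0], [-1, 0, 1], atol=1e-12)

    def test_idempotent(self, rng):
        once = standardize(make_block(rng.standard_normal((20, 5))))
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_zero_mean_unit_sd(self, rng):
        out = standardize(make_block(rng.standard_normal((30, 8)) * 5 + 3))
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_constant_column_dropped(self, rng):
        vals = rng.standard_normal((15, 5))
        vals[:, 2] = 3.0
        out = standardize(make_block(vals))
        assert out.n_variables == 4
        assert out.dropped_variables == ("v2",)
        assert "v2" not in out.variable_ids

    def test_all_constant_errors(self):
        with pytest.raises(DegenerateBlockError, match="degenerate"):
            standardize(make_block(np.ones((10, 3))))

    def test_missing_values_name_columns(self, rng):
        vals = rng.standard_normal((10, 4))
        vals[3, 1] = np.nan
        with pytest.raises(ValueError, match="v1"):
            standardize(make_block(vals))

    def test_duplicate_variable_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DataBlock(np.zeros((5, 2)), [f"s{i}" for i in range(5)], ["x", "x"])

    @given(arrays(float, (12, 4), elements=st.floats(-50, 50)))
    def test_property_standardized_or_degenerate(self, vals):
        block = make_block(vals + np.arange(12)[:, None] * 1e-3)
        try:
            out = standardize(block)
        except DegenerateBlockError:
            return
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-8)


class TestCrossProduct:
    def test_self_product_is_n_minus_one(self):
        b = standardize(make_block(np.arange(10.0)[:, None]))
        a = cross_product(b, b)
        np.testing.assert_allclose(a, [[9.0]], atol=1e-10)

    def test_orthogonal_columns_give_zero(self):
        z = standardize(make_block(
            np.column_stack([[1, -1, 1, -1.0], [1, 1, -1, -1.0]])))
        a = cross_product(z, z)
        assert abs(a[0, 1]) < 1e-10

    def test_matrix_free_matches_materialized(self):
        b1, b2 = random_std_pair(20, 5, 7, seed=3)
        a = cross_product(b1, b2)
        op = cross_product_operator(b1, b2)
        rng = np.random.default_rng(0)
        v = rng.standard_normal(7)
        u = rng.standard_normal(5)
        np.testing.assert_allclose(op @ v, a @ v, atol=1e-10)
        np.testing.assert_allclose(op.rmatvec(u), a.T @ u, atol=1e-10)
        np.testing.assert_allclose(op.total_squared_singular_values(),
                                   np.sum(np.linalg.svd(a, compute_uv=False)**2),
                                   rtol=1e-10)

    def test_sample_mismatch_errors(self):
        b1, _ = random_std_pair(20, 5, 7)
        b2, _ = random_std_pair(21, 5, 7)
        with pytest.raises(ValueError, match="sample"):
            cross_product(b1, b2)


class TestExplainedVariance:
    @pytest.mark.parametrize("s, expected", [
        ((3, 4), (0.36, 0.64)),
        ((1, 1), (0.5, 0.5)),
        ((7,), (1.0,)),
    ])
    def test_fractions(self, s, expected):
        np.testing.assert_allclose(explained_variance(np.array(s)), expected,
                                   atol=1e-12)

    def test_sums_to_one(self, rng):
        frac = explained_variance(rng.uniform(0.1, 5, size=9))
        assert abs(frac.sum() - 1) < 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            explained_variance(np.zeros(3))


class TestPlscFit:
    def test_matches_direct_svd_oracle(self):
        # block 2 is a column permutation of block 1: singular values of A
        # equal those of X1'X1, and score covariance equals s_i
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((30, 5))
        b1 = standardize(make_block(vals, "a"))
        b2 = standardize(make_block(vals[:, [3, 0, 4, 1, 2]], "b"))
        model = plsc_fit(b1, b2, n_components=5)
        expected = np.linalg.svd(b1.values.T @ b1.values, compute_uv=False)
        np.testing.assert_allclose(model.singular_values, expected, rtol=1e-8)
        cov = model.score_covariance()
        np.testing.assert_allclose(cov, model.singular_values, rtol=1e-8)

    def test_scalar_blocks(self):
        rng = np.random.default_rng(1)
        b1 = standardize(make_block(rng.standard_normal((12, 1)), "a"))
        b2 = standardize(make_block(rng.standard_normal((12, 1)), "b"))
        model = plsc_fit(b1, b2, n_components=1)
        assert model.n_components == 1
        np.testing.assert_allclose(abs(model.weights_1[0, 0]), 1)
        np.testing.assert_allclose(model.singular_values[0],
                                   abs(cross_product(b1, b2)[0, 0]), rtol=1e-10)

    def test_too_many_components_errors(self):
        b1, b2 = random_std_pair(20, 6, 4)
        with pytest.raises(ValueError, match="n_components"):
            plsc_fit(b1, b2, n_components=5)

    def test_rank_deficient_reports_rank(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((25, 2))
        vals = base @ rng.standard_normal((2, 6))  # rank 2 block
        b1 = standardize(make_block(vals, "a"))
        b2, _ = random_std_pair(25, 5, 3, seed=9)
        with pytest.raises(ValueError, match="rank is 2"):
            plsc_fit(b1, b2, n_components=4)

    def test_variance_target_smallest_m(self):
        b1, b2 = random_std_pair(40, 8, 6, seed=11)
        model = plsc_fit(b1, b2, variance_target=0.5)
        cum = np.cumsum(explained_variance(
            np.linalg.svd(cross_product(b1, b2), compute_uv=False)))
        assert model.n_components == np.searchsorted(cum, 0.5) + 1

    def test_svd_reconstruction(self):
        b1, b2 = random_std_pair(30, 6, 5, seed=4)
        m = plsc_fit(b1, b2, n_components=5)
        recon = (m.weights_1 * m.singular_values) @ m.weights_2.T
        np.testing.assert_allclose(recon, cross_product(b1, b2), atol=1e-8)

    def test_weight_columns_orthonormal(self):
        b1, b2 = random_std_pair(30, 7, 5, seed=6)
        m = plsc_fit(b1, b2, n_components=5)
        for w in (m.weights_1, m.weights_2):
            np.testing.assert_allclose(w.T @ w, np.eye(5), atol=1e-8)

    def test_sign_convention_deterministic(self):
        b1, b2 = random_std_pair(30, 6, 5, seed=8)
        m1 = plsc_fit(b1, b2, n_components=3)
        m2 = plsc_fit(b1, b2, n_components=3)
        np.testing.assert_array_equal(m1.weights_1, m2.weights_1)
        # largest-|entry| of each block-2 column is positive
        for i in range(3):
            j = np.argmax(np.abs(m1.weights_2[:, i]))
            assert m1.weights_2[j, i] > 0

    def test_eigendecomposition_oracle(self):
        # weights match a brute-force eigen-decomposition of A'A / AA'
        b1, b2 = random_std_pair(20, 6, 8, seed=13)
        a = cross_product(b1, b2)
        m = plsc_fit(b1, b2, n_components=5)
        evals1, evecs1 = np.linalg.eigh(a @ a.T)
        evals2, evecs2 = np.linalg.eigh(a.T @ a)
        for i in range(5):
            u = evecs1[:, np.argsort(evals1)[::-1][i]]
            v = evecs2[:, np.argsort(evals2)[::-1][i]]
            assert min(np.linalg.norm(m.weights_1[:, i] - u),
                       np.linalg.norm(m.weights_1[:, i] + u)) < 1e-8
            assert min(np.linalg.norm(m.weights_2[:, i] - v),
                       np.linalg.norm(m.weights_2[:, i] + v)) < 1e-8

    def test_matrix_free_path_matches_dense(self):
        b1, b2 = random_std_pair(25, 12, 9, seed=15)
        dense = plsc_fit(b1, b2, n_components=3)
        free = plsc_fit(b1, b2, n_components=3, memory_budget=10)
        np.testing.assert_allclose(free.singular_values, dense.singular_values,
                                   rtol=1e-8)
        np.testing.assert_allclose(np.abs(free.weights_2), np.abs(dense.weights_2),
                                   atol=1e-7)
        np.testing.assert_allclose(free.explained_fraction, dense.explained_fraction,
                                   rtol=1e-8)


class TestSelectComponent:
    def test_single_component_is_selected(self):
        b1, b2 = random_std_pair(40, 4, 1, seed=3)
        idx, oos = select_component(b1, b2, n_components=1, folds=5)
        assert idx == 0 and oos.shape == (1,)

    def test_fold_validation(self):
        b1, b2 = random_std_pair(12, 4, 3)
        with pytest.raises(ValueError):
            select_component(b1, b2, n_components=1, folds=13)
        with pytest.raises(ValueError):
            select_component(b1, b2, n_components=1, folds=1)
        with pytest.raises(ValueError, match="2\\*folds"):
            select_component(b1, b2, n_components=1, folds=10)

    def test_seeded_reproducibility(self):
        b1, b2 = random_std_pair(40, 6, 5, seed=21)
        _, oos1 = select_component(b1, b2, n_components=3, seed=5)
        _, oos2 = select_component(b1, b2, n_components=3, seed=5)
        np.testing.assert_array_equal(oos1, oos2)

    def test_causal_design_selects_first_component(self, causal_scenario):
        b1, b2, truth = causal_scenario
        idx, oos = select_component(b1, b2, variance_target=0.8, folds=10, seed=0)
        assert idx == 0
        assert oos[0] > 2 * max(abs(oos[1:]))

    def test_stronger_of_two_planted_signals_wins(self):
        # two orthogonal associations of very different strength: the
        # out-of-sample covariance ranks the strong one first
        rng = np.random.default_rng(17)
        n = 120
        g = rng.standard_normal((n, 2))
        x1 = rng.standard_normal((n, 6))
        x2 = rng.standard_normal((n, 8))
        x1[:, 0] = 0.9 * g[:, 0] + 0.45 * rng.standard_normal(n)  # strong
        x2[:, 0] = 0.9 * g[:, 0] + 0.45 * rng.standard_normal(n)
        x1[:, 1] = 0.4 * g[:, 1] + 0.92 * rng.standard_normal(n)  # weak
        x2[:, 1] = 0.4 * g[:, 1] + 0.92 * rng.standard_normal(n)
        b1 = standardize(make_block(x1, "a"))
        b2 = standardize(make_block(x2, "b"))
        idx, oos = select_component(b1, b2, n_components=2, folds=10, seed=1)
        assert idx == 0
        assert oos[0] > oos[1] > 0
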