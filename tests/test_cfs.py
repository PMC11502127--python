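from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwoselect.cfs import (CFSSelector, FeatureMask, MeritScore, cfs_select,
                           merit_score, pearson_correlation)
from gwoselect.preprocess import ExpressionMatrix
from gwoselect.synthetic import SyntheticConfig, make_microarray


def exhaustive_best_merit(X, y):
    """Independent oracle: merit of every non-empty subset via np.corrcoef."""
    p = X.shape[1]
    full = np.column_stack([X, y])
    C = np.abs(np.corrcoef(full, rowvar=False))
    C = np.nan_to_num(C)
    best, best_set = -np.inf, None
    for k in range(1, p + 1):
        for sub in combinations(range(p), k):
            mu_ic = C[list(sub), p].mean()
            if k == 1:
                mu_ii = 0.0
            else:
                mu_ii = np.mean([C[a, b] for a, b in combinations(sub, 2)])
            m = k * mu_ic / np.sqrt(k + k * (k - 1) * mu_ii)
            if m > best:
                best, best_set = m, sub
    return best, best_set


class TestPearson:
    @pytest.mark.parametrize("x,y,r", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ])
    def test_hand_values(self, x, y, r):
        assert pearson_correlation(x, y) == pytest.approx(r)

    def test_constant_vector_is_zero(self):
        assert pearson_correlation([1.0, 1.0, 1.0], [1, 2, 3]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1.0], [2.0])

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0),
           st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        r = pearson_correlation(x, y)
        assert pearson_correlation(y, x) == pytest.approx(r)
        assert pearson_correlation(scale * x + shift, y) == pytest.approx(r)
        assert pearson_correlation(-scale * x, y) == pytest.approx(-r)
        assert abs(r) <= 1 + 1e-12


class TestMeritScore:
    def test_formula_cases(self):
        assert MeritScore(1, 0.7, 0.0).merit == pytest.approx(0.7)
        assert MeritScore(2, 0.8, 1.0).merit == pytest.approx(0.8)
        assert MeritScore(3, 0.6, 0.2).merit == pytest.approx(1.8 / np.sqrt(4.2))

    def test_on_matrix_matches_components(self, toy_matrix):
        ms = merit_score(toy_matrix, FeatureMask([True, True, False]))
        assert ms.n_features == 2
        y = toy_matrix.labels.astype(float)
        r1 = abs(pearson_correlation(toy_matrix.values[:, 0], y))
        r2 = abs(pearson_correlation(toy_matrix.values[:, 1], y))
        assert ms.avg_feature_class_corr == pytest.approx((r1 + r2) / 2)

    def test_gene_permutation_invariance(self, toy_matrix):
        perm = [2, 0, 1]
        em = ExpressionMatrix(values=toy_matrix.values[:, perm],
                              labels=toy_matrix.labels)
        a = merit_score(toy_matrix, FeatureMask([True, False, True])).merit
        b = merit_score(em, FeatureMask([True, True, False])).merit
        assert a == pytest.approx(b)

    def test_empty_mask_errors(self, toy_matrix):
        with pytest.raises(ValueError):
            merit_score(toy_matrix, FeatureMask([False, False, False]))


class TestCfsSelect:
    def test_redundant_copy_yields_singleton(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        g1 = y + 0.05 * rng.standard_normal(20)
        g3 = rng.standard_normal(20)
        em = ExpressionMatrix(values=np.column_stack([g1, g1, g3]), labels=y)
        mask = cfs_select(em, max_features=3)
        assert mask.indices.tolist() == [0]
        best, best_set = exhaustive_best_merit(em.values, y.astype(float))
        assert mask.merit == pytest.approx(best)

    def test_noise_returns_best_singleton(self):
        rng = np.random.default_rng(3)
        em = ExpressionMatrix(values=rng.standard_normal((30, 8)),
                              labels=np.array([0, 1] * 15))
        mask = cfs_select(em, max_features=8, patience=3)
        assert mask.n_selected >= 1
        best, _ = exhaustive_best_merit(em.values, em.labels.astype(float))
        assert mask.merit <= best + 1e-9

    def test_greedy_near_exhaustive_optimum(self):
        """Greedy merit stays within 5% of brute force on small instances."""
        rng = np.random.default_rng(7)
        for _ in range(8):
            n, p = 25, rng.integers(4, 9)
            y = np.array([0, 1] * 13)[:n]
            X = rng.standard_normal((n, p))
            X[:, 0] += 1.2 * y  # one informative gene
            em = ExpressionMatrix(values=X, labels=y)
            mask = cfs_select(em, max_features=int(p), patience=int(p))
            best, _ = exhaustive_best_merit(X, y.astype(float))
            assert mask.merit >= 0.95 * best

    def test_planted_recovery(self):
        hits = []
        for seed in range(10):
            t = make_microarray(SyntheticConfig(
                n_samples=100, n_genes=50, n_informative=5, n_redundant=0,
                effect_size=2.0, seed=seed))
            mask = cfs_select(t.matrix, max_features=10)
            hits.append(len(set(t.informative_idx) & set(mask.indices)))
        assert np.median(hits) >= 4

    def test_zero_correlation_gene_never_helps(self):
        # a gene exactly orthogonal to the label: dropping it cannot
        # decrease the merit
        y = np.array([0, 0, 1, 1], dtype=float)
        g_inf = np.array([0.0, 0.1, 1.0, 0.9])
        g_null = np.array([1.0, -1.0, 1.0, -1.0])  # corr with y == 0
        em = ExpressionMatrix(values=np.column_stack([g_inf, g_null]),
                              labels=y.astype(int))
        with_null = merit_score(em, FeatureMask([True, True])).merit
        without = merit_score(em, FeatureMask([True, False])).merit
        assert without >= with_null

    def test_all_constant_matrix_errors(self):
        em = ExpressionMatrix(values=np.ones((6, 3)),
                              labels=np.array([0, 1] * 3))
        with pytest.raises(ValueError):
            cfs_select(em)

    def test_sklearn_selector_interface(self, planted_truth):
        sel = CFSSelector(max_features=10).fit(planted_truth.matrix.values,
                                               planted_truth.matrix.labels)
        Xt = sel.transform(planted_truth.matrix.values)
        assert Xt.shape == (planted_truth.matrix.n_samples,
                            sel.support_.sum())
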