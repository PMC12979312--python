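import itertools

import numpy as np
import pytest

from conftest import make_noiseless
from sparsesem import fit_cardinality, standardize
from sparsesem.cardinality import (
    CardinalityFactorAnalysis,
    OrthogonalityError,
    dense_loadings,
    hard_threshold_top,
    procrustes_scores,
)
from sparsesem.evaluate import align, recovery_rate
from sparsesem.lasso import update_scores


def orthogonal_scores(rng, n, q):
    u, _, vt = np.linalg.svd(rng.standard_normal((n, q)), full_matrices=False)
    return np.sqrt(n) * u @ vt


class TestDenseLoadings:
    def test_exact_inversion(self, rng):
        n, j, q = 12, 5, 2
        eta = orthogonal_scores(rng, n, q)
        P_true = rng.standard_normal((j, q))
        Y = eta @ P_true.T
        np.testing.assert_allclose(dense_loadings(Y, eta), P_true, atol=1e-10)

    def test_equals_pearson_correlations(self, small_standardized, rng):
        Y = small_standardized
        eta = procrustes_scores(Y, rng.standard_normal((6, 2)))
        P = dense_loadings(Y, eta)
        for j in range(Y.shape[1]):
            for q in range(2):
                r = np.corrcoef(Y[:, j], eta[:, q])[0, 1]
                assert P[j, q] == pytest.approx(r, abs=1e-10)

    def test_rejects_nonorthogonal_scores(self, small_standardized, rng):
        eta = rng.standard_normal((20, 2))  # not on the constraint set
        with pytest.raises(OrthogonalityError):
            dense_loadings(small_standardized, eta)


class TestHardThreshold:
    def test_full_cardinality_is_identity(self, rng):
        P = rng.standard_normal((4, 2))
        np.testing.assert_array_equal(hard_threshold_top(P, 8), P)

    def test_keeps_single_largest(self):
        P = np.array([[1.0, -3.0], [2.0, 0.5]])
        out = hard_threshold_top(P, 2)
        np.testing.assert_array_equal(out, [[0.0, -3.0], [2.0, 0.0]])

    def test_out_of_range_cardinality(self, rng):
        P = rng.standard_normal((4, 2))
        with pytest.raises(ValueError):
            hard_threshold_top(P, 1)  # below Q
        with pytest.raises(ValueError):
            hard_threshold_top(P, 9)  # above J*Q

    def test_tie_break_is_column_major(self):
        P = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = hard_threshold_top(P, 3)
        # first column and (0, 1) survive; (1, 1) is dropped
        np.testing.assert_array_equal(out, [[1.0, 1.0], [1.0, 0.0]])

    def test_matches_exhaustive_subset_search(self, rng):
        """Top-C magnitude = the reconstruction-optimal support of size C."""
        n, j, q, c = 15, 4, 2, 3
        Y = np.asarray(standardize(rng.standard_normal((n, j)))[0])
        eta = orthogonal_scores(rng, n, q)
        dense = dense_loadings(Y, eta)
        best_loss, best_mask = np.inf, None
        for support in itertools.combinations(range(j * q), c):
            P = np.zeros(j * q)
            P[list(support)] = dense.ravel()[list(support)]
            P = P.reshape(j, q)
            cur = np.sum((Y - eta @ P.T) ** 2)
            if cur < best_loss:
                best_loss, best_mask = cur, P != 0
        out = hard_threshold_top(dense, c)
        loss_out = np.sum((Y - eta @ out.T) ** 2)
        assert loss_out == pytest.approx(best_loss, rel=1e-12)
        np.testing.assert_array_equal(out != 0, best_mask)


class TestProcrustesScores:
    def test_recovers_generating_scores(self, rng):
        n, j, q = 15, 6, 2
        eta_true = orthogonal_scores(rng, n, q)
        P = rng.standard_normal((j, q))
        Y = eta_true @ P.T
        eta = procrustes_scores(Y, P)
        np.testing.assert_allclose(eta, eta_true, atol=1e-8)

    def test_constraint_satisfied(self, small_standardized, rng):
        eta = procrustes_scores(small_standardized, rng.standard_normal((6, 2)))
        n = small_standardized.shape[0]
        np.testing.assert_allclose(eta.T @ eta / n, np.eye(2), atol=1e-10)

    def test_single_factor_agrees_with_lasso_update(self, small_standardized):
        p = np.array([[0.4], [0.1], [-0.2], [0.7], [0.0], [0.3]])
        eta_card = procrustes_scores(small_standardized, p)
        eta_lasso = update_scores(small_standardized, p, np.ones((20, 1)))
        np.testing.assert_allclose(np.abs(eta_card), np.abs(eta_lasso), atol=1e-10)

    def test_rank_deficiency_warns(self, small_standardized):
        P = np.zeros((6, 2))
        P[0, 0] = 1.0  # second factor has zero loadings -> YP rank 1
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            procrustes_scores(small_standardized, P)


class TestFitCardinality:
    def test_full_cardinality_matches_truncated_svd(self, small_standardized):
        Y = small_standardized
        n, j = Y.shape
        fit = fit_cardinality(Y, 2, j * 2, n_starts=3, seed=0)
        svd_rss = (np.linalg.svd(Y, compute_uv=False) ** 2)[2:].sum()
        assert fit.loss_trace_[-1] == pytest.approx(svd_rss, rel=1e-6)

    def test_matches_exhaustive_pattern_enumeration(self, rng):
        """Global check on a 6-variable toy: alternating fits per support."""
        n, j, q, c = 20, 6, 2, 4
        Y = np.asarray(standardize(rng.standard_normal((n, j)))[0])
        best = np.inf
        for support in itertools.combinations(range(j * q), c):
            mask = np.zeros(j * q, dtype=bool)
            mask[list(support)] = True
            mask = mask.reshape(j, q)
            if (mask.sum(axis=0) == 0).any():
                continue  # empty factor: equivalent to a lower-Q pattern
            eta = orthogonal_scores(rng, n, q)
            prev = np.inf
            for _ in range(200):
                P = np.where(mask, Y.T @ eta / n, 0.0)
                eta = procrustes_scores(Y, P)
                cur = np.sum((Y - eta @ P.T) ** 2)
                if prev - cur < 1e-10 * prev:
                    break
                prev = cur
            best = min(best, cur)
        fit = fit_cardinality(Y, q, c, n_starts=30, seed=1)
        assert fit.loss_trace_[-1] == pytest.approx(best, rel=1e-6)

    def test_noiseless_oracle_cardinality_recovers_pattern(self):
        data = make_noiseless(q=3, k=3, n=40)
        fit = fit_cardinality(data.data, 3, data.truth.n_nonzero, n_starts=10, seed=0)
        aligned = align(fit.loadings_, data.truth.loadings_true)
        assert recovery_rate(aligned.loadings_aligned, data.truth.loadings_true) == 1.0
        assert aligned.per_factor_congruence.min() > 0.999

    def test_invariants_on_random_data(self, small_standardized):
        Y = small_standardized
        n = Y.shape[0]
        fit = fit_cardinality(Y, 2, 5, n_starts=5, seed=4)
        assert fit.n_nonzero_ <= 5
        np.testing.assert_allclose(fit.scores_.T @ fit.scores_ / n, np.eye(2), atol=1e-8)
        # nonzero loadings are exact item-score correlations
        for j, q in zip(*np.nonzero(fit.loadings_)):
            r = np.corrcoef(Y[:, j], fit.scores_[:, q])[0, 1]
            assert fit.loadings_[j, q] == pytest.approx(r, abs=1e-8)
        trace = fit.loss_trace_
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))
        assert trace[-1] <= trace[0] + 1e-9

    def test_pev_nondecreasing_in_cardinality(self, small_standardized):
        pevs = []
        warm = None
        for c in range(2, 13):
            est = CardinalityFactorAnalysis(
                n_factors=2, cardinality=c, n_starts=5, random_state=0
            )
            est.fit(small_standardized, warm_scores=warm)
            warm = [est.scores_]
            pevs.append(est.pev_)
        diffs = np.diff(pevs)
        assert np.all(diffs >= -1e-8)
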