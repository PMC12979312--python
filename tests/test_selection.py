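import numpy as np
import pytest

from conftest import make_noiseless
from sparsesem import (
    DesignCell,
    fit_lasso,
    index_of_sparseness,
    lambda_for_cardinality,
    lambda_max,
    make_grid,
    parallel_analysis,
    pev_model,
    pev_pca,
    select,
    simulate_cell,
    standardize,
)
from sparsesem.selection import SparsenessIndexSelector


class TestPev:
    def test_full_rank_pca_explains_everything(self, small_standardized):
        assert pev_pca(small_standardized, 6) == pytest.approx(1.0)

    def test_uncorrelated_columns_give_q_over_j(self):
        # Hadamard contrast columns: mean zero, +-1, mutually orthogonal
        Y = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        Y = np.asarray(standardize(Y)[0])
        assert pev_pca(Y, 2) == pytest.approx(2 / 3, abs=1e-10)

    def test_pev_model_bounds(self, small_standardized, rng):
        Y = small_standardized
        eta = rng.standard_normal((20, 2))
        P = rng.standard_normal((6, 2))
        assert pev_model(eta @ P.T, eta, P) == pytest.approx(1.0)
        assert pev_model(Y, eta, np.zeros((6, 2))) == pytest.approx(0.0)

    def test_model_never_beats_pca(self, small_standardized):
        fit = fit_lasso(small_standardized, 2, 2.0, n_starts=5, seed=0)
        assert fit.pev_ <= pev_pca(small_standardized, 2) + 1e-10

    def test_pev_pca_rejects_bad_q(self, small_standardized):
        with pytest.raises(ValueError):
            pev_pca(small_standardized, 7)


class TestIndexOfSparseness:
    @pytest.mark.parametrize(
        "args, expected",
        [((0.7, 0.9, 0.0), 0.0), ((1.0, 1.0, 0.5), 0.5), ((0.5, 0.4, 0.3), 0.06)],
    )
    def test_product(self, args, expected):
        assert index_of_sparseness(*args) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            index_of_sparseness(1.2, 0.5, 0.5)


class TestGrids:
    def test_cardinality_grid_bounds(self):
        grid = make_grid("cardinality", 3, 9, lower="3Q")
        assert grid == list(range(9, 28))
        grid = make_grid("cardinality", 5, 25, lower="3Q")
        assert grid[0] == 15 and grid[-1] == 125 and len(grid) == 111
        assert make_grid("cardinality", 2, 4, lower="Q")[0] == 2

    def test_lambda_grid_shape(self):
        grid = make_grid("lambda", 3, 9, N=50, n_points=17, lam_max=40.0)
        assert len(grid) == 17
        assert grid[0] == pytest.approx(5.0)
        assert grid[-1] == pytest.approx(40.0)
        assert np.all(np.diff(grid) > 0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            make_grid("cardinality", 3, 2, lower="3Q")
        with pytest.raises(ValueError):
            make_grid("lambda", 3, 9, N=50, lam_max=1.0)  # floor above ceiling


class TestLambdaMax:
    def test_fit_at_lambda_max_has_at_most_q_nonzeros(self):
        data = make_noiseless(q=2, k=3, n=30)
        lam = lambda_max(data.data, 2, n_starts=3, seed=0)
        fit = fit_lasso(data.data, 2, lam, n_starts=3, seed=0)
        assert fit.n_nonzero_ <= 2
        # slightly below the bracket, more loadings survive
        fit_lo = fit_lasso(data.data, 2, 0.9 * lam, n_starts=3, seed=0)
        assert fit_lo.n_nonzero_ > 2

    def test_dominant_variable_survives(self, rng):
        # one variable is (almost) the factor itself; it must be the survivor
        n = 60
        eta = rng.standard_normal((n, 1))
        raw = np.column_stack(
            [
                eta[:, 0] + 0.05 * rng.standard_normal(n),
                0.5 * eta[:, 0] + rng.standard_normal(n),
                0.4 * eta[:, 0] + rng.standard_normal(n),
            ]
        )
        lam = lambda_max(raw, 1, n_starts=3, seed=0)
        fit = fit_lasso(raw, 1, 0.999 * lam, n_starts=3, seed=0)
        nz = np.nonzero(fit.loadings_[:, 0])[0]
        assert 0 in nz and len(nz) <= 2


class TestSelect:
    def test_unique_maximizer_is_chosen_and_ties_break_sparser(self):
        data = make_noiseless(q=2, k=3, n=30)
        grid = make_grid("cardinality", 2, 6, lower="Q")
        result = select(data.data, 2, grid, "cardinality", n_starts=3, seed=0)
        frame = result.to_frame()
        # chosen candidate maximizes IS
        assert frame.loc[result.chosen, "is_value"] == pytest.approx(frame["is_value"].max())
        # noiseless data: IS is maximized exactly at the true count
        assert result.chosen_candidate.parameter_value == data.truth.n_nonzero
        np.testing.assert_allclose(
            frame["is_value"],
            frame["pev_pca"] * frame["pev_model"] * frame["ps"],
            atol=1e-12,
        )

    def test_is_selection_recovers_truth_at_large_n(self):
        cell = DesignCell(500, 3, 3, 0.0, 0.8, 0.0, 0.9)
        data = simulate_cell(cell, base_seed=11, replicate=0)
        grid = make_grid("cardinality", 3, 9, lower="3Q")
        result = select(
            data.data, 3, grid, "cardinality", n_starts=2, seed=0,
            assume_standardized=True,
        )
        assert result.chosen_candidate.parameter_value == data.truth.n_nonzero

    def test_empty_grid_rejected(self, small_standardized):
        with pytest.raises(ValueError):
            select(small_standardized, 2, [], "cardinality")

    def test_selector_estimator_wrapper(self, small_standardized):
        sel = SparsenessIndexSelector(
            method="cardinality", n_factors=2, grid=[4, 6, 8], n_starts=2, random_state=0
        ).fit(small_standardized)
        assert sel.best_value_ in (4, 6, 8)
        assert sel.candidates_.shape[0] == 3
        assert sel.best_estimator_.n_nonzero_ <= sel.best_value_


class TestLambdaForCardinality:
    def test_noiseless_fixture_hits_exact_count(self):
        data = make_noiseless(q=2, k=3, n=30)
        target = data.truth.n_nonzero
        lam = lambda_for_cardinality(data.data, 2, target, n_starts=3, seed=0)
        fit = fit_lasso(data.data, 2, lam, n_starts=3, seed=0)
        assert fit.n_nonzero_ == target

    def test_dense_target_returns_small_lambda(self):
        data = make_noiseless(q=2, k=3, n=30)
        lam = lambda_for_cardinality(data.data, 2, 12, n_starts=3, seed=0)
        fit = fit_lasso(data.data, 2, lam, n_starts=3, seed=0)
        assert fit.n_nonzero_ == 12

    def test_invalid_target(self, small_standardized):
        with pytest.raises(ValueError):
            lambda_for_cardinality(small_standardized, 2, 1)


class TestParallelAnalysis:
    def test_pure_noise_retains_nothing(self):
        rng = np.random.default_rng(202)
        hits = 0
        runs = 40
        for _ in range(runs):
            Y = rng.standard_normal((200, 10))
            q = parallel_analysis(Y, n_perm=60, quantile=0.99, seed=int(rng.integers(2**31)))
            hits += q == 0
        assert hits / runs >= 0.95

    def test_strong_single_factor_detected(self):
        rng = np.random.default_rng(7)
        eta = rng.standard_normal((200, 1))
        raw = 0.9 * eta + np.sqrt(1 - 0.81) * rng.standard_normal((200, 8))
        assert parallel_analysis(raw, n_perm=100, quantile=0.95, seed=3) == 1

    def test_column_permutation_invariance(self, rng):
        eta = rng.standard_normal((150, 2))
        P = np.array([[0.9, 0], [0.9, 0], [0.9, 0], [0, 0.9], [0, 0.9], [0, 0.9]])
        raw = eta @ P.T + 0.4 * rng.standard_normal((150, 6))
        q1 = parallel_analysis(raw, n_perm=50, quantile=0.95, seed=9)
        q2 = parallel_analysis(raw[:, ::-1], n_perm=50, quantile=0.95, seed=9)
        assert q1 == q2 == 2
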