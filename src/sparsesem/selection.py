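"""Model selection for the sparse factor analyzers.

The sparsity level (LASSO penalty lambda, or cardinality C) is chosen by
maximizing the Index of Sparseness

    IS = PEV_PCA * PEV_model * PS,

the product of the proportion of variance a rank-Q PCA explains, the
proportion the sparse model explains, and the proportion of zero loadings.
IS rewards fit and parsimony at once; the candidate with the highest IS wins,
ties going to the sparser model.  Also provided: an operational ``lambda_max``
(smallest penalty leaving one nonzero loading per factor, found by bisection
over refits), candidate grids, a bisection that targets a given nonzero count
(used for oracle-sparsity LASSO fits), and Horn's parallel analysis as a
convenience for choosing the number of factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cardinality import CardinalityFactorAnalysis
from .io import standardize
from .lasso import LassoFactorAnalysis

__all__ = [
    "SelectionCandidate",
    "SelectionResult",
    "pev_pca",
    "pev_model",
    "index_of_sparseness",
    "lambda_max",
    "make_grid",
    "select",
    "lambda_for_cardinality",
    "parallel_analysis",
    "SparsenessIndexSelector",
]


def pev_pca(Y, Q):
    """Proportion of variance explained by ordinary PCA with Q components.

    Equals the sum of the Q largest correlation-matrix eigenvalues over J for
    standardized data, computed as ``1 - RSS_svd / ||Y||_F^2`` via an economy
    SVD (cheap even when J >> N).
    """
    Y = np.asarray(Y, dtype=float)
    if not 1 <= Q <= Y.shape[1]:
        raise ValueError(f"Q={Q} must lie in [1, J={Y.shape[1]}]")
    s2 = np.linalg.svd(Y, compute_uv=False) ** 2
    return float(s2[:Q].sum() / s2.sum())


def pev_model(Y, eta, P):
    """Proportion of variance explained by a fitted factor model,
    ``1 - ||Y - eta P^T||_F^2 / ||Y||_F^2``."""
    Y = np.asarray(Y, dtype=float)
    resid = Y - np.asarray(eta, float) @ np.asarray(P, float).T
    return float(1.0 - np.sum(resid * resid) / np.sum(Y * Y))


def index_of_sparseness(pev_pca_value, pev_model_value, ps):
    """Index of Sparseness: product of PEV_PCA, PEV_model and the zero share."""
    for name, value in (
        ("pev_pca", pev_pca_value),
        ("pev_model", pev_model_value),
        ("ps", ps),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name}={value} must lie in [0, 1]")
    return float(pev_pca_value * pev_model_value * ps)


@dataclass(frozen=True)
class SelectionCandidate:
    """Per-candidate record of a selection path."""

    parameter_kind: str  # "lambda" or "cardinality"
    parameter_value: float
    pev_pca: float
    pev_model: float
    ps: float
    is_value: float
    n_nonzero: int


@dataclass
class SelectionResult:
    """Outcome of Index-of-Sparseness selection over a candidate grid."""

    candidates: list[SelectionCandidate]
    chosen: int
    chosen_fit: object = field(repr=False, default=None)

    @property
    def chosen_candidate(self) -> SelectionCandidate:
        return self.candidates[self.chosen]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "parameter_kind": c.parameter_kind,
                    "parameter_value": c.parameter_value,
                    "n_nonzero": c.n_nonzero,
                    "pev_pca": c.pev_pca,
                    "pev_model": c.pev_model,
                    "ps": c.ps,
                    "is_value": c.is_value,
                }
                for c in self.candidates
            ]
        )
        frame["chosen"] = False
        frame.loc[self.chosen, "chosen"] = True
        return frame


def make_grid(kind, Q, J, N=None, n_points=100, lower="3Q", lam_max=None, lam_min=None):
    """Candidate grid for sparsity-level selection.

    ``kind="cardinality"``: all integers in [lower, J*Q] with lower either
    ``"Q"`` (at least one loading per factor) or ``"3Q"`` (at least three, the
    simulation-study convention), or an explicit integer.
    ``kind="lambda"``: ``n_points`` log-spaced values in [N*0.1, lam_max]
    (``lam_min`` overrides the default floor), increasing.
    """
    if kind == "cardinality":
        if lower == "Q":
            lo = Q
        elif lower == "3Q":
            lo = 3 * Q
        else:
            lo = int(lower)
        hi = J * Q
        if lo > hi:
            raise ValueError(f"grid lower bound {lo} exceeds J*Q={hi}")
        return list(range(lo, hi + 1))
    if kind == "lambda":
        if lam_max is None:
            raise ValueError("lambda grid requires lam_max")
        lo = 0.1 * N if lam_min is None else lam_min
        if lo <= 0 or lo > lam_max:
            raise ValueError(f"invalid lambda bounds [{lo}, {lam_max}]")
        return list(np.geomspace(lo, lam_max, n_points))
    raise ValueError(f"unknown grid kind {kind!r}")


def _fit_candidate(Y, Q, method, value, n_starts, seed, warm, **fit_kwargs):
    if method == "cardinality":
        est = CardinalityFactorAnalysis(
            n_factors=Q,
            cardinality=int(value),
            n_starts=n_starts,
            random_state=seed,
            standardize=False,
            **fit_kwargs,
        )
    elif method == "lasso":
        est = LassoFactorAnalysis(
            n_factors=Q,
            penalty=float(value),
            n_starts=n_starts,
            random_state=seed,
            standardize=False,
            **fit_kwargs,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.fit(Y, warm_scores=warm)
    return est


def lambda_max(Y, Q, fit_budget=40, n_starts=10, seed=None, **fit_kwargs):
    """Smallest penalty leaving (about) one nonzero loading per factor.

    No closed form exists under the norm-constrained alternating scheme, so
    the value is bracketed by bisection over refitted models until the
    bracket's relative width is below 1%; the upper bracket is returned, so a
    fit at the returned value has at most Q nonzero loadings.
    """
    Y = np.asarray(standardize(Y)[0], dtype=float)
    n = Y.shape[0]
    hi = 2.0 * n  # |eta_q^T y_j| <= N, so lam >= 2N zeroes everything
    lo = 0.0
    warm = None
    budget = fit_budget
    fit = _fit_candidate(Y, Q, "lasso", hi, n_starts, seed, warm, **fit_kwargs)
    budget -= 1
    if fit.n_nonzero_ > Q:  # pragma: no cover - defensive
        warnings.warn("lambda_max: upper bound did not reach Q nonzeros")
        return hi
    warm = [fit.scores_]
    while budget > 0 and (hi - lo) > 0.01 * hi:
        mid = 0.5 * (lo + hi)
        fit = _fit_candidate(Y, Q, "lasso", mid, n_starts, seed, warm, **fit_kwargs)
        warm = [fit.scores_]
        budget -= 1
        if fit.n_nonzero_ <= Q:
            hi = mid
        else:
            lo = mid
    if budget <= 0 and (hi - lo) > 0.01 * hi:
        warnings.warn(
            "lambda_max: bracket not narrowed within fit budget; returning the"
            " smallest lambda seen with <= Q nonzeros"
        )
    return hi


def select(
    Y,
    Q,
    grid,
    method,
    n_starts=5,
    seed=None,
    keep_fits=False,
    assume_standardized=False,
    fit_tol=1e-6,
    fit_max_iter=500,
    **fit_kwargs,
):
    """Fit every candidate in ``grid`` and pick the Index-of-Sparseness argmax.

    Candidates are visited from sparsest to densest, each fit warm-started
    from the previous candidate's solution in addition to ``n_starts`` fresh
    random starts and the deterministic SVD start.  IS ties within 1e-12 go to
    the sparser candidate (fewer nonzeros).

    Candidate fits use a looser convergence tolerance than final fits
    (``fit_tol``, relative): the Index of Sparseness ranks candidates on PEV
    differences far above 1e-6, while the slow tail of alternating least
    squares past that point can cost hundreds of iterations per candidate.
    Refit the chosen sparsity level at full tolerance if exact loadings are
    needed.
    """
    fit_kwargs.setdefault("tol", fit_tol)
    fit_kwargs.setdefault("max_iter", fit_max_iter)
    if len(grid) == 0:
        raise ValueError("empty candidate grid")
    if not assume_standardized:
        Y = np.asarray(standardize(Y)[0], dtype=float)
    else:
        Y = np.asarray(Y, dtype=float)
    j = Y.shape[1]
    pca = pev_pca(Y, Q)
    rng = np.random.default_rng(seed)

    order = sorted(range(len(grid)), key=lambda i: grid[i])
    if method == "cardinality":
        pass  # ascending C = sparse -> dense
    elif method == "lambda" or method == "lasso":
        method = "lasso"
        order = order[::-1]  # descending lambda = sparse -> dense
    else:
        raise ValueError(f"unknown method {method!r}")

    candidates: list[SelectionCandidate | None] = [None] * len(grid)
    fits: list[object | None] = [None] * len(grid)
    kind = "cardinality" if method == "cardinality" else "lambda"

    def record(idx, fit):
        ps = 1.0 - fit.n_nonzero_ / (j * Q)
        candidates[idx] = SelectionCandidate(
            parameter_kind=kind,
            parameter_value=grid[idx],
            pev_pca=pca,
            pev_model=fit.pev_,
            ps=ps,
            is_value=index_of_sparseness(pca, max(0.0, fit.pev_), ps),
            n_nonzero=fit.n_nonzero_,
        )
        fits[idx] = fit

    warm = None
    for idx in order:
        sub_seed = int(rng.integers(2**31))
        fit = _fit_candidate(Y, Q, method, grid[idx], n_starts, sub_seed, warm,
                             **fit_kwargs)
        warm = [fit.scores_]
        record(idx, fit)

    # backward refinement sweep (dense -> sparse): a sparse candidate has no
    # warm start on the forward pass and a poor local optimum there can
    # propagate; re-fitting each candidate warm-started from its denser
    # neighbour's solution and keeping the better fit removes that cold-start
    # asymmetry
    warm = None
    for idx in reversed(order):
        sub_seed = int(rng.integers(2**31))
        refit = _fit_candidate(Y, Q, method, grid[idx], 1, sub_seed, warm,
                               **fit_kwargs)
        if refit.loss_trace_[-1] < fits[idx].loss_trace_[-1]:
            record(idx, refit)
        warm = [fits[idx].scores_]

    best_idx = None
    for idx, cand in enumerate(candidates):
        if best_idx is None:
            best_idx = idx
            continue
        best = candidates[best_idx]
        if cand.is_value > best.is_value + 1e-12:
            best_idx = idx
        elif abs(cand.is_value - best.is_value) <= 1e-12:
            if cand.n_nonzero < best.n_nonzero:
                best_idx = idx
    chosen_fit = fits[best_idx]
    if all(c.pev_model <= 0 for c in candidates):
        raise RuntimeError("selection failed: all candidates degenerate")
    result = SelectionResult(candidates=candidates, chosen=best_idx, chosen_fit=chosen_fit)
    if keep_fits:
        result.fits = fits
    return result


def lambda_for_cardinality(
    Y, Q, target_nonzero, max_steps=30, n_starts=10, seed=None, **fit_kwargs
):
    """Bisection for the penalty whose fit has a target number of nonzeros.

    Searches [0, lambda_max]; at each step the model is refit and the penalty
    is increased when too many loadings survive, decreased when too few.  The
    nonzero count need not be perfectly monotone in lambda under nonconvex
    alternating optimization, so after ``max_steps`` the closest-count penalty
    is returned with a warning.
    """
    Ys = np.asarray(standardize(Y)[0], dtype=float)
    j = Ys.shape[1]
    if not Q <= target_nonzero <= j * Q:
        raise ValueError(
            f"target_nonzero={target_nonzero} must lie in [Q, J*Q] = [{Q}, {j * Q}]"
        )
    hi = lambda_max(Ys, Q, n_starts=n_starts, seed=seed, **fit_kwargs)
    lo = 0.0
    warm = None
    best = None  # (count gap, lam)
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        fit = _fit_candidate(Ys, Q, "lasso", mid, n_starts, seed, warm, **fit_kwargs)
        warm = [fit.scores_]
        gap = abs(fit.n_nonzero_ - target_nonzero)
        if best is None or gap < best[0]:
            best = (gap, mid)
        if fit.n_nonzero_ == target_nonzero:
            return mid
        if fit.n_nonzero_ > target_nonzero:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"lambda_for_cardinality: target {target_nonzero} not attained in"
        f" {max_steps} steps; returning closest (gap {best[0]})"
    )
    return best[1]


def parallel_analysis(Y, n_perm=100, quantile=0.95, seed=None):
    """Horn's parallel analysis for the number of factors.

    Compares the correlation-matrix eigenvalues of the data with the stated
    quantile of eigenvalues obtained after permuting each column
    independently; retains leading components exceeding their threshold,
    stopping at the first failure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Ys = np.asarray(standardize(Y)[0], dtype=float)
    n = Ys.shape[0]
    observed = np.linalg.svd(Ys, compute_uv=False) ** 2 / n
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        permuted = rng.permuted(Ys, axis=0)  # each column shuffled independently
        null[b] = np.linalg.svd(permuted, compute_uv=False) ** 2 / n
    thresholds = np.quantile(null, quantile, axis=0)
    q_hat = 0
    for eig, thr in zip(observed, thresholds):
        if eig > thr:
            q_hat += 1
        else:
            break
    return q_hat


class SparsenessIndexSelector(BaseEstimator):
    """Sklearn-style wrapper: grid search over the sparsity level by IS.

    Parameters
    ----------
    method : {"cardinality", "lasso"}
    n_factors : int
    grid : sequence or None
        Candidate cardinalities or penalties; if None, built with
        :func:`make_grid` (``[3Q, J*Q]`` integers for the cardinality path,
        100 log-spaced penalties in ``[0.1*N, lambda_max]`` for the LASSO).
    n_starts : int
        Fresh random starts per candidate (plus SVD start and warm start).
    """

    def __init__(self, method="cardinality", n_factors=1, grid=None, n_starts=5,
                 grid_lower="3Q", random_state=None):
        self.method = method
        self.n_factors = n_factors
        self.grid = grid
        self.n_starts = n_starts
        self.grid_lower = grid_lower
        self.random_state = random_state

    def fit(self, X, y=None):
        Ys = np.asarray(standardize(X)[0], dtype=float)
        n, j = Ys.shape
        grid = self.grid
        if grid is None:
            if self.method == "cardinality":
                grid = make_grid("cardinality", self.n_factors, j, lower=self.grid_lower)
            else:
                lam_hi = lambda_max(Ys, self.n_factors, seed=self.random_state)
                grid = make_grid("lambda", self.n_factors, j, N=n, lam_max=lam_hi)
        result = select(
            Ys,
            self.n_factors,
            grid,
            self.method,
            n_starts=self.n_starts,
            seed=self.random_state,
            assume_standardized=True,
        )
        self.result_ = result
        self.best_value_ = result.chosen_candidate.parameter_value
        self.best_index_ = result.chosen
        self.best_estimator_ = result.chosen_fit
        self.candidates_ = result.to_frame()
        return self
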