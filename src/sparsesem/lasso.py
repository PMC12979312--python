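"""LASSO-penalized exploratory approximate factor analysis.

The measurement model ``y = P eta + eps`` is estimated by minimizing the
penalized least-squares objective

    sum_ij (y_ij - sum_q eta_iq p_jq)^2  +  lambda * sum_jq |p_jq|

subject to the column-norm constraint ``sum_i eta_iq^2 = N`` for every factor
q.  Estimation alternates between (a) a column-wise block update of the factor
scores (each column's constrained subproblem has the closed-form solution
``eta_q = sqrt(N) R_q p_q / ||R_q p_q||`` with R_q the partial residual) and
(b) coordinate descent with soft thresholding on the loadings.  Both half
steps are exact conditional minimizers, so the loss sequence is nonincreasing;
because the joint problem is non-convex, a multistart protocol is used and the
run with the lowest final loss is retained.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import standardize

__all__ = [
    "DegenerateFactorError",
    "soft_threshold",
    "loss",
    "update_scores",
    "update_loadings",
    "fit_lasso",
    "LassoFactorAnalysis",
]


class DegenerateFactorError(RuntimeError):
    """A factor's score update is undefined (zero projection)."""


def soft_threshold(x, lam):
    """Soft-thresholding operator ``S(x, lam) = sign(x) * max(0, |x| - lam)``."""
    if lam < 0:
        raise ValueError(f"threshold must be nonnegative, got {lam}")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def loss(Y, eta, P, lam):
    """Penalized least-squares objective value."""
    Y = np.asarray(Y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    P = np.asarray(P, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if Y.shape[0] != eta.shape[0] or Y.shape[1] != P.shape[0] or eta.shape[1] != P.shape[1]:
        raise ValueError(
            f"shape mismatch: Y {Y.shape}, eta {eta.shape}, P {P.shape}"
        )
    resid = Y - eta @ P.T
    return float(np.sum(resid * resid) + lam * np.abs(P).sum())


def update_scores(Y, P, eta, on_degenerate="raise"):
    """One pass of column-wise score updates under the norm-N constraint.

    For each factor q in turn, with ``R_q = Y - sum_{t != q} eta_t p_t^T``,
    sets ``eta_q = sqrt(N) * R_q p_q / ||R_q p_q||`` -- the exact minimizer of
    the objective over eta_q given everything else (via a Lagrange multiplier
    for the norm constraint).  The objective never increases.

    Parameters
    ----------
    on_degenerate : {"raise", "keep"}
        What to do when ``R_q p_q`` is (numerically) the zero vector, e.g.
        because p_q is all zero: raise :class:`DegenerateFactorError` or keep
        the current column (its loadings are zero, so the loss is unaffected).
    """
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    eta = np.array(eta, dtype=float, copy=True)
    n, q_tot = eta.shape
    sqrt_n = np.sqrt(n)
    # R_q p_q = Y p_q - eta (P^T p_q) + eta_q (p_q^T p_q); refresh cross-products
    # as columns change.
    M = Y @ P
    for q in range(q_tot):
        s = P.T @ P[:, q]
        v = M[:, q] - eta @ s + eta[:, q] * s[q]
        norm_v = float(np.linalg.norm(v))
        if not norm_v > 1e-12:
            if on_degenerate == "raise":
                raise DegenerateFactorError(
                    f"score update undefined for factor {q}: zero projection"
                    " (all-zero loadings or orthogonal data)"
                )
            continue
        eta[:, q] = sqrt_n * v / norm_v
    return eta


def update_loadings(Y, eta, lam, P, inner_tol=1e-8, max_cycles=1000):
    """Cyclic coordinate descent on the loadings with soft thresholding.

    Each coordinate (j, q) has the closed-form update
    ``p_jq <- S(eta_q^T r_j^(-q), lam/2) / (eta_q^T eta_q)`` where
    ``r_j^(-q)`` is the partial residual of variable j excluding factor q.
    Updates for a given factor are independent across variables, so a full
    column of P is updated at once; cycles repeat until the maximum absolute
    coordinate change drops below ``inner_tol``.  Zeros produced by the
    threshold are exact.
    """
    Y = np.asarray(Y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    P = np.array(P, dtype=float, copy=True)
    q_tot = eta.shape[1]
    gram = eta.T @ eta
    cross = eta.T @ Y  # Q x J
    thr = lam / 2.0
    for _ in range(max_cycles):
        delta = 0.0
        for q in range(q_tot):
            c = cross[q] - P @ gram[q] + P[:, q] * gram[q, q]
            new = soft_threshold(c, thr) / gram[q, q]
            step = np.max(np.abs(new - P[:, q])) if new.size else 0.0
            if step > delta:
                delta = step
            P[:, q] = new
        if delta < inner_tol:
            break
    return P


def _random_score_start(rng, n, q):
    eta = rng.standard_normal((n, q))
    norms = np.linalg.norm(eta, axis=0)
    norms[norms == 0] = 1.0
    return np.sqrt(n) * eta / norms


def _svd_score_start(Y, q):
    u = np.linalg.svd(Y, full_matrices=False)[0][:, :q]
    norms = np.linalg.norm(u, axis=0)
    norms[norms == 0] = 1.0
    return np.sqrt(Y.shape[0]) * u / norms


class LassoFactorAnalysis(TransformerMixin, BaseEstimator):
    """Sparse exploratory approximate factor analysis with an l1 penalty.

    Parameters
    ----------
    n_factors : int
        Number of factors Q.
    penalty : float
        LASSO tuning parameter lambda (>= 0) on the unnormalized objective
        (residual sum of squares plus ``penalty * sum |p_jq|``).
    n_starts : int, default 100
        Number of random initializations; one deterministic start from the
        top-Q left singular vectors is always added.  The run with the lowest
        final loss wins; ties (within 1e-9) keep the earliest start.
    tol : float
        Relative decrease of the loss below which a run stops.
    max_iter : int
        Cap on alternating iterations per start.
    inner_tol : float
        Convergence tolerance of the coordinate-descent inner loop.
    standardize : bool, default True
        Standardize columns (mean 0, squared norm N) before fitting.  The
        model's identities (loss N*J at P=0, PEV bounds) assume this.
    random_state : int or None
        Seed for the random starts.

    Attributes
    ----------
    loadings_ : ndarray of shape (J, Q)
        Sparse loading matrix; stored zeros are exact.
    scores_ : ndarray of shape (N, Q)
        Factor scores, each column with squared norm N.
    score_correlation_ : ndarray of shape (Q, Q)
        Sample correlation matrix of the score columns.
    loss_trace_ : ndarray
        Loss after every alternating iteration of the winning start
        (nonincreasing).
    converged_ : bool
    n_iter_ : int
    start_losses_ : ndarray
        Final loss of every start, in initialization order (SVD start first).
    pev_ : float
        Proportion of explained variance, ``1 - RSS / ||Y||_F^2``.
    n_nonzero_ : int
    """

    def __init__(
        self,
        n_factors=1,
        penalty=0.0,
        n_starts=100,
        tol=1e-8,
        max_iter=1000,
        inner_tol=1e-8,
        standardize=True,
        random_state=None,
    ):
        self.n_factors = n_factors
        self.penalty = penalty
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.inner_tol = inner_tol
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _prepare(self, X):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        if self.standardize:
            Y, record = standardize(X)
            Y = np.asarray(Y, dtype=float)
        else:
            Y, record = np.asarray(X, dtype=float), None
        n, j = Y.shape
        q = self.n_factors
        if not 1 <= q <= min(n, j):
            raise ValueError(
                f"n_factors={q} must lie in [1, min(N, J)] = [1, {min(n, j)}]"
            )
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        return Y, record

    def _single_run(self, Y, eta0):
        lam = self.penalty
        n, j = Y.shape
        q = self.n_factors
        eta = eta0
        P = update_loadings(Y, eta, lam, np.zeros((j, q)), self.inner_tol)
        prev = loss(Y, eta, P, lam)
        trace = [prev]
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            eta = update_scores(Y, P, eta, on_degenerate="keep")
            P = update_loadings(Y, eta, lam, P, self.inner_tol)
            cur = loss(Y, eta, P, lam)
            trace.append(cur)
            if prev - cur <= self.tol * max(prev, 1e-300):
                converged = True
                break
            prev = cur
        return eta, P, np.asarray(trace), converged, n_iter

    def fit(self, X, y=None, warm_scores=None):
        """Fit the model; ``warm_scores`` adds extra deterministic starts."""
        Y, record = self._prepare(X)
        n = Y.shape[0]
        q = self.n_factors
        rng = np.random.default_rng(self.random_state)
        starts = [_svd_score_start(Y, q)]
        starts += [_random_score_start(rng, n, q) for _ in range(self.n_starts)]
        if warm_scores is not None:
            for eta0 in warm_scores:
                eta0 = np.asarray(eta0, dtype=float)
                norms = np.linalg.norm(eta0, axis=0)
                norms[norms == 0] = 1.0
                starts.append(np.sqrt(n) * eta0 / norms)

        best = None
        start_losses = []
        for eta0 in starts:
            eta, P, trace, converged, n_iter = self._single_run(Y, eta0)
            final = trace[-1]
            start_losses.append(final)
            if best is None or final < best[0] - 1e-9:
                best = (final, eta, P, trace, converged, n_iter)
        final, eta, P, trace, converged, n_iter = best
        if not converged:
            warnings.warn(
                "alternating optimization did not converge within max_iter",
                RuntimeWarning,
                stacklevel=2,
            )

        self.standardization_ = record
        self.loadings_ = P
        self.scores_ = eta
        with np.errstate(invalid="ignore"):
            self.score_correlation_ = np.corrcoef(eta, rowvar=False).reshape(q, q)
        self.loss_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.start_losses_ = np.asarray(start_losses)
        self.n_nonzero_ = int(np.count_nonzero(P))
        total = float(np.sum(Y * Y))
        rss = final - self.penalty * float(np.abs(P).sum())
        self.pev_ = 1.0 - rss / total
        self.n_features_in_ = Y.shape[1]
        return self

    def transform(self, X):
        """Least-squares factor scores for (new) data under the fitted loadings.

        Note: unlike the in-sample ``scores_``, these projections are not
        rescaled to the norm-N constraint.
        """
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        if self.standardize:
            X = self.standardization_.apply(X)
        P = self.loadings_
        return X @ P @ np.linalg.pinv(P.T @ P)


def fit_lasso(Y, Q, lam, n_starts=100, seed=None, tol=1e-8, max_iter=1000, **kwargs):
    """Functional front end: fit :class:`LassoFactorAnalysis` and return it."""
    est = LassoFactorAnalysis(
        n_factors=Q,
        penalty=lam,
        n_starts=n_starts,
        random_state=seed,
        tol=tol,
        max_iter=max_iter,
        **kwargs,
    )
    return est.fit(Y)
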