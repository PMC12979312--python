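"""Cardinality-constrained approximate factor analysis with orthogonal factors.

Minimizes ``||Y - eta P^T||_F^2`` subject to ``eta^T eta = N I`` (uncorrelated
unit-variance factor scores) and ``Card(P) <= C`` nonzero loadings.  With
standardized data and orthogonal scores the unconstrained least-squares
loadings are ``P = Y^T eta / N``, whose entries are exactly the item-score
Pearson correlations; the cardinality constraint is then handled at no extra
cost because, for fixed orthogonal scores, the loss is separable over loading
entries -- keeping the C largest-magnitude entries of the dense solution is
the exact constrained minimizer.  The score subproblem is an orthogonal
Procrustes problem solved by SVD.  Both half steps are exact conditional
minimizers, so the alternating loss sequence is nonincreasing; the constraint
set is nonconvex, so a multistart protocol and a best-iterate guard are used.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import standardize
from .lasso import _random_score_start

__all__ = [
    "OrthogonalityError",
    "dense_loadings",
    "hard_threshold_top",
    "procrustes_scores",
    "fit_cardinality",
    "CardinalityFactorAnalysis",
]


class OrthogonalityError(ValueError):
    """Score matrix does not satisfy ``eta^T eta = N I`` within tolerance."""


def _check_orthogonal(eta, tol=1e-6):
    eta = np.asarray(eta, dtype=float)
    n = eta.shape[0]
    gram = eta.T @ eta / n
    dev = np.max(np.abs(gram - np.eye(eta.shape[1])))
    if dev > tol:
        raise OrthogonalityError(
            f"scores violate eta^T eta = N I (max deviation {dev:.2e} > {tol:.0e})"
        )
    return eta


def dense_loadings(Y, eta):
    """Unconstrained least-squares loadings ``Y^T eta / N`` for orthogonal scores.

    On standardized data each entry (j, q) equals the sample correlation of
    variable j with score column q.
    """
    Y = np.asarray(Y, dtype=float)
    eta = _check_orthogonal(eta)
    return Y.T @ eta / Y.shape[0]


def hard_threshold_top(P_dense, C):
    """Keep the C largest-magnitude entries of a loading matrix, zero the rest.

    For fixed orthogonal scores the least-squares loss is entrywise separable,
    so this is the exact minimizer over ``Card(P) <= C``.  Ties at the C-th
    magnitude are broken deterministically: the entry earlier in column-major
    (factor, then variable) order is kept.
    """
    P_dense = np.asarray(P_dense, dtype=float)
    j, q = P_dense.shape
    if not q <= C <= j * q:
        raise ValueError(f"cardinality C={C} must lie in [Q, J*Q] = [{q}, {j * q}]")
    flat = P_dense.flatten(order="F")
    # stable sort on descending magnitude keeps column-major order among ties
    order = np.argsort(-np.abs(flat), kind="stable")
    out = np.zeros_like(flat)
    keep = order[:C]
    out[keep] = flat[keep]
    return out.reshape((j, q), order="F")


def procrustes_scores(Y, P):
    """Orthogonal-Procrustes score update: ``eta = sqrt(N) U V^T``, SVD of Y P.

    Maximizes ``trace(eta^T Y P)`` subject to ``eta^T eta = N I``, which is the
    exact score minimizer of the least-squares loss for fixed loadings.  If
    Y P is rank deficient the solution is not unique; a warning is emitted.
    """
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    m = Y @ P
    u, d, vt = np.linalg.svd(m, full_matrices=False)
    if d.size and d[-1] < 1e-10:
        warnings.warn(
            "Y P is (numerically) rank deficient; the Procrustes score update"
            " is not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.sqrt(Y.shape[0]) * u @ vt


def _orthogonal_random_start(rng, n, q):
    raw = rng.standard_normal((n, q))
    u, _, vt = np.linalg.svd(raw, full_matrices=False)
    return np.sqrt(n) * u @ vt


def _orthogonal_svd_start(Y, q):
    u = np.linalg.svd(Y, full_matrices=False)[0][:, :q]
    return np.sqrt(Y.shape[0]) * u


class CardinalityFactorAnalysis(TransformerMixin, BaseEstimator):
    """Orthogonal sparse factor analysis with a hard cap on nonzero loadings.

    Parameters mirror :class:`~sparsesem.lasso.LassoFactorAnalysis`, with the
    l1 penalty replaced by ``cardinality`` (the exact number C of retained
    loadings, ``Q <= C <= J*Q``).  Random starts draw a standard normal score
    matrix and project it onto the constraint set (polar factor, scaled by
    sqrt(N)); one deterministic start uses the top-Q left singular vectors.

    Attributes
    ----------
    loadings_ : ndarray (J, Q)
        At most C nonzeros; each nonzero equals the correlation of its item
        with its score column.
    scores_ : ndarray (N, Q)
        ``scores_.T @ scores_ = N I`` within 1e-8.
    loss_trace_, converged_, n_iter_, start_losses_, pev_, n_nonzero_ :
        As in the LASSO estimator; the trace is truncated at the best iterate.
    """

    def __init__(
        self,
        n_factors=1,
        cardinality=None,
        n_starts=100,
        tol=1e-8,
        max_iter=1000,
        standardize=True,
        random_state=None,
    ):
        self.n_factors = n_factors
        self.cardinality = cardinality
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

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
        c = j * q if self.cardinality is None else int(self.cardinality)
        if not q <= c <= j * q:
            raise ValueError(f"cardinality={c} must lie in [Q, J*Q] = [{q}, {j * q}]")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        return Y, record, c

    def _single_run(self, Y, eta0, c):
        n = Y.shape[0]
        eta = eta0
        best = None
        prev = None
        trace = []
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            P = hard_threshold_top(Y.T @ eta / n, c)
            eta = procrustes_scores(Y, P)
            resid = Y - eta @ P.T
            cur = float(np.sum(resid * resid))
            if prev is not None and cur > prev + 1e-9:
                # non-convexity guard: stop, keep the best iterate seen so far
                break
            trace.append(cur)
            if best is None or cur < best[0]:
                best = (cur, eta, P)
            if prev is not None and prev - cur <= self.tol * max(prev, 1e-300):
                converged = True
                break
            prev = cur
        final, eta, P = best
        # finishing half-step: make the loadings the exact conditional
        # minimizer for the returned scores (nonzeros = item-score
        # correlations); cannot increase the loss
        P = hard_threshold_top(Y.T @ eta / n, c)
        resid = Y - eta @ P.T
        cur = float(np.sum(resid * resid))
        if cur < final:
            trace = trace + [cur] if isinstance(trace, list) else list(trace) + [cur]
        else:
            cur = final
        return eta, P, np.asarray(trace), converged, n_iter

    def fit(self, X, y=None, warm_scores=None):
        """Fit the model; ``warm_scores`` adds extra deterministic starts
        (each is projected onto the orthogonality constraint first)."""
        Y, record, c = self._prepare(X)
        n = Y.shape[0]
        q = self.n_factors
        rng = np.random.default_rng(self.random_state)
        starts = [_orthogonal_svd_start(Y, q)]
        starts += [_orthogonal_random_start(rng, n, q) for _ in range(self.n_starts)]
        if warm_scores is not None:
            for eta0 in warm_scores:
                eta0 = np.asarray(eta0, dtype=float)
                u, _, vt = np.linalg.svd(eta0, full_matrices=False)
                starts.append(np.sqrt(n) * u @ vt)

        best = None
        start_losses = []
        for eta0 in starts:
            eta, P, trace, converged, n_iter = self._single_run(Y, eta0, c)
            final = trace[-1] if trace.size else np.inf
            final = min(final, float(np.sum((Y - eta @ P.T) ** 2)))
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
        self.cardinality_ = c
        self.loss_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.start_losses_ = np.asarray(start_losses)
        self.n_nonzero_ = int(np.count_nonzero(P))
        if self.n_nonzero_ < c and np.any(np.count_nonzero(P, axis=0) == 0):
            warnings.warn(
                "a factor ended with an all-zero loading column",
                RuntimeWarning,
                stacklevel=2,
            )
        total = float(np.sum(Y * Y))
        self.pev_ = 1.0 - final / total
        self.n_features_in_ = Y.shape[1]
        return self

    def transform(self, X):
        """Least-squares factor scores for (new) data under the fitted loadings."""
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        if self.standardize:
            X = self.standardization_.apply(X)
        P = self.loadings_
        return X @ P @ np.linalg.pinv(P.T @ P)


def fit_cardinality(
    Y, Q, C, n_starts=100, seed=None, tol=1e-8, max_iter=1000, **kwargs
):
    """Functional front end: fit :class:`CardinalityFactorAnalysis`, return it."""
    est = CardinalityFactorAnalysis(
        n_factors=Q,
        cardinality=C,
        n_starts=n_starts,
        random_state=seed,
        tol=tol,
        max_iter=max_iter,
        **kwargs,
    )
    return est.fit(Y)
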