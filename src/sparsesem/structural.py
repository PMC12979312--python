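"""Stage 2: structural-path estimation on recovered factor scores.

Given the factor scores from Stage 1, the structural model is a single-
equation ordinary least-squares regression of an outcome on the scores,
optional observed covariates, and optional factor-by-covariate interactions.
Classical (non-robust) standard errors and t-based p-values are reported;
no uncertainty from Stage 1 is propagated (two-stage inference is an open
problem deferred by design).  Stage 2 is not regularized: the design must be
full rank and N must exceed the number of terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "MulticollinearityError",
    "UnderdeterminedError",
    "StructuralFit",
    "build_design",
    "fit_regression",
    "FactorScoreRegression",
]


class MulticollinearityError(ValueError):
    """Design matrix is rank deficient; lists the dependent terms."""


class UnderdeterminedError(ValueError):
    """More regression terms than cases; Stage 2 is not regularized."""


@dataclass
class StructuralFit:
    """OLS estimates of the structural model."""

    coefficients: dict
    standard_errors: dict
    t_values: dict
    p_values: dict
    r_squared: float
    residuals: np.ndarray
    design_terms: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.design_terms,
                "estimate": [self.coefficients[t] for t in self.design_terms],
                "se": [self.standard_errors[t] for t in self.design_terms],
                "t": [self.t_values[t] for t in self.design_terms],
                "p": [self.p_values[t] for t in self.design_terms],
            }
        )


def _column_names(obj, prefix, count):
    if isinstance(obj, pd.DataFrame):
        return [str(c) for c in obj.columns]
    return [f"{prefix}{i + 1}" for i in range(count)]


def build_design(scores, covariates=None, interactions=None):
    """Assemble the Stage-2 design matrix.

    Column order: intercept, factor scores, covariates, then one product
    column per requested (factor, covariate) interaction.  ``interactions``
    is a list of index pairs (or name pairs when DataFrames are supplied).
    Categorical covariates must arrive pre-encoded as numeric columns.

    Returns ``(design, term_names)`` with ``design`` a DataFrame.

    Raises
    ------
    MulticollinearityError
        If the design is rank deficient (lists the dependent terms).
    """
    eta = np.asarray(scores, dtype=float)
    if eta.ndim != 2:
        raise ValueError("scores must be a 2-D N x Q matrix")
    n, n_fac = eta.shape
    factor_names = _column_names(scores, "factor", n_fac)
    columns = [np.ones(n)]
    names = ["intercept"]
    for q in range(n_fac):
        columns.append(eta[:, q])
        names.append(factor_names[q])
    cov_names: list[str] = []
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates row count does not match scores")
        cov_names = _column_names(covariates, "covariate", cov.shape[1])
        for k in range(cov.shape[1]):
            columns.append(cov[:, k])
            names.append(cov_names[k])
    if interactions:
        if cov is None:
            raise ValueError("interactions requested but no covariates supplied")
        for fac, covar in interactions:
            fi = factor_names.index(fac) if isinstance(fac, str) else int(fac)
            ci = cov_names.index(covar) if isinstance(covar, str) else int(covar)
            columns.append(eta[:, fi] * cov[:, ci])
            names.append(f"{factor_names[fi]}:{cov_names[ci]}")
    design = np.column_stack(columns)

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        dependent = []
        running = np.empty((n, 0))
        r = 0
        for idx in range(design.shape[1]):
            trial = np.column_stack([running, design[:, idx]])
            r_new = np.linalg.matrix_rank(trial)
            if r_new == r:
                dependent.append(names[idx])
            else:
                running = trial
                r = r_new
        raise MulticollinearityError(
            "design matrix is rank deficient; linearly dependent terms: "
            + ", ".join(dependent)
        )
    return pd.DataFrame(design, columns=names), names


def fit_regression(design, outcome) -> StructuralFit:
    """Ordinary least squares via QR, with classical standard errors.

    Two-sided p-values use the t distribution with N minus #terms degrees of
    freedom.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("outcome length does not match design rows")
    if n <= p:
        raise UnderdeterminedError(
            f"N={n} must exceed the number of terms ({p}); Stage 2 is not"
            " regularized"
        )
    names = (
        [str(c) for c in design.columns]
        if isinstance(design, pd.DataFrame)
        else [f"x{i}" for i in range(p)]
    )
    model = sm.OLS(y, X)
    res = model.fit(method="qr")
    return StructuralFit(
        coefficients=dict(zip(names, res.params)),
        standard_errors=dict(zip(names, res.bse)),
        t_values=dict(zip(names, res.tvalues)),
        p_values=dict(zip(names, res.pvalues)),
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        design_terms=names,
    )


class FactorScoreRegression(BaseEstimator):
    """Sklearn-style Stage-2 estimator: outcome ~ factor scores (+ covariates).

    ``fit(scores, y)`` builds the design (intercept first) and runs OLS.
    Fitted attributes mirror :class:`StructuralFit` with trailing
    underscores.
    """

    def __init__(self, covariates=None, interactions=None):
        self.covariates = covariates
        self.interactions = interactions

    def fit(self, X, y):
        design, names = build_design(X, self.covariates, self.interactions)
        result = fit_regression(design, y)
        self.result_ = result
        self.coefficients_ = result.coefficients
        self.standard_errors_ = result.standard_errors
        self.t_values_ = result.t_values
        self.p_values_ = result.p_values
        self.r_squared_ = result.r_squared
        self.residuals_ = result.residuals
        self.design_terms_ = names
        return self

    def predict(self, X):
        design, _ = build_design(X, self.covariates, self.interactions)
        beta = np.array([self.coefficients_[t] for t in self.design_terms_])
        return np.asarray(design, dtype=float) @ beta
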