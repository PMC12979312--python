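"""Scoring estimated factor solutions against ground truth.

Factor solutions are identified only up to column permutation and sign, so
estimated loadings are first aligned to the truth by exhaustively searching
all Q! permutations combined with the per-factor sign that maximizes Tucker's
congruence (the cosine between a recovered and a true loading vector).  On
the aligned solution the zero/nonzero recovery rate PL, per-factor
congruences, coefficient bias/RMSE across replicates, entrywise loading
stability, and multistart agreement counts are computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "tucker_congruence",
    "AlignedSolution",
    "align",
    "recovery_rate",
    "coefficient_errors",
    "loading_stability",
    "multistart_agreement",
]

_MAX_ENUM_Q = 8


def tucker_congruence(x, y):
    """Tucker's congruence coefficient: ``x.y / (||x|| ||y||)``.

    Scale invariant; 1 for proportional vectors, -1 for anti-proportional.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("congruence is undefined for a zero vector")
    return float(x @ y / (nx * ny))


@dataclass(frozen=True)
class AlignedSolution:
    """An estimated solution after permutation/sign matching to the truth."""

    permutation: tuple
    signs: np.ndarray
    loadings_aligned: np.ndarray
    scores_aligned: np.ndarray
    per_factor_congruence: np.ndarray
    mean_congruence: float


def _congruence_matrix(P_est, P_true):
    est = np.asarray(P_est, dtype=float)
    true = np.asarray(P_true, dtype=float)
    ne = np.linalg.norm(est, axis=0)
    nt = np.linalg.norm(true, axis=0)
    if np.any(nt == 0):
        raise ValueError("true loading matrix has a zero column")
    safe_ne = np.where(ne == 0, 1.0, ne)
    c = (est / safe_ne).T @ (true / nt)
    c[ne == 0, :] = 0.0  # zero estimated columns contribute congruence 0
    return c


def align(P_est, P_true, scores=None) -> AlignedSolution:
    """Match estimated factors to true factors over all Q! 2^Q configurations.

    The optimal sign for a factor is the one making its congruence
    nonnegative, so the search enumerates permutations and reads signs off
    the congruence matrix -- equivalent to exhausting all sign patterns.
    The aggregate maximized is the mean per-factor congruence; ties go to the
    lexicographically smallest permutation, and a zero congruence gets a
    positive sign.
    """
    est = np.asarray(P_est, dtype=float)
    true = np.asarray(P_true, dtype=float)
    if est.shape != true.shape:
        raise ValueError("estimated and true loading matrices differ in shape")
    q = est.shape[1]
    if q > _MAX_ENUM_Q:
        raise ValueError(
            f"exhaustive alignment is limited to Q <= {_MAX_ENUM_Q}; use a"
            " greedy assignment for larger Q"
        )
    c = _congruence_matrix(est, true)
    best_perm = None
    best_value = -np.inf
    for perm in itertools.permutations(range(q)):
        value = sum(abs(c[perm[t], t]) for t in range(q))
        if value > best_value + 1e-15:
            best_value = value
            best_perm = perm
    signs = np.array(
        [1.0 if c[best_perm[t], t] >= 0 else -1.0 for t in range(q)]
    )
    loadings_aligned = est[:, best_perm] * signs
    scores_aligned = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        scores_aligned = scores[:, best_perm] * signs
    per_factor = np.array([abs(c[best_perm[t], t]) for t in range(q)])
    return AlignedSolution(
        permutation=tuple(best_perm),
        signs=signs,
        loadings_aligned=loadings_aligned,
        scores_aligned=scores_aligned,
        per_factor_congruence=per_factor,
        mean_congruence=float(per_factor.mean()),
    )


def recovery_rate(P_est_aligned, P_true):
    """Zero/nonzero recovery rate PL.

    Fraction of loading positions whose zero/nonzero status matches the
    generating pattern; "estimated nonzero" means exactly nonzero as stored
    (both estimators produce exact zeros, no epsilon threshold).
    """
    est = np.asarray(P_est_aligned, dtype=float)
    true = np.asarray(P_true, dtype=float)
    if est.shape != true.shape:
        raise ValueError("shape mismatch")
    est_nz = est != 0
    true_nz = true != 0
    agree = (est_nz & true_nz) | (~est_nz & ~true_nz)
    return float(agree.mean())


def coefficient_errors(estimates, truth):
    """Absolute bias and RMSE of coefficients across replicates.

    ``estimates`` is a nonempty list of equally keyed mappings (or equal-
    length vectors); ``truth`` matches.  Returns ``(abs_bias, rmse)`` with
    the same keying: ``abs_bias = |mean(est) - truth|`` and
    ``rmse = sqrt(mean((est - truth)^2))`` per coefficient.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one replicate")
    if isinstance(estimates[0], dict):
        keys = list(estimates[0])
        mat = np.array([[e[k] for k in keys] for e in estimates], dtype=float)
        tru = np.array([truth[k] for k in keys], dtype=float)
        bias = np.abs(mat.mean(axis=0) - tru)
        rmse = np.sqrt(np.mean((mat - tru) ** 2, axis=0))
        return dict(zip(keys, bias)), dict(zip(keys, rmse))
    mat = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    bias = np.abs(mat.mean(axis=0) - tru)
    rmse = np.sqrt(np.mean((mat - tru) ** 2, axis=0))
    return bias, rmse


def loading_stability(fits, check_alignment=True):
    """Entrywise standard deviation (ddof=1) of aligned loading matrices.

    With ``check_alignment`` the pairwise column congruences to the first
    matrix must all be nonnegative, catching permutation-inconsistent input.
    """
    mats = [np.asarray(f, dtype=float) for f in fits]
    if len(mats) < 2:
        raise ValueError("need at least two fits")
    ref = mats[0]
    if check_alignment:
        for m in mats[1:]:
            for qcol in range(ref.shape[1]):
                a, b = m[:, qcol], ref[:, qcol]
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na > 0 and nb > 0 and a @ b / (na * nb) < -1e-12:
                    raise ValueError(
                        "fits do not appear to be aligned to a common"
                        f" reference (negative congruence in column {qcol})"
                    )
    return np.std(np.stack(mats), axis=0, ddof=1)


def multistart_agreement(start_losses, rel_tol=1e-6):
    """Number of starts whose final loss matches the best one.

    A start agrees when its loss is within ``rel_tol`` (relative) of the
    minimum.
    """
    losses = np.asarray(start_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("empty loss list")
    m = losses.min()
    return int(np.sum(losses <= m + rel_tol * max(abs(m), 1e-300)))
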