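"""Synthetic-data generator for the simulation study.

The population model is a block-sparse factor model: J = Q*K standardizable
items, item block k loading sqrt(0.6) on its factor; optionally the first
item of each block carries an additional 0.5 cross-loading on the next factor
(cyclically, so every factor receives exactly one cross-loading).  Factor
scores are multivariate normal with unit variances and a common inter-factor
correlation r.  Item residual variances are solved from the target item
reliability (share of item variance explained by the factors), and the
outcome z is a weighted sum of all factors (weight b = 0.1) plus noise whose
variance is solved from the target VAFz (share of outcome variance due to the
factors).  Generated indicator matrices and outcomes are standardized
empirically before being returned, matching what the estimators consume; the
outcome's scale is recorded so structural coefficients can be mapped back to
the raw-outcome units where the population weight b lives.

Design grids reproduce the full factorial study: the low-dimensional regime
crosses N in {50, 100, 500}, Q in {3, 5}, K in {3, 5}, cross-loadings in
{0, 0.5}, reliability in {0.3, 0.8}, r in {0, 0.3}, VAFz in {0.5, 0.9}
(192 cells); the high-dimensional regime fixes N = 50, Q = 5 and crosses
K in {15, 30, 100} with the same remaining levels (48 cells).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .io import StandardizationRecord, standardize

__all__ = [
    "DesignCell",
    "PopulationModel",
    "SimulatedDataset",
    "build_population",
    "simulate",
    "simulate_cell",
    "design_grid",
    "dataset_seed",
]

LOW_DIM_LEVELS = {
    "N": (50, 100, 500),
    "Q": (3, 5),
    "K": (3, 5),
    "cross": (0.0, 0.5),
    "reliability": (0.3, 0.8),
    "r": (0.0, 0.3),
    "vafz": (0.5, 0.9),
}
HIGH_DIM_K = (15, 30, 100)
DEFAULT_B = 0.1  # structural weight, identical for all factors and conditions


@dataclass(frozen=True)
class DesignCell:
    """One cell of the factorial simulation design."""

    N: int
    Q: int
    K: int
    cross: float
    reliability: float
    r: float
    vafz: float
    regime: str = "low_dim"

    def __post_init__(self):
        if self.regime not in ("low_dim", "high_dim"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "high_dim" and (self.N != 50 or self.Q != 5):
            raise ValueError("the high-dimensional regime fixes N=50, Q=5")
        if not 0 <= self.r < 1:
            raise ValueError("factor correlation must lie in [0, 1)")
        if not 0 < self.reliability < 1 or not 0 < self.vafz < 1:
            raise ValueError("reliability and vafz must lie in (0, 1)")

    @property
    def J(self) -> int:
        return self.Q * self.K

    def to_dict(self) -> dict:
        return {
            "N": self.N, "Q": self.Q, "K": self.K, "cross": self.cross,
            "reliability": self.reliability, "r": self.r, "vafz": self.vafz,
            "regime": self.regime,
        }


@dataclass(frozen=True)
class PopulationModel:
    """Population parameters implied by a design cell."""

    loadings_true: np.ndarray  # J x Q, primaries sqrt(0.6), cross 0.5
    factor_corr: np.ndarray  # Q x Q, unit diagonal, off-diagonal r
    residual_sd: np.ndarray  # J item residual standard deviations
    b: float  # structural weight of every factor on z
    outcome_resid_sd: float

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.loadings_true))

    @property
    def structural_weights(self) -> np.ndarray:
        return np.full(self.factor_corr.shape[0], self.b)


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated dataset together with its ground truth."""

    data: np.ndarray  # N x J, standardized
    outcome: np.ndarray  # N, standardized
    truth: PopulationModel
    cell: DesignCell
    seed: int
    outcome_scale: float  # raw-outcome sd removed by standardization
    scores_true: np.ndarray = field(repr=False, default=None)
    standardization: StandardizationRecord = field(repr=False, default=None)


def build_population(cell: DesignCell, b: float = DEFAULT_B) -> PopulationModel:
    """Population loadings, residual scales and outcome noise for a cell.

    Residual variances solve ``reliability = explained / (explained + sd^2)``
    with ``explained = p_j^T Phi p_j``; the outcome noise solves
    ``vafz = var(b 1^T eta) / (var(b 1^T eta) + sd_z^2)`` with
    ``var(b 1^T eta) = b^2 (Q + Q (Q - 1) r)``.
    """
    q, k, j = cell.Q, cell.K, cell.J
    loadings = np.zeros((j, q))
    for f in range(q):
        loadings[f * k : (f + 1) * k, f] = np.sqrt(0.6)
    if cell.cross > 0:
        for f in range(q):
            # first item of block f cross-loads on the next factor, cyclically
            loadings[f * k, (f + 1) % q] = cell.cross
    phi = np.full((q, q), cell.r)
    np.fill_diagonal(phi, 1.0)
    explained = np.einsum("jq,qt,jt->j", loadings, phi, loadings)
    residual_var = explained * (1.0 - cell.reliability) / cell.reliability
    struct_var = b**2 * (q + q * (q - 1) * cell.r)
    outcome_resid_var = struct_var * (1.0 - cell.vafz) / cell.vafz
    return PopulationModel(
        loadings_true=loadings,
        factor_corr=phi,
        residual_sd=np.sqrt(residual_var),
        b=b,
        outcome_resid_sd=float(np.sqrt(outcome_resid_var)),
    )


def simulate(pop: PopulationModel, N: int, seed, cell: DesignCell = None) -> SimulatedDataset:
    """Draw one dataset from a population model.

    Factor scores are sampled from a zero-mean multivariate normal with
    covariance ``factor_corr`` (via its Cholesky factor, for bitwise
    reproducibility), item residuals and the outcome noise are independent
    normals.  Indicators and outcome are standardized empirically (their
    sample moments, not the population ones), so finite-sample deviations
    from the population reliabilities are intended sampling noise.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    try:
        chol = np.linalg.cholesky(pop.factor_corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("factor correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    q = pop.factor_corr.shape[0]
    eta = rng.standard_normal((N, q)) @ chol.T
    eps = rng.standard_normal((N, pop.loadings_true.shape[0])) * pop.residual_sd
    raw = eta @ pop.loadings_true.T + eps
    z_raw = pop.b * eta.sum(axis=1) + rng.standard_normal(N) * pop.outcome_resid_sd
    data, record = standardize(raw)
    z_mean = z_raw.mean()
    z_scale = float(np.sqrt(np.mean((z_raw - z_mean) ** 2)))
    outcome = (z_raw - z_mean) / z_scale
    return SimulatedDataset(
        data=np.asarray(data, dtype=float),
        outcome=outcome,
        truth=pop,
        cell=cell,
        seed=int(seed) if np.isscalar(seed) else seed,
        outcome_scale=z_scale,
        scores_true=eta,
        standardization=record,
    )


def design_grid(regime: str) -> list[DesignCell]:
    """Enumerate all design cells of a regime (192 low-dim, 48 high-dim)."""
    cells = []
    if regime == "low_dim":
        levels = LOW_DIM_LEVELS
        for n, q, k, cross, rel, r, vafz in itertools.product(
            levels["N"], levels["Q"], levels["K"], levels["cross"],
            levels["reliability"], levels["r"], levels["vafz"],
        ):
            cells.append(DesignCell(n, q, k, cross, rel, r, vafz, "low_dim"))
    elif regime == "high_dim":
        levels = LOW_DIM_LEVELS
        for k, cross, rel, r, vafz in itertools.product(
            HIGH_DIM_K, levels["cross"], levels["reliability"],
            levels["r"], levels["vafz"],
        ):
            cells.append(DesignCell(50, 5, k, cross, rel, r, vafz, "high_dim"))
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return cells


def dataset_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-dataset seed, enumerable and parallelizable."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cell(cell: DesignCell, base_seed: int, replicate: int,
                  cell_index: int = 0) -> SimulatedDataset:
    """Simulate one replicate of a cell under the study seed protocol."""
    pop = build_population(cell)
    return simulate(pop, cell.N, dataset_seed(base_seed, cell_index, replicate), cell)


def write_dataset(dataset: SimulatedDataset, out_dir, delimiter=","):
    """Write data, outcome, truth loadings and a JSON sidecar to a directory."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    j = dataset.data.shape[1]
    names = [f"item{i + 1}" for i in range(j)]
    pd.DataFrame(dataset.data, columns=names).to_csv(out / "data.csv", index=False, sep=delimiter)
    pd.DataFrame({"outcome": dataset.outcome}).to_csv(out / "outcome.csv", index=False, sep=delimiter)
    q = dataset.truth.loadings_true.shape[1]
    pd.DataFrame(dataset.truth.loadings_true, columns=[f"factor{i + 1}" for i in range(q)],
                 index=names).to_csv(out / "truth_loadings.csv", sep=delimiter)
    sidecar = {
        "cell": dataset.cell.to_dict() if dataset.cell is not None else None,
        "seed": dataset.seed,
        "outcome_scale": dataset.outcome_scale,
        "b": dataset.truth.b,
        "n_nonzero_true": dataset.truth.n_nonzero,
    }
    (out / "dataset.json").write_text(json.dumps(sidecar, indent=2))
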