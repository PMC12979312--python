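import numpy as np
import pytest

from sparsesem import DesignCell, build_population, simulate, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_standardized(rng):
    """A 20 x 6 standardized matrix with mild 2-factor structure."""
    eta = rng.standard_normal((20, 2))
    P = np.array([[0.8, 0.0], [0.7, 0.0], [0.6, 0.0], [0.0, 0.8], [0.0, 0.7], [0.3, 0.6]])
    raw = eta @ P.T + 0.4 * rng.standard_normal((20, 6))
    Y, _ = standardize(raw)
    return np.asarray(Y)


def make_noiseless(q=3, k=3, n=40, cross=0.0, seed=0):
    """Noiseless sparse factor data: residual sd forced to ~0."""
    cell = DesignCell(n, q, k, cross, 0.8, 0.0, 0.9)
    pop = build_population(cell)
    pop = type(pop)(
        loadings_true=pop.loadings_true,
        factor_corr=pop.factor_corr,
        residual_sd=np.full_like(pop.residual_sd, 1e-6),
        b=pop.b,
        outcome_resid_sd=pop.outcome_resid_sd,
    )
    return simulate(pop, n, seed, cell)


@pytest.fixture
def noiseless_dataset():
    return make_noiseless()
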