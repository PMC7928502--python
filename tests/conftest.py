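import numpy as np
import pytest

from bati.cohort import Cohort
from bati.design import GeneDesign, ModelConfig
from bati.simulate import BackgroundCohortSpec, simulate_background


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """200 samples, 30 genes; shared read-only across tests."""
    spec = BackgroundCohortSpec(n_samples=200, n_genes=30, seed=11)
    return simulate_background(spec)


@pytest.fixture(scope="session")
def two_param_design() -> GeneDesign:
    """Intercept + one variant (no characteristics): u is 2-dimensional."""
    rng = np.random.default_rng(5)
    n = 40
    G = rng.binomial(2, 0.15, size=(n, 1)).astype(float)
    eta = -0.3 + 0.9 * G[:, 0]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    return GeneDesign(
        gene_id="toy",
        y=y,
        X=np.ones((n, 1)),
        G=G,
        Z=np.empty((1, 0)),
        x_names=["intercept"],
    )


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


def quadrature_log_marginal(design: GeneDesign, config: ModelConfig,
                            psi: float, half_width: float = 8.0,
                            n_grid: int = 401) -> float:
    """Brute-force 2-D quadrature of the exact hyperparameter marginal.

    Only valid for designs with a 2-dimensional latent field
    (intercept + one variant).  Independent of the Laplace code path.
    """
    from bati.inference import _log_hyperprior

    assert design.n_latent == 2
    G = design.G[:, 0]
    y = design.y
    prec = np.array([config.fixed_effect_prior_precision, np.exp(psi)])
    a = np.linspace(-half_width, half_width, n_grid)
    # delta's posterior is no wider than its prior: shrink its range so
    # the grid resolves the narrow direction at high precision
    d_half = min(half_width, 12.0 * np.exp(-psi / 2.0) + 0.01)
    d = np.linspace(-d_half, d_half, n_grid)
    A, D = np.meshgrid(a, d, indexing="ij")
    eta = A[..., None] + D[..., None] * G
    ll = (y * eta - np.logaddexp(0.0, eta)).sum(-1)
    lp = (ll - 0.5 * (prec[0] * A**2 + prec[1] * D**2)
          + 0.5 * np.log(prec).sum() - np.log(2 * np.pi))
    m = lp.max()
    integral = m + np.log(np.exp(lp - m).sum() * (a[1] - a[0]) * (d[1] - d[0]))
    return float(integral + _log_hyperprior(psi, config))
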