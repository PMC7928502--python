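"""Laplace-approximation inference for the hierarchical logistic model.

The posterior factorises as p(u, tau | y) = p(u | tau, y) p(tau | y)
with latent field u = (alpha, omega, delta).  Inference follows the
integrated-nested-Laplace recipe specialised to this model:

1. for fixed log-precision psi = -log(tau), the conditional posterior
   p(u | psi, y) is approximated by a Gaussian centred at its mode
   (Newton iterations with step-halving);
2. the hyperparameter marginal p(psi | y) is approximated by the
   Laplace identity  p~(psi | y) ∝ p(y, u*, psi) / |H/2pi|^{1/2} and
   integrated over a mode-centred grid whose spacing scales with the
   local curvature;
3. latent fixed-effect marginals are weight-mixtures of the
   conditional Gaussians across the grid, and model fit is summarised
   by the deviance information criterion DIC = Dbar + pD.

Fixed effects have N(0, 1/c) priors; the random-effect precision
exp(psi) has a Gamma hyperprior (on the precision scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import brentq
from scipy.special import gammaln, ndtr, ndtri

from .design import GeneDesign, ModelConfig

_LOG_2PI = np.log(2.0 * np.pi)
_PROB_EPS = 1e-12


class ConvergenceError(RuntimeError):
    """Newton mode search failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class GaussianApprox:
    """Gaussian approximation to p(u | psi, y) at one grid point."""

    log_precision: float  # psi = -log tau
    mode: np.ndarray
    hessian: np.ndarray  # negative Hessian of joint log-posterior at mode
    chol: np.ndarray  # lower Cholesky factor of hessian
    log_det: float
    joint_log_density: float  # log p(y, u*, psi), hyperprior excluded
    n_iter: int = 0
    _cov_diag: np.ndarray | None = None

    def covariance_diag(self) -> np.ndarray:
        if self._cov_diag is None:
            inv = solve_triangular(self.chol, np.eye(len(self.mode)), lower=True)
            self._cov_diag = (inv * inv).sum(axis=0)
        return self._cov_diag


@dataclass
class TauPosterior:
    """Grid approximation to the hyperparameter posterior p(psi | y)."""

    log_precision_grid: np.ndarray
    log_density: np.ndarray  # unnormalised log p~(psi | y)
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.log_precision_grid) < 1:
            raise ValueError("hyperparameter grid needs at least one point")
        if not np.all(np.diff(self.log_precision_grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @property
    def mode_index(self) -> int:
        return int(np.argmax(self.weights))

    def mean_log_precision(self) -> float:
        return float(self.weights @ self.log_precision_grid)

    def mean_tau(self) -> float:
        return float(self.weights @ np.exp(-self.log_precision_grid))


@dataclass
class FitResult:
    """Posterior summaries and DIC for one hypothesis model."""

    gene_id: str
    hypothesis: str  # "null" or "full"
    effects: pd.DataFrame | None  # columns: name, kind, mean, sd, q025, q975
    dbar: float
    p_eff: float
    dic: float
    hyper: dict = field(default_factory=dict)
    status: str = "ok"  # ok / degenerate
    n_grid: int = 1
    n_variants: int = 0

    def __post_init__(self) -> None:
        if self.status == "ok" and not np.isfinite(self.dic):
            raise ValueError("DIC must be finite for a converged fit")


# ----------------------------------------------------------------------
# likelihood / prior pieces
# ----------------------------------------------------------------------

def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    return -2.0 * _bernoulli_loglik(eta, y)


def _prior_precisions(design: GeneDesign, config: ModelConfig,
                      log_precision: float) -> np.ndarray:
    c = config.fixed_effect_prior_precision
    return np.concatenate([
        np.full(design.m + design.q, c),
        np.full(design.p, np.exp(log_precision)),
    ])


def _log_hyperprior(log_precision: float, config: ModelConfig) -> float:
    """Log-density of psi when the precision kappa = e^psi is Gamma(a, b).

    Includes the Jacobian dkappa/dpsi = kappa of the change of
    variables, so densities are comparable across psi.
    """
    a, b = config.hyperprior_shape, config.hyperprior_rate
    return a * np.log(b) - gammaln(a) + a * log_precision - b * np.exp(log_precision)


# ----------------------------------------------------------------------
# conditional mode (inner Newton)
# ----------------------------------------------------------------------

def find_conditional_mode(
    design: GeneDesign,
    config: ModelConfig,
    log_precision: float,
    u0: np.ndarray | None = None,
    A: np.ndarray | None = None,
) -> GaussianApprox:
    """Newton mode search for p(u | psi, y) with step-halving.

    Maximises the Bernoulli log-likelihood plus the Gaussian log-priors
    of all latent blocks; converged when the penalised log-posterior
    improves by less than ``config.newton_tol``.
    """
    if not np.isfinite(log_precision):
        raise ValueError("log_precision must be finite")
    if A is None:
        A = design.predictor_matrix()
    y = design.y
    prec = _prior_precisions(design, config, log_precision)
    d = A.shape[1]
    log_prior_const = 0.5 * np.log(prec).sum() - 0.5 * d * _LOG_2PI

    def objective(u: np.ndarray, eta: np.ndarray) -> float:
        return (_bernoulli_loglik(eta, y)
                + log_prior_const - 0.5 * float(prec @ (u * u)))

    u = np.zeros(d) if u0 is None else np.array(u0, dtype=float)
    eta = A @ u
    f = objective(u, eta)
    trace = [f]
    for it in range(config.newton_max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = A.T @ (y - mu) - prec * u
        H = (A * w[:, None]).T @ A
        H[np.diag_indices(d)] += prec
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by priors
            raise ConvergenceError(f"singular Hessian at iteration {it}", trace) from exc
        # step-halving line search
        t = 1.0
        for _ in range(30):
            u_new = u + t * step
            eta_new = A @ u_new
            f_new = objective(u_new, eta_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        else:  # pragma: no cover - priors keep the problem well behaved
            raise ConvergenceError(f"line search failed at iteration {it}", trace)
        improvement = f_new - f
        u, eta, f = u_new, eta_new, f_new
        trace.append(f)
        if improvement < config.newton_tol:
            break
    else:
        raise ConvergenceError(
            f"Newton did not converge in {config.newton_max_iter} iterations", trace
        )

    # final Hessian at the mode
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (A * w[:, None]).T @ A
    H[np.diag_indices(d)] += prec
    L = np.linalg.cholesky(H)
    log_det = 2.0 * np.log(np.diag(L)).sum()
    return GaussianApprox(
        log_precision=float(log_precision),
        mode=u,
        hessian=H,
        chol=L,
        log_det=float(log_det),
        joint_log_density=f,
        n_iter=len(trace) - 1,
    )


def log_marginal_tau(
    design: GeneDesign,
    config: ModelConfig,
    log_precision: float,
    u0: np.ndarray | None = None,
    A: np.ndarray | None = None,
    return_approx: bool = False,
):
    """Unnormalised log p~(psi | y) via the Laplace identity.

    log p~(psi|y) = log p(y, u*, psi) + log p(psi)
                    - 0.5 log|H| + (d/2) log 2pi
    with all normalising constants kept so that prior-only Gaussian
    blocks cancel exactly.
    """
    ga = find_conditional_mode(design, config, log_precision, u0=u0, A=A)
    d = design.n_latent
    val = (ga.joint_log_density + _log_hyperprior(log_precision, config)
           - 0.5 * ga.log_det + 0.5 * d * _LOG_2PI)
    if return_approx:
        return float(val), ga
    return float(val)


# ----------------------------------------------------------------------
# hyperparameter grid
# ----------------------------------------------------------------------

def integrate_tau(
    design: GeneDesign, config: ModelConfig
) -> tuple[TauPosterior, list[GaussianApprox]]:
    """Mode-centred grid integration of the hyperparameter posterior.

    Locates the mode of log p~(psi | y), sets the grid step to
    ``grid_step_factor`` times the curvature-based standard deviation,
    and extends symmetrically until the log-density has dropped by
    ``grid_log_drop`` units (capped at ``grid_max_points``).
    """
    A = design.predictor_matrix()
    cache: dict[float, tuple[float, GaussianApprox]] = {}
    last_mode: list[np.ndarray | None] = [None]

    def f(psi: float) -> float:
        key = round(float(psi), 10)
        if key not in cache:
            val, ga = log_marginal_tau(
                design, config, psi, u0=last_mode[0], A=A, return_approx=True
            )
            last_mode[0] = ga.mode
            cache[key] = (val, ga)
        return cache[key][0]

    lo, hi = config.psi_bounds
    # coarse bracket followed by golden refinement
    coarse = np.arange(lo, hi + 1e-9, 2.0)
    vals = np.array([f(p) for p in coarse])
    i = int(np.argmax(vals))
    a = coarse[max(i - 1, 0)]
    b = coarse[min(i + 1, len(coarse) - 1)]
    gr = 0.5 * (np.sqrt(5.0) - 1.0)
    x1, x2 = b - gr * (b - a), a + gr * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > 0.12:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + gr * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - gr * (b - a)
            f1 = f(x1)
    psi_mode = 0.5 * (a + b)
    f_mode = f(psi_mode)

    h = 0.4
    curv = -(f(psi_mode + h) - 2.0 * f_mode + f(psi_mode - h)) / (h * h)
    sd = 1.0 / np.sqrt(curv) if curv > 1e-6 else 1.0
    step = config.grid_step_factor * sd

    points = [psi_mode]
    for direction in (+1.0, -1.0):
        k = 1
        while len(points) < config.grid_max_points:
            psi = psi_mode + direction * k * step
            if psi < lo or psi > hi:
                break
            if f_mode - f(psi) >= config.grid_log_drop:
                break
            points.append(psi)
            k += 1

    points = sorted(points)
    log_dens = np.array([f(p) for p in points])
    approxes = [cache[round(float(p), 10)][1] for p in points]
    w = np.exp(log_dens - log_dens.max())
    w /= w.sum()
    post = TauPosterior(
        log_precision_grid=np.array(points), log_density=log_dens, weights=w
    )
    return post, approxes


# ----------------------------------------------------------------------
# marginals, DIC
# ----------------------------------------------------------------------

def _mixture_moments(approxes: list[GaussianApprox], weights: np.ndarray):
    """Per-coefficient means and sds of each mixture component."""
    means = np.stack([g.mode for g in approxes])
    var = np.stack([g.covariance_diag() for g in approxes])
    return means, np.sqrt(var)


def _mixture_quantile(q: float, mu: np.ndarray, sd: np.ndarray,
                      w: np.ndarray) -> float:
    lo = float(np.min(mu - 10.0 * sd))
    hi = float(np.max(mu + 10.0 * sd))

    def cdf(x: float) -> float:
        return float(w @ ndtr((x - mu) / sd)) - q

    return brentq(cdf, lo, hi, xtol=1e-10)


def latent_marginals(
    design: GeneDesign,
    tau_posterior: TauPosterior,
    approxes: list[GaussianApprox],
    config: ModelConfig,
) -> pd.DataFrame:
    """Posterior summaries for every fixed-effect coefficient.

    Each coefficient's marginal is the grid-weight mixture of its
    per-grid-point Gaussian conditionals; reported are the mixture
    mean, sd and 2.5% / 97.5% quantiles.
    """
    if len(approxes) != len(tau_posterior.weights):
        raise ValueError("grid and approximation list are inconsistent")
    w = tau_posterior.weights
    means, sds = _mixture_moments(approxes, w)
    n_fixed = design.m + design.q
    names = design.fixed_effect_names()
    kinds = ["covariate"] * design.m + list(design.z_kinds)
    rows = []
    for i in range(n_fixed):
        mu_i, sd_i = means[:, i], sds[:, i]
        mean = float(w @ mu_i)
        var = float(w @ (sd_i**2 + mu_i**2) - mean**2)
        sd = float(np.sqrt(max(var, 0.0)))
        if len(w) == 1:
            lo = mean + ndtri(0.025) * sd
            hi = mean + ndtri(0.975) * sd
        else:
            lo = _mixture_quantile(0.025, mu_i, sd_i, w)
            hi = _mixture_quantile(0.975, mu_i, sd_i, w)
        rows.append((names[i], kinds[i], mean, sd, lo, hi))
    return pd.DataFrame(rows, columns=["name", "kind", "mean", "sd", "q025", "q975"])


def compute_dic(
    design: GeneDesign,
    tau_posterior: TauPosterior,
    approxes: list[GaussianApprox],
    config: ModelConfig,
    method: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Deviance information criterion of the fitted model.

    ``method="mc"``: Dbar is the average deviance over
    ``config.dic_samples`` draws from the mixture-of-Gaussians
    posterior; pD = Dbar - D(u_bar) with u_bar the posterior mean.
    ``method="plugin"``: deterministic second-order approximation,
    E[D] per component = D(u*) + trace(A'WA H^-1); used in fast
    permutation scans.
    """
    method = method or config.dic_method
    A = design.predictor_matrix()
    y = design.y
    w = tau_posterior.weights
    u_bar = np.einsum("k,kd->d", w, np.stack([g.mode for g in approxes]))
    d_at_mean = _deviance(A @ u_bar, y)

    if method == "plugin":
        dbar = 0.0
        for wk, g in zip(w, approxes):
            prec = _prior_precisions(design, config, g.log_precision)
            var_diag = g.covariance_diag()
            # trace(A'WA H^-1) = d - trace(P H^-1)
            trace_term = len(g.mode) - float(prec @ var_diag)
            dbar += wk * (_deviance(A @ g.mode, y) + trace_term)
    elif method == "mc":
        rng = rng or np.random.default_rng(config.seed)
        M = config.dic_samples
        counts = rng.multinomial(M, w)
        dev_sum, clamped = 0.0, False
        for g, n_k in zip(approxes, counts):
            if n_k == 0:
                continue
            z = rng.standard_normal((n_k, len(g.mode)))
            # H = L L' => cov = H^-1, samples = mode + L^-T z
            draws = g.mode + solve_triangular(g.chol, z.T, lower=True, trans="T").T
            eta = draws @ A.T
            prob_clip = np.clip(eta, -700, 700)
            ll = eta @ y - np.logaddexp(0.0, prob_clip).sum(axis=1)
            if not np.isfinite(ll).all():
                clamped = True
                mu = np.clip(1.0 / (1.0 + np.exp(-prob_clip)), _PROB_EPS, 1 - _PROB_EPS)
                ll = (np.log(mu) @ y + np.log1p(-mu) @ (1.0 - y))
            dev_sum += float(-2.0 * ll.sum())
        if clamped:
            warnings.warn("DIC sampling clamped degenerate probabilities", RuntimeWarning)
        dbar = dev_sum / M
    else:
        raise ValueError(f"unknown DIC method '{method}'")

    p_eff = dbar - d_at_mean
    return float(dbar), float(p_eff), float(dbar + p_eff)


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

def _single_point_posterior(ga: GaussianApprox) -> TauPosterior:
    return TauPosterior(
        log_precision_grid=np.array([ga.log_precision]),
        log_density=np.array([0.0]),
        weights=np.array([1.0]),
    )


def fit_model(
    design: GeneDesign,
    config: ModelConfig,
    hypothesis: str = "full",
    compute_effects: bool = True,
) -> FitResult:
    """Fit the null (covariates-only) or full (genetic) model.

    The null model is a Bayesian logistic regression on X alone — a
    single Laplace fit with no hyperparameter grid.  The full model
    runs the psi-grid pipeline.  A full fit with zero variants returns
    the null fit flagged ``degenerate``.  ``compute_effects=False``
    skips the marginal summaries (permutation scans need only DIC).
    """
    if hypothesis not in ("null", "full"):
        raise ValueError("hypothesis must be 'null' or 'full'")

    if hypothesis == "null" or design.p == 0:
        reduced = design.drop_variants()
        ga = find_conditional_mode(reduced, config, 0.0)
        post = _single_point_posterior(ga)
        effects = (latent_marginals(reduced, post, [ga], config)
                   if compute_effects else None)
        dbar, p_eff, dic = compute_dic(reduced, post, [ga], config)
        return FitResult(
            gene_id=design.gene_id,
            hypothesis=hypothesis,
            effects=effects,
            dbar=dbar,
            p_eff=p_eff,
            dic=dic,
            status="ok" if (hypothesis == "null" or design.p > 0) else "degenerate",
            n_grid=1,
            n_variants=0,
        )

    post, approxes = integrate_tau(design, config)
    effects = (latent_marginals(design, post, approxes, config)
               if compute_effects else None)
    dbar, p_eff, dic = compute_dic(design, post, approxes, config)
    return FitResult(
        gene_id=design.gene_id,
        hypothesis="full",
        effects=effects,
        dbar=dbar,
        p_eff=p_eff,
        dic=dic,
        hyper={
            "psi_mean": post.mean_log_precision(),
            "tau_mean": post.mean_tau(),
            "psi_mode": float(post.log_precision_grid[post.mode_index]),
        },
        n_grid=len(post.weights),
        n_variants=design.p,
    )
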