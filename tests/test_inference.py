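"""Unit and oracle tests for the Laplace/grid inference engine."""

import dataclasses

import numpy as np
import pytest

from bati.design import GeneDesign, ModelConfig
from bati.inference import (
    compute_dic,
    find_conditional_mode,
    fit_model,
    integrate_tau,
    latent_marginals,
    log_marginal_tau,
)

from conftest import quadrature_log_marginal


def _intercept_design(y):
    y = np.asarray(y)
    return GeneDesign(gene_id="g", y=y, X=np.ones((len(y), 1)),
                      G=np.empty((len(y), 0)), Z=np.empty((0, 0)),
                      x_names=["intercept"])


class TestConditionalMode:
    def test_balanced_intercept_mode_is_zero(self, default_config):
        ga = find_conditional_mode(_intercept_design([0, 1, 0, 1]),
                                   default_config, 0.0)
        assert abs(ga.mode[0]) < 1e-6

    def test_mode_matches_dense_grid_search(self, two_param_design,
                                            default_config):
        """Newton mode equals the brute-force maximiser of the penalised
        log-posterior on a dense 2-D grid."""
        psi = 1.0
        ga = find_conditional_mode(two_param_design, default_config, psi)
        prec = np.array([default_config.fixed_effect_prior_precision,
                         np.exp(psi)])
        G = two_param_design.G[:, 0]
        y = two_param_design.y

        def argmax_on(a, d):
            A, D = np.meshgrid(a, d, indexing="ij")
            eta = A[..., None] + D[..., None] * G
            lp = ((y * eta - np.logaddexp(0.0, eta)).sum(-1)
                  - 0.5 * (prec[0] * A**2 + prec[1] * D**2))
            i, j = np.unravel_index(lp.argmax(), lp.shape)
            return a[i], d[j]

        # coarse pass, then refine around the coarse maximiser
        a0, d0 = argmax_on(np.linspace(-2, 2, 401), np.linspace(-2, 2, 401))
        a1, d1 = argmax_on(np.linspace(a0 - 0.02, a0 + 0.02, 401),
                           np.linspace(d0 - 0.02, d0 + 0.02, 401))
        assert ga.mode[0] == pytest.approx(a1, abs=1e-4)
        assert ga.mode[1] == pytest.approx(d1, abs=1e-4)

    def test_infinite_shrinkage_limit(self, two_param_design, default_config):
        """|delta| at the mode decreases monotonically as the random-effect
        precision grows, approaching 0."""
        mags = []
        for psi in [0.0, 3.0, 6.0, 10.0, 14.0]:
            ga = find_conditional_mode(two_param_design, default_config, psi)
            mags.append(abs(ga.mode[1]))
        assert all(b <= a + 1e-12 for a, b in zip(mags, mags[1:]))
        assert mags[-1] < 1e-4

    def test_hessian_is_spd_at_mode(self, two_param_design, default_config):
        ga = find_conditional_mode(two_param_design, default_config, 0.0)
        eigvals = np.linalg.eigvalsh(ga.hessian)
        assert (eigvals > 0).all()
        assert np.isfinite(ga.log_det)

    def test_nonfinite_precision_rejected(self, two_param_design,
                                          default_config):
        with pytest.raises(ValueError):
            find_conditional_mode(two_param_design, default_config, np.inf)


class TestLogMarginalTau:
    @pytest.mark.parametrize("psi", [0.0, 2.0, 5.0, 9.0])
    def test_agrees_with_2d_quadrature(self, two_param_design, default_config,
                                       psi):
        """Laplace marginal within 0.05 log-units of exact quadrature."""
        ours = log_marginal_tau(two_param_design, default_config, psi)
        exact = quadrature_log_marginal(two_param_design, default_config, psi)
        assert ours == pytest.approx(exact, abs=0.05)

    def test_all_zero_genotype_column_is_free(self, two_param_design,
                                              default_config):
        """A variant nobody carries integrates out exactly: the marginal is
        unchanged when such a column is appended."""
        d = two_param_design
        d2 = GeneDesign(
            gene_id="g", y=d.y, X=d.X,
            G=np.hstack([d.G, np.zeros((d.n, 1))]),
            Z=np.empty((2, 0)), x_names=d.x_names,
        )
        for psi in (0.0, 4.0):
            v1 = log_marginal_tau(d, default_config, psi)
            v2 = log_marginal_tau(d2, default_config, psi)
            assert v2 == pytest.approx(v1, abs=1e-8)

    def test_variant_permutation_invariance(self, default_config):
        rng = np.random.default_rng(3)
        n, p = 60, 4
        G = rng.binomial(2, 0.1, size=(n, p)).astype(float)
        Z = np.column_stack([rng.integers(0, 2, p).astype(float),
                             rng.normal(20, 5, p)])
        y = rng.binomial(1, 0.5, n)
        d1 = GeneDesign(gene_id="g", y=y, X=np.ones((n, 1)), G=G, Z=Z)
        perm = rng.permutation(p)
        d2 = GeneDesign(gene_id="g", y=y, X=np.ones((n, 1)), G=G[:, perm],
                        Z=Z[perm])
        for psi in (0.0, 5.0):
            assert log_marginal_tau(d1, default_config, psi) == pytest.approx(
                log_marginal_tau(d2, default_config, psi), abs=1e-8
            )


class TestIntegrateTau:
    def test_weights_normalised_and_mode_interior(self, two_param_design,
                                                  default_config):
        post, apx = integrate_tau(two_param_design, default_config)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(post.log_precision_grid) > 0)
        k = post.mode_index
        # maximum-weight point is the interior mode of the grid
        assert post.log_density[k] == post.log_density.max()
        assert len(apx) == len(post.weights)

    def test_grid_refinement_stability(self, two_param_design, default_config):
        """Doubling the grid density moves posterior means by < 1e-3."""
        coarse = default_config
        fine = dataclasses.replace(coarse, grid_step_factor=0.25,
                                   grid_max_points=70)
        m1 = latent_marginals(two_param_design,
                              *integrate_tau(two_param_design, coarse), coarse)
        m2 = latent_marginals(two_param_design,
                              *integrate_tau(two_param_design, fine), fine)
        assert np.abs(m1["mean"].to_numpy() - m2["mean"].to_numpy()).max() < 1e-3


class TestLatentMarginals:
    def test_single_grid_point_reduces_to_gaussian(self, two_param_design,
                                                   default_config):
        from bati.inference import _single_point_posterior

        ga = find_conditional_mode(two_param_design, default_config, 2.0)
        post = _single_point_posterior(ga)
        m = latent_marginals(two_param_design, post, [ga], default_config)
        sd = np.sqrt(ga.covariance_diag()[0])
        assert m["mean"].iloc[0] == pytest.approx(ga.mode[0], abs=1e-9)
        assert m["sd"].iloc[0] == pytest.approx(sd, abs=1e-9)
        assert m["q025"].iloc[0] == pytest.approx(ga.mode[0] - 1.959964 * sd,
                                                  abs=1e-5)
        assert m["q975"].iloc[0] == pytest.approx(ga.mode[0] + 1.959964 * sd,
                                                  abs=1e-5)

    def test_mixture_quantiles_match_monte_carlo(self, two_param_design,
                                                 default_config):
        """Reported 2.5%/97.5% quantiles agree with empirical quantiles of
        10^6 draws from the same Gaussian mixture."""
        post, apx = integrate_tau(two_param_design, default_config)
        m = latent_marginals(two_param_design, post, apx, default_config)
        rng = np.random.default_rng(0)
        comp = rng.choice(len(post.weights), size=10**6, p=post.weights)
        mus = np.array([g.mode[0] for g in apx])
        sds = np.array([np.sqrt(g.covariance_diag()[0]) for g in apx])
        draws = rng.normal(mus[comp], sds[comp])
        assert m["q025"].iloc[0] == pytest.approx(
            np.quantile(draws, 0.025), abs=0.005)
        assert m["q975"].iloc[0] == pytest.approx(
            np.quantile(draws, 0.975), abs=0.005)


class TestDic:
    def test_plugin_deviance_closed_form(self):
        """Intercept-only, 5 cases of 10: deviance at the (near-flat-prior)
        mode is -2 * 10 * log(0.5)."""
        d = _intercept_design([1] * 5 + [0] * 5)
        cfg = ModelConfig(fixed_effect_prior_precision=1e-8,
                          dic_method="plugin")
        fr = fit_model(d, cfg, "null")
        d_at_mode = fr.dic - 2.0 * fr.p_eff  # D(u_bar) = DIC - 2 pD
        assert d_at_mode == pytest.approx(-2 * 10 * np.log(0.5), abs=1e-4)

    def test_effective_parameters_one_free_coefficient(self):
        """pD ~ 1 for a single weakly-penalised intercept (MC, M=10^4)."""
        d = _intercept_design([1] * 5 + [0] * 5)
        cfg = ModelConfig(fixed_effect_prior_precision=1e-6,
                          dic_samples=10**4, seed=1)
        fr = fit_model(d, cfg, "null")
        assert fr.p_eff == pytest.approx(1.0, abs=0.15)

    def test_monte_carlo_seed_stability(self, default_config):
        """DIC varies < 0.1 between independent seeds at M=10^5."""
        rng = np.random.default_rng(8)
        y = rng.binomial(1, 0.5, 20)
        d = _intercept_design(y)
        dics = []
        for seed in (1, 2):
            cfg = ModelConfig(dic_samples=10**5, seed=seed)
            dics.append(fit_model(d, cfg, "null").dic)
        assert abs(dics[0] - dics[1]) < 0.1

    def test_dic_additivity_and_finite_peff(self, two_param_design,
                                            default_config):
        for method in ("mc", "plugin"):
            cfg = dataclasses.replace(default_config, dic_method=method)
            fr = fit_model(two_param_design, cfg, "full")
            assert fr.dic == pytest.approx(fr.dbar + fr.p_eff, abs=1e-12)
            assert np.isfinite(fr.p_eff) and fr.p_eff >= -0.5


class TestFitModel:
    def test_empty_gene_full_fit_equals_null(self, default_config):
        d = _intercept_design([0, 1, 1, 0, 1])
        null = fit_model(d, default_config, "null")
        full = fit_model(d, default_config, "full")
        assert full.status == "degenerate"
        assert full.dic == pytest.approx(null.dic, abs=1e-6)

    def test_byte_identical_reruns(self, two_param_design, default_config):
        a = fit_model(two_param_design, default_config, "full")
        b = fit_model(two_param_design, default_config, "full")
        assert a.dic == b.dic and a.dbar == b.dbar
        assert a.effects.equals(b.effects)

    def test_invalid_hypothesis_rejected(self, two_param_design,
                                         default_config):
        with pytest.raises(ValueError):
            fit_model(two_param_design, default_config, "alternative")


class TestQuadratureEquivalence:
    def test_posterior_moments_match_exact_3d_quadrature(
            self, two_param_design, default_config):
        """Grid-Laplace fixed-effect posterior mean within 0.02 and sd
        within 5% of exhaustive (alpha, delta, psi) quadrature."""
        cfg = default_config
        G = two_param_design.G[:, 0]
        y = two_param_design.y

        psis = np.linspace(-3, 14, 60)
        log_marg = np.array([
            quadrature_log_marginal(two_param_design, cfg, p, half_width=6,
                                    n_grid=241)
            for p in psis
        ])
        w = np.exp(log_marg - log_marg.max())
        w /= w.sum()

        a = np.linspace(-4, 4, 241)
        de = np.linspace(-5, 5, 241)
        A, D = np.meshgrid(a, de, indexing="ij")
        eta = A[..., None] + D[..., None] * G
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(-1)
        mean = var = 0.0
        for p_k, w_k in zip(psis, w):
            prec = np.array([cfg.fixed_effect_prior_precision, np.exp(p_k)])
            lp = ll - 0.5 * (prec[0] * A**2 + prec[1] * D**2)
            wq = np.exp(lp - lp.max())
            wq /= wq.sum()
            m_k = (wq * A).sum()
            v_k = (wq * A**2).sum()
            mean += w_k * m_k
            var += w_k * v_k
        var -= mean**2

        post, apx = integrate_tau(two_param_design, cfg)
        marg = latent_marginals(two_param_design, post, apx, cfg)
        assert marg["mean"].iloc[0] == pytest.approx(mean, abs=0.02)
        assert marg["sd"].iloc[0] == pytest.approx(np.sqrt(var), rel=0.05)


class TestShrinkageMonotonicity:
    def test_posterior_delta_magnitude_nonincreasing_in_precision(
            self, two_param_design, default_config):
        mags = []
        for psi in np.linspace(-1, 12, 8):
            ga = find_conditional_mode(two_param_design, default_config, psi)
            mags.append(abs(ga.mode[1]))
        assert all(b <= a + 1e-10 for a, b in zip(mags, mags[1:]))
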