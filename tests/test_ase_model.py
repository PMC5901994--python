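import numpy as np
import pytest
from scipy import special, stats

from reqtl.ase_model import (
    AseGxeDesign,
    IGPrior,
    ase_lrt,
    estimate_ig_prior,
    fit_ase_gxe,
    fit_ase_model,
    fit_tsnp_variance,
    fold_count,
    marginal_loglik,
)
from tests.conftest import simulate_ase_design


class TestFoldCount:
    @pytest.mark.parametrize("y,n,expected", [(10, 30, 10), (25, 30, 5), (15, 30, 15)])
    def test_examples(self, y, n, expected):
        assert fold_count(y, n) == expected

    def test_y_above_n_errors(self):
        with pytest.raises(ValueError):
            fold_count(31, 30)

    def test_never_exceeds_half(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 200))
            y = int(rng.integers(0, n + 1))
            assert fold_count(y, n) <= n / 2


def _design_one(n, y, e=0.0, h=1.0):
    return AseGxeDesign(n=[n], y=[y], e=[e], h=[h])


class TestMarginalLoglik:
    def test_v_zero_exact_binomial(self):
        d = _design_one(10, 3)
        ll = marginal_loglik([0.0, 0.0, 0.0, 0.0, 0.0], d)
        assert ll == pytest.approx(np.log(special.comb(10, 3) * 0.5**10), abs=1e-12)

    def test_quadrature_matches_dense_trapezoid(self):
        # m=4, n=12, eta=0.3, v=0.5 against 4000-point trapezoid on [-8 sd, 8 sd]
        m, n, eta, v = 4, 12, 0.3, 0.5
        eps = np.linspace(-8 * np.sqrt(v), 8 * np.sqrt(v), 4000)
        integrand = stats.binom.pmf(m, n, special.expit(eta + eps)) * stats.norm.pdf(
            eps, 0, np.sqrt(v)
        )
        dense = np.log(np.trapezoid(integrand, eps))
        d = _design_one(12, 4)
        got = marginal_loglik([eta, 0.0, 0.0, 0.0, v], d)
        assert abs((got - dense) / dense) < 1e-6

    def test_node_count_converged(self, prior):
        design, _ = simulate_ase_design(42, n_samples=120, mu_s=0.4, gamma_sh=0.3)
        params = np.array([0.2, 0.1, -0.1, 0.05, 0.01])
        l20 = marginal_loglik(params, design, n_nodes=20)
        l40 = marginal_loglik(params, design, n_nodes=40)
        assert abs(l20 - l40) < 1e-6

    def test_prior_term_added(self, prior):
        d = _design_one(12, 4)
        base = marginal_loglik([0.1, 0, 0, 0, 0.01], d)
        with_prior = marginal_loglik([0.1, 0, 0, 0, 0.01], d, prior=prior)
        assert with_prior == pytest.approx(base + prior.logpdf(0.01), abs=1e-10)

    def test_negative_variance_errors(self):
        with pytest.raises(ValueError):
            marginal_loglik([0, 0, 0, 0, -0.1], _design_one(10, 3))

    def test_nonfinite_predictor_errors(self):
        with pytest.raises(ValueError, match="finite"):
            marginal_loglik([np.inf, 0, 0, 0, 0.1], _design_one(10, 3))

    def test_mixture_even_in_eta(self):
        d = _design_one(20, 6)
        a = marginal_loglik([0.7, 0, 0, 0, 0.2], d, likelihood="mixture")
        b = marginal_loglik([-0.7, 0, 0, 0, 0.2], d, likelihood="mixture")
        # quadrature nodes center on the lead term, so evenness holds to
        # quadrature accuracy rather than machine precision
        assert a == pytest.approx(b, abs=1e-7)


class TestFit:
    def test_folding_symmetry(self, prior):
        design, _ = simulate_ase_design(7, n_samples=200, mu_s=0.4, beta_seh=0.8)
        swapped = AseGxeDesign(
            n=design.n, y=design.n - design.y, e=design.e, h=design.h
        )
        f1, _ = fit_ase_gxe(design, prior)
        f2, _ = fit_ase_gxe(swapped, prior)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-8)
        assert f1.p_value == pytest.approx(f2.p_value, abs=1e-10)

    def test_interaction_never_decreases_objective(self, prior):
        for seed in (1, 2, 3):
            design, _ = simulate_ase_design(seed, n_samples=150, mu_s=0.5)
            full, null = fit_ase_gxe(design, prior)
            assert full.loglik >= null.loglik - 1e-6

    def test_matches_fixed_effect_glm_when_unoverdispersed(self):
        # data straight from a fixed-effect binomial: ML v -> 0, betas -> GLM
        statsmodels = pytest.importorskip("statsmodels.api")
        # keep eta well below 0 so min(y, n-y) = y always: the folded model
        # is then exactly a fixed-effect binomial GLM and ML v -> 0
        rng = np.random.default_rng(3)
        n_obs = 400
        e = rng.integers(0, 2, n_obs).astype(float)
        h = rng.integers(0, 2, n_obs).astype(float)
        n = np.full(n_obs, 80)
        eta = -1.6 + 0.3 * e + 0.2 * h + 0.25 * e * h
        y = rng.binomial(n, special.expit(eta))
        assert (y < n - y).all()
        m = np.minimum(y, n - y)
        design = AseGxeDesign(n=n, y=y, e=e, h=h)
        fit = fit_ase_model(design, prior=None, include_interaction=True)
        X = design.matrix(True)
        glm = statsmodels.GLM(
            np.column_stack([m, n - m]), X, family=statsmodels.families.Binomial()
        ).fit()
        assert fit.v < 1e-4
        np.testing.assert_allclose(fit.params[:-1], glm.params, atol=2e-3)

    def test_constant_environment_errors(self, prior):
        d = AseGxeDesign(n=[50, 60], y=[20, 30], e=[1.0, 1.0], h=[1.0, 0.0])
        with pytest.raises(ValueError, match="environment"):
            fit_ase_model(d, prior)

    def test_no_double_het_errors(self, prior):
        d = AseGxeDesign(n=[50, 60], y=[20, 30], e=[0.0, 1.0], h=[0.0, 0.0])
        with pytest.raises(ValueError, match="double heterozygotes"):
            fit_ase_model(d, prior)

    def test_parameter_recovery_smoke(self, prior):
        # scaled-down recovery (5 seeds; acceptance runs 20): beta=1.5,
        # dichotomous env, sign aligned via mu (folding flips all signs)
        est = []
        for seed in range(5):
            design, _ = simulate_ase_design(
                100 + seed, n_samples=600, mu_s=0.5, beta_seh=1.5, env_kind="dichotomous"
            )
            fit, _ = fit_ase_gxe(design, prior)
            est.append(fit.beta_seh * np.sign(fit.mu) * np.sign(0.5))
        assert 1.0 <= np.mean(est) <= 2.0

    def test_covariates_enter_linear_predictor(self, prior, rng):
        design, _ = simulate_ase_design(9, n_samples=200, mu_s=0.4)
        cov = rng.standard_normal((design.n_obs, 2))
        with_cov = AseGxeDesign(n=design.n, y=design.y, e=design.e, h=design.h, covariates=cov)
        fit = fit_ase_model(with_cov, prior)
        assert fit.cov_effects.shape == (2,)


class TestLrt:
    def _dummy(self, ll):
        from reqtl.ase_model import AseGxeFit

        return AseGxeFit(0, 0, 0, None, np.array([]), 0.01, ll, True, 10)

    def test_lambda_zero_gives_one(self):
        assert ase_lrt(self._dummy(-5.0), self._dummy(-5.0)) == 1.0

    def test_chi2_quantile(self):
        # lambda = 3.841459 is the 95% chi2_1 quantile
        p = ase_lrt(self._dummy(-5.0 + 3.841459 / 2), self._dummy(-5.0))
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_violation_errors(self):
        with pytest.raises(ValueError, match="refit"):
            ase_lrt(self._dummy(-6.0), self._dummy(-5.0))

    def test_monte_carlo_alpha(self, prior):
        # scaled-down null check (120 sims; acceptance runs 1000)
        rejections = 0
        n_sims = 120
        for seed in range(n_sims):
            design, _ = simulate_ase_design(
                5000 + seed, n_samples=200, mu_s=0.5, gamma_sh=0.2
            )
            full, _ = fit_ase_gxe(design, prior)
            rejections += full.p_value <= 0.05
        rate = rejections / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) <= 3 * se + 1e-9


class TestIgPrior:
    def test_self_consistency_at_reference_values(self):
        rng = np.random.default_rng(2024)
        draws = 1.0 / rng.gamma(1.80, 1.0 / 0.0024, 5000)
        prior = estimate_ig_prior(draws)
        assert 1.6 <= prior.a <= 2.0
        assert 0.002 <= prior.b <= 0.003

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        draws = 1.0 / rng.gamma(2.5, 1.0 / 0.01, 400)
        prior = estimate_ig_prior(draws, min_estimates=50)

        def nll(a, b):
            return -stats.invgamma.logpdf(draws, a, scale=b).sum()

        # coarse-to-fine grid around the ML solution
        a_grid = np.linspace(prior.a * 0.8, prior.a * 1.2, 81)
        b_grid = np.linspace(prior.b * 0.8, prior.b * 1.2, 81)
        grid_vals = np.array([[nll(a, b) for b in b_grid] for a in a_grid])
        ia, ib = np.unravel_index(grid_vals.argmin(), grid_vals.shape)
        assert nll(prior.a, prior.b) <= grid_vals[ia, ib] + 1e-6

    def test_nonpositive_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        draws = np.concatenate([1.0 / rng.gamma(2.0, 100.0, 100), [-1.0, 0.0]])
        with pytest.warns(UserWarning, match="non-positive"):
            estimate_ig_prior(draws)

    def test_too_few_errors(self):
        with pytest.raises(ValueError, match=">= 50"):
            estimate_ig_prior(np.full(10, 0.1))

    def test_degenerate_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_ig_prior(np.full(60, 0.1))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            IGPrior(-1.0, 0.5)

    def test_tsnp_variance_fit_recovers_overdispersion(self):
        rng = np.random.default_rng(77)
        n = np.full(400, 100)
        v_true = 0.25
        eps = rng.normal(0, np.sqrt(v_true), 400)
        y = rng.binomial(n, special.expit(0.5 + eps))
        mu, v = fit_tsnp_variance(n, y)
        assert 0.1 < v < 0.5
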