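"""Zero-inflated beta distribution functions and marginal fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize, special, stats

import copulacov as cc
from copulacov.errors import InsufficientDataError
from copulacov.margins import MarginModel, _fit_beta_newton


class TestDistributionFunctions:
    def test_beta_pdf_uniform_case(self):
        # mu*phi = (1-mu)*phi = 1 is the uniform density
        assert cc.beta_pdf(0.5, 0.5, 2.0) == pytest.approx(1.0)
        assert cc.beta_pdf(0.3, 0.5, 2.0) == pytest.approx(1.0)

    def test_beta_pdf_against_quadrature_normalization(self):
        # oracle: numerically normalized kernel x^(a-1)(1-x)^(b-1)
        mu, phi = 2 / 7, 7.0
        a, b = mu * phi, (1 - mu) * phi
        norm, _ = integrate.quad(lambda x: x ** (a - 1) * (1 - x) ** (b - 1), 0, 1)
        x = 0.5
        assert cc.beta_pdf(x, mu, phi) == pytest.approx(
            x ** (a - 1) * (1 - x) ** (b - 1) / norm, rel=1e-9
        )

    def test_zib_pdf_atom_and_continuous(self):
        g = cc.ZIBParams(0.3, 0.5, 2.0)
        assert cc.zib_pdf(0.0, g) == pytest.approx(0.3)
        assert cc.zib_pdf(0.5, g) == pytest.approx(0.7)
        assert cc.zib_pdf(0.0, cc.ZIBParams(0.0, 0.5, 2.0)) == 0.0

    def test_zib_pdf_total_mass_one(self):
        for p in (0.0, 0.2, 0.6):
            for mu, phi in [(0.3, 5.0), (0.7, 2.0)]:
                g = cc.ZIBParams(p, mu, phi)
                cont, _ = integrate.quad(lambda x: cc.zib_pdf(x, g), 1e-12, 1 - 1e-12)
                assert p + cont == pytest.approx(1.0, abs=1e-8)

    def test_zib_cdf_jump_and_left_limit(self):
        g = cc.ZIBParams(0.4, 0.5, 2.0)
        assert cc.zib_cdf(0.0, g) == pytest.approx(0.4)
        assert cc.zib_cdf(0.0, g, left_limit=True) == 0.0
        # uniform beta part: F(0.5) = 0.4 + 0.6*0.5
        assert cc.zib_cdf(0.5, g) == pytest.approx(0.7)
        assert cc.zib_cdf(0.5, g, left_limit=True) == pytest.approx(0.7)

    def test_zib_cdf_monotone(self):
        g = cc.ZIBParams(0.25, 0.4, 6.0)
        x = np.linspace(0, 1 - 1e-9, 200)
        F = cc.zib_cdf(x, g)
        assert np.all(np.diff(F) >= 0)

    def test_zib_quantile_branches(self):
        g = cc.ZIBParams(0.4, 0.5, 2.0)
        assert cc.zib_quantile(0.3, g) == 0.0
        assert cc.zib_quantile(0.7, g) == pytest.approx(0.5)

    @given(u=st.floats(0.01, 0.99), p=st.floats(0.0, 0.8),
           mu=st.floats(0.1, 0.9), phi=st.floats(0.5, 20))
    def test_quantile_cdf_round_trip(self, u, p, mu, phi):
        g = cc.ZIBParams(p, mu, phi)
        x = cc.zib_quantile(u, g)
        if u > p:
            assert cc.zib_cdf(x, g) == pytest.approx(u, abs=1e-8)
        else:
            assert x == 0.0

    def test_zib_loglik_examples_and_identity(self, rng):
        assert cc.zib_loglik([0.0, 0.5], cc.ZIBParams(0.5, 0.5, 2.0)) == pytest.approx(
            2 * np.log(0.5)
        )
        assert cc.zib_loglik([0.5], cc.ZIBParams(0.0, 0.5, 2.0)) == pytest.approx(0.0)
        g = cc.ZIBParams(0.3, 0.4, 5.0)
        x = cc.sample_pair(n=200, theta=0.0, gamma_i=g, gamma_j=g, rng=rng).x_i
        direct = sum(np.log(cc.zib_pdf(xi, g)) for xi in x)
        assert cc.zib_loglik(x, g) == pytest.approx(direct, abs=1e-10)

    def test_domain_errors(self):
        g = cc.ZIBParams(0.3, 0.5, 2.0)
        with pytest.raises(ValueError):
            cc.zib_pdf(1.0, g)
        with pytest.raises(ValueError):
            cc.zib_cdf(-0.1, g)
        with pytest.raises(ValueError):
            cc.zib_quantile(1.0, g)
        with pytest.raises(ValueError):
            cc.ZIBParams(1.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            cc.ZIBParams(0.2, 0.5, -1.0)


class TestFitMargin:
    def test_intercept_only_zero_fraction_is_exact(self, rng):
        x = np.concatenate([np.zeros(20), rng.beta(2, 3, size=30)])
        fit = cc.fit_margin(x)
        assert fit.p[0] == pytest.approx(0.4, abs=0)
        assert fit.n_zero == 20

    def test_loglik_field_matches_zib_loglik(self, paired_sample):
        fit = cc.fit_margin(paired_sample.x_i)
        assert fit.loglik == pytest.approx(
            cc.zib_loglik(paired_sample.x_i, (fit.p, fit.mu, fit.phi)), abs=1e-10
        )

    def test_parameter_recovery_large_n(self, rng):
        truth = cc.ZIBParams(0.25, 2 / 7, 7.0)
        x = cc.sample_pair(n=2000, theta=0.0, gamma_i=truth, gamma_j=truth, rng=rng).x_i
        fit = cc.fit_margin(x)
        assert abs(fit.p[0] - truth.p) <= 3 * fit.se["p"]
        assert abs(fit.mu[0] - truth.mu) <= 3 * fit.se["mu"]
        assert abs(fit.phi[0] - truth.phi) <= 3 * fit.se["phi"]

    def test_optimum_dominates_truth(self, rng):
        truth = cc.ZIBParams(0.3, 0.4, 5.0)
        for _ in range(5):
            x = cc.sample_pair(n=60, theta=0.0, gamma_i=truth, gamma_j=truth, rng=rng).x_i
            fit = cc.fit_margin(x)
            assert fit.loglik >= cc.zib_loglik(x, truth) - 1e-9

    def test_pure_beta_matches_generic_optimizer(self, rng):
        x = rng.beta(2.0, 5.0, size=300)
        fit = cc.fit_margin(x)
        assert fit.p[0] == 0.0

        def nll(z):
            return -np.sum(stats.beta.logpdf(x, np.exp(z[0]), np.exp(z[1])))

        res = optimize.minimize(nll, [np.log(2), np.log(5)], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-12})
        a, b = np.exp(res.x)
        assert fit.mu[0] == pytest.approx(a / (a + b), abs=1e-6)
        assert fit.phi[0] == pytest.approx(a + b, abs=1e-5 * (a + b))

    def test_logistic_covariate_recovery(self, rng):
        s = cc.sample_pair_covariate(n=2000, theta=0.0, coef_i=(-0.5, 0.7),
                                     coef_j=(-0.3, 0.4), rng=rng)
        Q = np.column_stack([np.ones(2000), s.covariate_i])
        fit = cc.fit_margin(s.x_i, MarginModel(design_p=Q))
        for est, true, se in zip(fit.rho, (-0.5, 0.7), fit.se["rho"]):
            assert abs(est - true) <= 3 * se

    def test_insufficient_nonzero_raises(self):
        x = np.concatenate([np.zeros(48), [0.2, 0.4]])
        with pytest.raises(InsufficientDataError):
            cc.fit_margin(x)

    def test_clamping_warns(self):
        x = np.concatenate([np.full(5, 0.5), [1.0 - 1e-13]])
        with pytest.warns(UserWarning, match="clamped"):
            cc.fit_margin(x)

    def test_newton_agrees_with_mom_free_optimizer(self, rng):
        # ill-conditioned small-n beta fit still reaches the optimizer's optimum
        x = rng.beta(0.8, 9.0, size=12)
        mu, phi, _, _ = _fit_beta_newton(x)

        def nll(z):
            return -np.sum(stats.beta.logpdf(x, np.exp(z[0]), np.exp(z[1])))

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000})
        assert -nll([np.log(mu * phi), np.log((1 - mu) * phi)]) >= -res.fun - 1e-7
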