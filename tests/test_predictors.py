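"""Weighted predictors: posterior kernel, prediction, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import norm

from glmmflag.families import LinearPredictorSpec, get_family
from glmmflag.predictors import (UNREACHABLE, PredictorContext,
                                 WeightDivergenceError, WeightSpec, invert,
                                 log_posterior_kernel, predict)

BINOM = get_family("binomial_logit")
GAUSS = get_family("gaussian_identity")

ALL_WEIGHTS = [WeightSpec.bp(), WeightSpec("SQ", 0.2), WeightSpec("SQ", 0.3),
               WeightSpec("SQ", 0.4), WeightSpec("AB", 1.2),
               WeightSpec("AB", 1.6), WeightSpec("AB", 2.0)]


def gaussian_posterior(lp: LinearPredictorSpec, gamma: float, y: float):
    """Conjugate posterior N(M, 1/P) of z given the Gaussian-total y."""
    P = 1.0 + gamma * lp.n * lp.sigma_u ** 2
    M = gamma * lp.sigma_u * (y - lp.fixed_part.sum()) / P
    return M, P


def gaussian_ab_predictor(M: float, P: float, lam: float) -> float:
    """Closed-form absolute-weighted posterior mean for N(M, 1/P)."""
    s = 1.0 / math.sqrt(P)
    mp, mm = M + lam * s * s, M - lam * s * s
    wp = math.exp(lam * M) * norm.cdf(mp / s)
    wm = math.exp(-lam * M) * norm.cdf(-mm / s)
    num = (math.exp(lam * M) * (mp * norm.cdf(mp / s) + s * norm.pdf(mp / s))
           + math.exp(-lam * M) * (mm * norm.cdf(-mm / s)
                                   - s * norm.pdf(mm / s)))
    return num / (wp + wm)


class TestPosteriorKernel:
    def test_logit_mirror_symmetry(self):
        # Bernoulli, mu=0: kernel for y=1 at z mirrors kernel for y=0 at -z
        ctx = PredictorContext.intercept_only(BINOM, 0.0, 1, 1.0)
        z = np.linspace(-3, 3, 13)
        k1 = log_posterior_kernel(ctx, 1, z)
        k0 = log_posterior_kernel(ctx, 0, -z)
        d = (k1 - k0).ravel()
        np.testing.assert_allclose(d, d[0], atol=1e-12)

    def test_gaussian_kernel_is_conjugate_quadratic(self):
        lp = LinearPredictorSpec.intercept_only(0.7, 6, 0.5)
        gamma = 2.0
        fam = get_family("gaussian_identity", scale=gamma)
        ctx = PredictorContext(fam, lp)
        y = 6.1
        M, P = gaussian_posterior(lp, gamma, y)
        z = np.linspace(-2, 2, 9)
        kern = log_posterior_kernel(ctx, y, z).ravel()
        exact = -0.5 * P * (z - M) ** 2
        d = kern - exact
        np.testing.assert_allclose(d, d[0], atol=1e-10)

    def test_kernel_derivative_in_total_is_gamma_sigma_z(self):
        # d log f / dY. = gamma * sigma_u * z, by finite difference in Y.
        ctx = PredictorContext.intercept_only(BINOM, -1.0, 10, 0.8)
        z = np.array([-1.5, 0.3, 2.0])
        d = (log_posterior_kernel(ctx, 4.0, z)
             - log_posterior_kernel(ctx, 3.0, z)).ravel()
        np.testing.assert_allclose(d, 0.8 * z, atol=1e-12)


class TestPredict:
    def test_lambda_zero_equals_best_predictor(self):
        ctx = PredictorContext.intercept_only(BINOM, -1.0, 10, 0.8)
        y = np.arange(11)
        bp = predict(ctx, y)
        for kind in ("SQ", "AB"):
            np.testing.assert_array_equal(
                predict(ctx.with_weight(WeightSpec(kind, 0.0)), y), bp)

    @pytest.mark.parametrize("weight", ALL_WEIGHTS,
                             ids=lambda w: f"{w.kind}-{w.lam}")
    def test_symmetric_posterior_gives_zero(self, weight):
        ctx = PredictorContext.intercept_only(BINOM, 0.0, 10, 1.0, weight)
        assert predict(ctx, 5) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_conjugate_closed_forms(self):
        lp = LinearPredictorSpec.intercept_only(0.2, 8, 0.6)
        gamma = 1.5
        fam = get_family("gaussian_identity", scale=gamma)
        for y in (0.3, 2.5, 4.0):
            M, P = gaussian_posterior(lp, gamma, y)
            bp = predict(PredictorContext(fam, lp), y)
            assert bp == pytest.approx(M, abs=1e-8)
            for lam in (0.1, 0.3):
                sq = predict(PredictorContext(
                    fam, lp, WeightSpec("SQ", lam)), y)
                assert sq == pytest.approx(M * P / (P - 2 * lam), abs=1e-8)
            for lam in (0.8, 1.6):
                ab = predict(PredictorContext(
                    fam, lp, WeightSpec("AB", lam)), y)
                assert ab == pytest.approx(
                    gaussian_ab_predictor(M, P, lam), abs=1e-8)

    def test_sufficiency_of_cluster_total(self):
        # cluster-constant covariates: unit-level X and the intercept-only
        # reduction give identical predictions
        beta = np.array([0.4, -0.6])
        x = np.array([1.0, 0.5])
        n = 9
        lp_units = LinearPredictorSpec(beta, np.tile(x, (n, 1)), 0.7)
        lp_total = LinearPredictorSpec.intercept_only(
            float(x @ beta), n, 0.7)
        w = WeightSpec("AB", 1.6)
        y = np.arange(n + 1)
        np.testing.assert_array_equal(
            predict(PredictorContext(BINOM, lp_units, w), y),
            predict(PredictorContext(BINOM, lp_total, w), y))

    def test_best_predictor_matches_self_normalized_monte_carlo(self, rng):
        from scipy.stats import binom as binom_dist
        for (mu, n, s, y) in [(-1.0, 7, 0.8, 6), (0.5, 20, 0.4, 3),
                              (-2.0, 100, 1.0, 30)]:
            ctx = PredictorContext.intercept_only(BINOM, mu, n, s)
            z = rng.standard_normal(1_000_000)
            w = binom_dist.pmf(y, n, expit(mu + s * z))
            est = np.average(z, weights=w)
            se = np.sqrt(np.sum((w * (z - est)) ** 2)) / w.sum()
            assert predict(ctx, y) == pytest.approx(est, abs=3 * se)

    def test_sq_divergence_raises_naming_lambda(self):
        ctx = PredictorContext.intercept_only(
            BINOM, 0.0, 5, 0.5, WeightSpec("SQ", 0.5))
        with pytest.raises(WeightDivergenceError, match="0.5"):
            predict(ctx, 3)


class TestMonotonicityAndShrinkage:
    @pytest.mark.parametrize("weight", ALL_WEIGHTS,
                             ids=lambda w: f"{w.kind}-{w.lam}")
    @pytest.mark.parametrize("mu,n,sigma_u", [
        (-1.0, 5, 0.3), (-1.0, 100, 1.2), (0.0, 20, 0.6), (1.0, 10, 0.9)])
    def test_predictor_nondecreasing_in_total(self, weight, mu, n, sigma_u):
        ctx = PredictorContext.intercept_only(BINOM, mu, n, sigma_u, weight)
        zt = predict(ctx, np.arange(n + 1))
        assert np.all(np.diff(zt) >= -1e-10)

    @given(st.integers(2, 30), st.floats(-1.5, 1.5), st.floats(0.1, 1.2))
    def test_weighted_shrink_less_than_bp_symmetric(self, n, mu, sigma_u):
        # at mu=0 the posterior is symmetric under y -> n-y, so the
        # |weighted| >= |BP| ordering is clean; we centre mu at 0
        ctx = PredictorContext.intercept_only(BINOM, 0.0, n, sigma_u)
        y = np.arange(n + 1)
        bp = np.abs(predict(ctx, y))
        for w in (WeightSpec("SQ", 0.3), WeightSpec("AB", 1.6)):
            wp = np.abs(predict(ctx.with_weight(w), y))
            assert np.all(wp >= bp - 1e-10)


class TestInvert:
    def test_unreachable_threshold_returns_sentinel(self):
        ctx = PredictorContext.intercept_only(BINOM, -1.0, 5, 0.3)
        assert invert(ctx, 2.0) == UNREACHABLE

    def test_definitional_bracketing(self):
        ctx = PredictorContext.intercept_only(
            BINOM, -0.5, 20, 0.8, WeightSpec("AB", 1.2))
        tau = 1.28
        y = invert(ctx, tau)
        assert predict(ctx, y) < tau <= predict(ctx, y + 1)

    def test_below_support_when_everything_flags(self):
        ctx = PredictorContext.intercept_only(BINOM, -3.0, 50, 1.0)
        tau = float(predict(ctx, 0)) - 0.5
        assert invert(ctx, tau) == -1.0

    def test_gaussian_root_matches_closed_form(self):
        lp = LinearPredictorSpec.intercept_only(0.4, 6, 0.5)
        gamma = 1.0
        fam = get_family("gaussian_identity", scale=gamma)
        ctx = PredictorContext(fam, lp)
        tau = 0.9
        y = invert(ctx, tau)
        M, P = gaussian_posterior(lp, gamma, 0.0)
        # BP: ztilde = gamma sigma (y - sum_f)/P = tau
        expect = lp.fixed_part.sum() + tau * P / (gamma * lp.sigma_u)
        assert y == pytest.approx(expect, abs=1e-8)

    def test_sigma_zero_raises(self):
        ctx = PredictorContext.intercept_only(BINOM, 0.0, 5, 0.0)
        with pytest.raises(ValueError, match="sigma_u"):
            invert(ctx, 1.0)
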