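"""Conditional MSEP: closed forms, consistency and enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from glmmflag.families import (LinearPredictorSpec, get_family,
                               total_distribution)
from glmmflag.msep import (msep_binary, msep_difference, msep_generic,
                           msep_poisson)
from glmmflag.predictors import PredictorContext, WeightSpec, predict
from glmmflag.quadrature import make_rule

BINOM = get_family("binomial_logit")
POIS = get_family("poisson_log")


def truncated_normal_msep(c: float, tau: float) -> float:
    """E[(z - c)^2 | z > tau] from truncated-normal moment identities."""
    h = norm.pdf(tau) / norm.sf(tau)
    mean = h
    var = 1.0 + tau * h - h * h
    return var + (mean - c) ** 2


class TestDegenerateAndLimits:
    @pytest.mark.parametrize("c", [0.0, 0.7, -1.2])
    def test_constant_predictor_recovers_truncated_normal_moments(self, c):
        ctx = PredictorContext.intercept_only(BINOM, -1.0, 6, 0.5)
        tau = 1.28
        res = msep_generic(ctx, tau,
                           predict_fn=lambda y: np.full(np.size(y), c))
        assert res.msep == pytest.approx(truncated_normal_msep(c, tau),
                                         abs=1e-10)

    def test_no_information_limit_is_truncated_variance_plus_bias(self):
        # sigma_u -> 0 with the predictor forced to its limit value 0
        ctx = PredictorContext.intercept_only(BINOM, -1.0, 6, 1e-8)
        tau = 1.645
        res = msep_generic(ctx, tau,
                           predict_fn=lambda y: np.zeros(np.size(y)))
        assert res.msep == pytest.approx(truncated_normal_msep(0.0, tau),
                                         abs=1e-9)

    def test_poisson_vanishing_mean_only_k0_contributes(self):
        lp = LinearPredictorSpec.intercept_only(-12.0, 1, 0.2)
        ctx = PredictorContext(POIS, lp)
        tau = 1.28
        res = msep_poisson(ctx, tau)
        z0 = predict(ctx, 0.0)
        assert res.msep == pytest.approx(truncated_normal_msep(z0, tau),
                                         rel=1e-5)


class TestRouteConsistency:
    def test_generic_equals_binary_closed_form(self):
        ctx = PredictorContext.intercept_only(
            BINOM, -1.0, 12, 0.7, WeightSpec("AB", 1.6))
        tau = 1.28
        total = total_distribution(BINOM, ctx.lp)
        a = msep_binary(ctx, tau).msep
        b = msep_generic(ctx, tau, total=total).msep
        assert a == pytest.approx(b, abs=1e-10)

    def test_poisson_entry_point_equals_generic(self):
        ctx = PredictorContext.intercept_only(POIS, -1.5, 10, 0.6)
        tau = 1.28
        probe = make_rule(tau, np.inf, 64)
        total = total_distribution(POIS, ctx.lp, probe, 1e-14)
        a = msep_poisson(ctx, tau).msep
        b = msep_generic(ctx, tau, total=total).msep
        assert a == pytest.approx(b, abs=1e-12)

    def test_unit_level_covariates_match_exhaustive_enumeration(self, rng):
        # n=8 Bernoullis with distinct covariates: sum over all 2^8
        # outcome vectors must equal the Poisson-binomial-total route
        n = 8
        beta = np.array([-0.8, 0.5])
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        lp = LinearPredictorSpec(beta, X, 0.6)
        ctx = PredictorContext(BINOM, lp, WeightSpec("AB", 1.2))
        tau = 1.0
        total = total_distribution(BINOM, lp)
        res = msep_generic(ctx, tau, total=total).msep

        rule = make_rule(tau, np.inf, 64)
        zt = predict(ctx, np.arange(n + 1))
        acc = 0.0
        p = expit(lp.eta(rule.nodes))            # (n, nodes)
        for bits in itertools.product([0, 1], repeat=n):
            bits = np.asarray(bits)
            pr = np.prod(np.where(bits[:, None], p, 1 - p), axis=0)
            acc += np.dot(rule.weights,
                          pr * (rule.nodes - zt[bits.sum()]) ** 2)
        brute = acc / norm.sf(tau)
        assert res == pytest.approx(brute, abs=1e-10)

    def test_lower_tail_by_sign_symmetry(self):
        # z -> -z, y -> n-y, mu -> -mu maps the lower tail onto the upper
        n, s, tau = 10, 0.7, 1.1
        for mu in (-1.0, 0.3):
            lo = msep_binary(PredictorContext.intercept_only(
                BINOM, mu, n, s, WeightSpec("SQ", 0.3)), -tau,
                tail="lower").msep
            hi = msep_binary(PredictorContext.intercept_only(
                BINOM, -mu, n, s, WeightSpec("SQ", 0.3)), tau).msep
            assert lo == pytest.approx(hi, abs=1e-10)

    def test_two_sided_combines_both_tails(self):
        ctx = PredictorContext.intercept_only(BINOM, 0.0, 10, 0.8)
        tau = 1.28
        two = msep_binary(ctx, tau, tail="two_sided").msep
        hi = msep_binary(ctx, tau).msep
        lo = msep_binary(ctx, -tau, tail="lower").msep
        assert two == pytest.approx(0.5 * (hi + lo), abs=1e-10)


class TestMonteCarloOracles:
    def test_binary_msep_matches_simulation(self, rng):
        from scipy.stats import truncnorm
        mu, n, s, tau = -2.0, 7, 0.8, 1.28
        ctx = PredictorContext.intercept_only(
            BINOM, mu, n, s, WeightSpec("AB", 1.6))
        exact = msep_binary(ctx, tau).msep
        N = 1_000_000
        z = truncnorm.rvs(tau, np.inf, size=N, random_state=rng)
        y = rng.binomial(n, expit(mu + s * z))
        zt = predict(ctx, np.arange(n + 1))
        err = (z - zt[y]) ** 2
        assert exact == pytest.approx(err.mean(),
                                      abs=3 * err.std() / np.sqrt(N))

    def test_poisson_msep_matches_simulation(self, rng):
        from scipy.stats import truncnorm
        mu, n, s, tau = -1.0, 5, 0.6, 1.28
        ctx = PredictorContext.intercept_only(
            POIS, mu, n, s, WeightSpec("SQ", 0.3))
        exact = msep_poisson(ctx, tau).msep
        N = 500_000
        z = truncnorm.rvs(tau, np.inf, size=N, random_state=rng)
        y = rng.poisson(n * np.exp(mu + s * z))
        uy, inv = np.unique(y, return_inverse=True)
        zt = np.atleast_1d(predict(ctx, uy.astype(float)))
        err = (z - zt[inv]) ** 2
        assert exact == pytest.approx(err.mean(),
                                      abs=3 * err.std() / np.sqrt(N))


class TestDifference:
    def test_zero_lambda_gives_zero_difference(self):
        lp = LinearPredictorSpec.intercept_only(-1.0, 10, 0.5)
        a = PredictorContext(BINOM, lp, WeightSpec("SQ", 0.0))
        b = PredictorContext(BINOM, lp, WeightSpec.bp())
        assert msep_difference(a, b, 1.28) == pytest.approx(0.0, abs=1e-14)

    def test_mismatched_scenarios_raise(self):
        a = PredictorContext.intercept_only(BINOM, -1.0, 10, 0.5,
                                            WeightSpec("AB", 1.2))
        b = PredictorContext.intercept_only(BINOM, -1.0, 12, 0.5)
        with pytest.raises(ValueError, match="identical"):
            msep_difference(a, b, 1.28)

    def test_sign_stable_under_quadrature_refinement(self):
        lp = LinearPredictorSpec.intercept_only(-2.0, 20, 0.5)
        w = PredictorContext(BINOM, lp, WeightSpec("AB", 1.6))
        b = PredictorContext(BINOM, lp, WeightSpec.bp())
        d64 = msep_difference(w, b, 1.28, n_nodes=64)
        d128 = msep_difference(w, b, 1.28, n_nodes=128)
        assert np.sign(d64) == np.sign(d128)
        assert d64 == pytest.approx(d128, abs=1e-6)
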