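"""Weighted prediction of the standardized random effect.

Given a cluster's outcome total Y., the posterior of the standardized
random effect z under a canonical-link GLMM has kernel

    f(z | Y) ∝ exp[ gamma {Y. sigma_u z - sum_j a(eta_j(z))} - z^2/2 ],

so any predictor built from the posterior depends on the data only
through Y..  The weighted predictor minimizing E[w(z) (ztilde - z)^2] is

    ztilde_w(Y.) = E[z w(z) | Y] / E[w(z) | Y],

with weight families

    BP : w(z) = 1            (the usual best predictor E[z | Y]),
    SQ : w(z) = exp(lambda z^2),
    AB : w(z) = exp(lambda |z|),

which up-weight extreme z and therefore shrink less than the best
predictor.  A Cauchy-Schwarz argument shows ztilde_w is non-decreasing
in Y. for every positive weight, so it can be inverted: ``invert`` finds
the largest total y with ztilde_w(y) < tau, the count threshold behind
all flagging rules.

Numerator and denominator are evaluated by quadrature entirely in log
space: exp(lambda z^2) at lambda = 0.4 and |z| = 8 overwhelms double
precision otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .families import (FamilySpec, LinearPredictorSpec, TotalDistribution,
                       total_distribution)
from .quadrature import QuadratureRule, make_composite_rule, make_rule

__all__ = ["WeightSpec", "PredictorContext", "WeightDivergenceError",
           "log_posterior_kernel", "predict", "invert",
           "UNREACHABLE", "BELOW_SUPPORT"]

#: Sentinel returned by ``invert`` when no total in the support reaches tau.
UNREACHABLE = math.inf
#: Offset below the support minimum returned when even the smallest total
#: already predicts above tau (every cluster flags).
BELOW_SUPPORT = -1


class WeightDivergenceError(ValueError):
    """The weighted posterior integral diverges for the requested weight."""


@dataclass(frozen=True)
class WeightSpec:
    """Weight family and tuning parameter lambda.

    lambda = 0 reduces SQ and AB to the unweighted best predictor.  For
    outcomes whose posterior has Gaussian tails (binary/binomial), the
    SQ integral only converges for lambda < 1/2.
    """

    kind: str                    # "BP" | "SQ" | "AB"
    lam: float = 0.0

    def __post_init__(self):
        if self.kind not in ("BP", "SQ", "AB"):
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")

    def log_w(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "BP" or self.lam == 0.0:
            return np.zeros_like(z)
        if self.kind == "SQ":
            return self.lam * z * z
        return self.lam * np.abs(z)

    @classmethod
    def bp(cls) -> "WeightSpec":
        return cls("BP", 0.0)


@dataclass
class PredictorContext:
    """Everything needed to evaluate ztilde_w: family, linear predictor,
    weight, and the quadrature rule for posterior integrals.

    The default rule integrates against phi over the effectively
    unbounded interval; the distribution of the cluster total (used by
    inversion and the flagging/MSEP integrals) is built lazily.
    """

    family: FamilySpec
    lp: LinearPredictorSpec
    weight: WeightSpec = field(default_factory=WeightSpec.bp)
    rule: QuadratureRule | None = None
    _total: TotalDistribution | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.rule is None:
            self.rule = make_composite_rule(-math.inf, math.inf, 25)

    @classmethod
    def intercept_only(cls, family: FamilySpec, mu: float, n: int,
                       sigma_u: float, weight: WeightSpec | None = None,
                       rule: QuadratureRule | None = None
                       ) -> "PredictorContext":
        lp = LinearPredictorSpec.intercept_only(mu, n, sigma_u)
        return cls(family, lp, weight or WeightSpec.bp(), rule)

    def with_weight(self, weight: WeightSpec) -> "PredictorContext":
        ctx = PredictorContext(self.family, self.lp, weight, self.rule)
        ctx._total = self._total
        return ctx

    def total(self, rule: QuadratureRule | None = None) -> TotalDistribution:
        """Distribution of Y. | z (cached; ``rule`` sets the Poisson
        truncation when the total has unbounded support)."""
        if self._total is None:
            self._total = total_distribution(
                self.family, self.lp, rule if rule is not None else self.rule)
        return self._total


def _sum_cumulant(ctx: PredictorContext, z: np.ndarray) -> np.ndarray:
    """sum_j a(eta_j(z)) at each z, exploiting cluster-constant covariates."""
    lp = ctx.lp
    if lp.cluster_constant:
        return lp.n * ctx.family.cumulant(
            lp.fixed_part[0] + lp.sigma_u * z)
    return ctx.family.cumulant(lp.eta(z)).sum(axis=0)


def log_posterior_kernel(ctx: PredictorContext, y_total, z) -> np.ndarray:
    """Log posterior kernel of z given the cluster total, up to a
    constant free of z:

        gamma {Y. sigma_u z - sum_j a(eta_j(z))} - z^2/2.

    Broadcasts to shape (len(y_total), len(z)).
    """
    y = np.atleast_1d(np.asarray(y_total, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    gamma = ctx.family.scale
    loglik = gamma * (np.outer(y, ctx.lp.sigma_u * z)
                      - _sum_cumulant(ctx, z)[None, :])
    return loglik - 0.5 * z * z


def _log_conditional_lik(ctx: PredictorContext, y: np.ndarray,
                         z: np.ndarray) -> np.ndarray:
    """gamma {Y. sigma_u z - sum_j a(eta_j(z))}; the z^2/2 prior term is
    carried by the quadrature weights."""
    gamma = ctx.family.scale
    return gamma * (np.outer(y, ctx.lp.sigma_u * z)
                    - _sum_cumulant(ctx, z)[None, :])


def predict(ctx: PredictorContext, y_total) -> np.ndarray | float:
    """Weighted predictor ztilde_w evaluated at cluster total(s).

    Accepts a scalar or an array of totals and evaluates the ratio of
    posterior integrals by log-space quadrature, vectorized over totals.

    Raises
    ------
    WeightDivergenceError
        If the weighted posterior integral diverges (SQ with lambda >=
        1/2 against a Gaussian-tailed posterior, or any weight whose
        integrand is still growing at the integration boundary).
    """
    scalar = np.isscalar(y_total) or np.ndim(y_total) == 0
    y = np.atleast_1d(np.asarray(y_total, dtype=float))
    w, rule = ctx.weight, ctx.rule

    # keep the (totals x nodes) work arrays modest for huge Poisson supports
    max_rows = max(1, 4_000_000 // rule.n_nodes)
    if y.size > max_rows:
        parts = [predict(ctx, y[i:i + max_rows])
                 for i in range(0, y.size, max_rows)]
        return np.concatenate([np.atleast_1d(p) for p in parts])

    if (w.kind == "SQ" and w.lam >= 0.5
            and ctx.family.name in ("bernoulli_logit", "binomial_logit",
                                    "gaussian_identity")):
        raise WeightDivergenceError(
            f"SQ weight with lambda={w.lam} >= 1/2 diverges against the "
            f"Gaussian-tailed posterior of family {ctx.family.name!r}")

    z = rule.nodes
    logpost = _log_conditional_lik(ctx, y, z) + w.log_w(z)[None, :]
    logterms = rule.log_weights[None, :] + logpost

    if w.kind == "SQ" and w.lam > 0.0:
        # a boundary-dominated integrand means the weighted integral is
        # still growing at the clipped endpoint, i.e. divergent; only the
        # SQ weight can outgrow the posterior kernels handled here
        peak = np.argmax(logterms, axis=1)
        if np.any((peak == 0) | (peak == z.size - 1)):
            raise WeightDivergenceError(
                f"weighted posterior integrand peaks at the integration "
                f"boundary for weight SQ lambda={w.lam}; the integral "
                f"diverges for this posterior tail")

    log_den = logsumexp(logterms, axis=1)
    with np.errstate(divide="ignore"):
        log_num, sign = logsumexp(logterms + np.log(np.abs(z))[None, :],
                                  b=np.sign(z)[None, :], axis=1,
                                  return_sign=True)
    out = sign * np.exp(log_num - log_den)
    if not np.all(np.isfinite(out)):
        raise WeightDivergenceError(
            f"non-finite weighted predictor for weight {w.kind} "
            f"lambda={w.lam}")
    return float(out[0]) if scalar else out


def _check_monotone(zt: np.ndarray) -> None:
    d = np.diff(zt)
    if d.size and d.min() < -1e-8:
        i = int(np.argmin(d))
        raise RuntimeError(
            "weighted predictor not non-decreasing in the cluster total "
            f"(drop {d.min():.3e} at total index {i}); this contradicts "
            "the Cauchy-Schwarz monotonicity of ztilde_w and indicates a "
            "quadrature failure")


def invert(ctx: PredictorContext, tau: float) -> float:
    """Count threshold y_{.,tau}: the largest total with ztilde_w < tau.

    Flagging "ztilde_w > tau" is then equivalent to "Y. > y_{.,tau}".
    For discrete totals this is the exhaustive search for the total y
    with ztilde_w(y) < tau <= ztilde_w(y+1); for continuous totals
    (Gaussian) a bracketed bisection solves ztilde_w(y) = tau.

    Returns ``min(support) + BELOW_SUPPORT`` when even the smallest
    total predicts >= tau (everything flags) and the ``UNREACHABLE``
    sentinel (+inf) when no total in the (possibly truncated) support
    reaches tau.
    """
    if ctx.lp.sigma_u <= 0:
        raise ValueError("inversion requires sigma_u > 0; ztilde is "
                         "constant in Y. otherwise")
    total = ctx.total()
    if not total.continuous:
        # exhaustive upward scan, chunked so Poisson supports with large
        # truncation bounds are only evaluated up to the crossing
        support = total.support
        prev = -math.inf
        for start in range(0, support.size, 1024):
            block = support[start:start + 1024]
            zt = np.atleast_1d(predict(ctx, block))
            _check_monotone(np.concatenate(([prev], zt)) if start else zt)
            prev = zt[-1]
            above = np.flatnonzero(zt >= tau)
            if above.size:
                i = start + int(above[0])
                if i == 0:
                    return float(support[0] + BELOW_SUPPORT)
                return float(support[i - 1])
        return UNREACHABLE

    # continuous branch: geometric bracket expansion then bisection
    y0 = float(ctx.lp.fixed_part.sum())
    scale = max(1.0, abs(y0)) * ctx.lp.n
    lo = hi = y0
    step = scale
    while predict(ctx, hi) < tau:
        hi += step
        step *= 2
        if step > 1e12 * scale:
            return UNREACHABLE
    step = scale
    while predict(ctx, lo) >= tau:
        lo -= step
        step *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if predict(ctx, mid) < tau:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, abs(mid)):
            break
    return 0.5 * (lo + hi)
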