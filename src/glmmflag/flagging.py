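"""Exact flagging probabilities and self-calibration of the weight.

A cluster is flagged as extreme when its weighted prediction exceeds the
threshold: ztilde_w > tau.  Because ztilde_w is non-decreasing in the
cluster total Y., the rule is equivalent to Y. > y_{.,tau} with
y_{.,tau} the count threshold from the monotone inversion, and the
operating characteristics are exact integrals:

    incorrect rate = Pr{ztilde > tau | z < tau}
                   = 1 - int_{-inf}^{tau} F(y_{.,tau} | z) phi(z) dz / Phi(tau)
    correct rate   = Pr{ztilde > tau | z > tau}
                   = 1 - int_{tau}^{inf} F(y_{.,tau} | z) phi(z) dz / (1-Phi(tau)),

(1 - specificity and sensitivity, respectively), with F the cdf of the
total given z.  A weight is *self-calibrated* at level alpha when its
incorrect rate is at most alpha; calibration tunes lambda so the count
threshold lands on y_alpha, the upper alpha-quantile of Y. given
z < tau.  When the discreteness of Y. prevents an exact landing, the
closest achievable threshold with rate <= alpha is returned instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .families import FamilySpec, LinearPredictorSpec, TotalDistribution
from .predictors import (BELOW_SUPPORT, UNREACHABLE, PredictorContext,
                         WeightDivergenceError, WeightSpec, invert, predict)
from .quadrature import QuadratureRule, make_rule

__all__ = ["FlagRates", "CalibrationResult", "incorrect_rate",
           "correct_rate", "flag_rates", "y_alpha_quantile", "calibrate",
           "flag"]

DEFAULT_TAIL_NODES = 64

#: Default bisection brackets for the calibration search.  The SQ weight
#: diverges at lambda = 1/2 against Gaussian-tailed posteriors, so its
#: bracket stays strictly below; the AB weight is always admissible.
DEFAULT_BRACKETS = {"SQ": (0.0, 0.499), "AB": (0.0, 8.0)}


@dataclass(frozen=True)
class FlagRates:
    """Exact operating characteristics of a count-threshold rule."""

    incorrect: float             # Pr{flag | z < tau}, 1 - specificity
    correct: float               # Pr{flag | z > tau}, sensitivity
    threshold_y: float           # flag iff Y. > threshold_y


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of self-calibrating a weight family at level alpha.

    ``feasible`` is False when even the best predictor's rule exceeds
    alpha (possible under highly discrete totals), in which case no
    self-calibrated member of the family exists and the reported rates
    are the best predictor's.  ``exact_boundary`` records whether the
    calibrated count threshold landed exactly on y_alpha (when it does
    for two weight families, their flagged sets coincide).
    """

    kind: str
    lambda_star: float | None
    y_alpha: float
    threshold_y: float
    achieved_incorrect: float
    achieved_correct: float
    feasible: bool
    exact_boundary: bool


def _exceed_prob(total: TotalDistribution, y: float, rule: QuadratureRule,
                 mass: float) -> float:
    """Pr{Y. > y | z in rule's interval} = 1 - int F(y|z) phi(z) dz / mass."""
    if y == UNREACHABLE:
        return 0.0
    F = np.asarray(total.cdf(y, rule.nodes), dtype=float)
    return float(1.0 - np.dot(rule.weights, np.atleast_1d(F)) / mass)


def _ctx_total(ctx: PredictorContext, tau: float,
               n_nodes: int) -> TotalDistribution:
    # the total's Poisson truncation only matters for inversion; the
    # cdf used by the rate integrals needs no support enumeration
    return ctx.total(make_rule(-math.inf, math.inf, n_nodes))


def flag_rates(ctx: PredictorContext, tau: float,
               threshold_y: float | None = None,
               n_nodes: int = DEFAULT_TAIL_NODES) -> FlagRates:
    """Both exact rates of the rule "flag iff Y. > y_{.,tau}".

    ``threshold_y`` defaults to the monotone inversion of the context's
    weighted predictor at tau.
    """
    if threshold_y is None:
        threshold_y = invert(ctx, tau)
    total = _ctx_total(ctx, tau, n_nodes)
    lo = make_rule(-math.inf, tau, n_nodes)
    hi = make_rule(tau, math.inf, n_nodes)
    return FlagRates(
        incorrect=_exceed_prob(total, threshold_y, lo, float(norm.cdf(tau))),
        correct=_exceed_prob(total, threshold_y, hi, float(norm.sf(tau))),
        threshold_y=threshold_y)


def incorrect_rate(ctx: PredictorContext, tau: float,
                   n_nodes: int = DEFAULT_TAIL_NODES) -> float:
    """Pr{ztilde_w > tau | z < tau}; returns 0 exactly when no total in
    the support reaches tau."""
    return flag_rates(ctx, tau, n_nodes=n_nodes).incorrect


def correct_rate(ctx: PredictorContext, tau: float,
                 n_nodes: int = DEFAULT_TAIL_NODES) -> float:
    """Pr{ztilde_w > tau | z > tau} (sensitivity)."""
    return flag_rates(ctx, tau, n_nodes=n_nodes).correct


def y_alpha_quantile(family: FamilySpec, lp: LinearPredictorSpec,
                     tau: float, alpha: float,
                     n_nodes: int = DEFAULT_TAIL_NODES) -> float:
    """Smallest y with Pr{Y. > y | z < tau} <= alpha.

    The conditional distribution of the total given a non-extreme random
    effect is the quadrature mixture of F(. | z) over z < tau.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if lp.sigma_u <= 0:
        raise ValueError("y_alpha requires sigma_u > 0")
    ctx = PredictorContext(family, lp)
    total = _ctx_total(ctx, tau, n_nodes)
    lo = make_rule(-math.inf, tau, n_nodes)
    mass = float(norm.cdf(tau))

    def tail(y):
        return _exceed_prob(total, y, lo, mass)

    if total.continuous:
        from scipy.optimize import brentq
        center = float(lp.fixed_part.sum())
        span = max(1.0, abs(center)) * lp.n
        a, b = center - span, center + span
        while tail(a) < alpha:
            a -= span
        while tail(b) > alpha:
            b += span
        return float(brentq(lambda y: tail(y) - alpha, a, b, xtol=1e-10))

    # exponential search then bisection on the non-increasing tail
    y0 = int(total.support[0])
    if tail(y0) <= alpha:
        return float(y0)
    step = 1
    lo_y, hi_y = y0, y0 + step
    while tail(hi_y) > alpha:
        lo_y, step = hi_y, step * 2
        hi_y = lo_y + step
    while hi_y - lo_y > 1:
        mid = (lo_y + hi_y) // 2
        if tail(mid) > alpha:
            lo_y = mid
        else:
            hi_y = mid
    return float(hi_y)


def flag(ctx: PredictorContext, tau: float, y_total) -> np.ndarray | bool:
    """Flag decision ztilde_w(Y.) > tau (strict).

    By monotonicity this agrees with the count comparison
    Y. > y_{.,tau} everywhere except exact ties ztilde_w = tau.
    """
    zt = predict(ctx, y_total)
    return zt > tau


def calibrate(family: FamilySpec, lp: LinearPredictorSpec, weight_kind: str,
              tau: float, alpha: float,
              lambda_bracket: tuple[float, float] | None = None,
              rule: QuadratureRule | None = None,
              n_nodes: int = DEFAULT_TAIL_NODES) -> CalibrationResult:
    """Self-calibrate a weight family: find lambda* whose flagging rule
    has incorrect rate <= alpha, as close to alpha as achievable.

    The search solves ztilde_lambda(y_alpha) = tau by bisection on
    lambda (the count threshold is non-increasing in lambda since larger
    lambda shrinks less).  Outcomes:

    * the best predictor (lambda = 0) already exceeds alpha ->
      ``feasible=False`` (no self-calibrated member exists);
    * the root lands the threshold exactly on y_alpha ->
      ``exact_boundary=True``;
    * the bracket cannot reach y_alpha (discreteness, or the SQ
      admissibility bound) -> the lambda attaining the closest
      achievable threshold with rate <= alpha, ``exact_boundary=False``.
    """
    if weight_kind not in ("SQ", "AB"):
        raise ValueError("calibration applies to the SQ and AB weight "
                         f"families, not {weight_kind!r}")
    if lambda_bracket is None:
        lambda_bracket = DEFAULT_BRACKETS[weight_kind]
    lo, hi = lambda_bracket
    if not 0.0 <= lo < hi:
        raise ValueError(f"invalid lambda bracket {lambda_bracket}")

    ctx_bp = PredictorContext(family, lp, WeightSpec.bp(), rule)
    bp = flag_rates(ctx_bp, tau, n_nodes=n_nodes)
    y_alpha = y_alpha_quantile(family, lp, tau, alpha, n_nodes=n_nodes)

    # Self-calibration is infeasible when the discreteness of Y. leaves no
    # rule to calibrate: either the α-quantile sits at the top of a bounded
    # support (even "flag only the maximal total" exceeds α, so the only
    # conforming rule flags nothing), or the best predictor's own rule —
    # the most shrunk, hence most conservative, member of the family —
    # already exceeds α.
    total = ctx_bp.total()
    degenerate = (not total.continuous and total.truncation_tolerance == 0.0
                  and y_alpha >= total.support[-1])
    if degenerate or bp.incorrect > alpha:
        return CalibrationResult(weight_kind, None, y_alpha, bp.threshold_y,
                                 bp.incorrect, bp.correct,
                                 feasible=False, exact_boundary=False)

    def ctx_at(lam):
        return PredictorContext(family, lp, WeightSpec(weight_kind, lam),
                                rule)

    def g(lam):
        """ztilde_lambda(y_alpha) - tau; increasing in lambda."""
        return predict(ctx_at(lam), y_alpha) - tau

    g_lo = g(lo)
    if g_lo > 0:
        # only possible if the caller's bracket starts above the root
        raise ValueError(
            f"lambda bracket lower end {lo} already predicts above tau")
    try:
        g_hi = g(hi)
    except WeightDivergenceError:
        g_hi = math.inf

    if g_hi < 0:
        # even the largest admissible lambda keeps y_alpha below tau:
        # fall back to the closest achievable threshold (still <= alpha)
        lam = hi
    else:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            try:
                gm = g(mid)
            except WeightDivergenceError:
                gm = math.inf
            if gm <= 0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-11 * max(1.0, hi):
                break
        lam = lo

    ctx = ctx_at(lam)
    threshold = invert(ctx, tau)
    rates = flag_rates(ctx, tau, threshold_y=threshold, n_nodes=n_nodes)
    return CalibrationResult(weight_kind, lam, y_alpha, threshold,
                             rates.incorrect, rates.correct,
                             feasible=True,
                             exact_boundary=bool(threshold == y_alpha))
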