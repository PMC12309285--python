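"""Gaussian quadrature against the standard normal density.

All posterior moments, mean-square-error integrals and flagging
probabilities in this package are integrals of the form

    I = int_a^b f(z) phi(z) dz,

where phi is the standard normal density and (a, b) may be the whole
line, a half line (tail integrals) or a bounded interval.  Two rules are
provided:

* both bounds infinite -> classical Gauss-Hermite with the change of
  variable z = sqrt(2) t, which is exact for polynomials f of degree
  <= 2 n - 1;
* any finite bound -> Gauss-Legendre on the (clipped) interval with
  phi folded into the weights, the standard realisation of bounded
  Gauss-Hermite quadrature.  Effectively-infinite endpoints are clipped
  at +/- 8, beyond which the standard normal mass is below 1e-15.

Accuracy is not asserted a priori: the test suite checks that doubling
the node count leaves downstream quantities unchanged to well below the
reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = ["QuadratureRule", "make_rule", "make_composite_rule",
           "integrate", "integrate_signed"]

#: Standard-normal mass beyond +/- EFFECTIVE_INFINITY is < 1e-15.
EFFECTIVE_INFINITY = 8.0

DEFAULT_NODES_BOUNDED = 64
DEFAULT_NODES_UNBOUNDED = 50


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes and positive weights approximating ``int_lower^upper f(z) phi(z) dz``.

    ``sum(weights * f(nodes))`` approximates the integral; in particular
    ``sum(weights)`` reproduces ``Phi(upper) - Phi(lower)``.
    """

    nodes: np.ndarray
    weights: np.ndarray
    lower: float
    upper: float

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(self.weights)


@lru_cache(maxsize=512)
def make_rule(lower: float = -np.inf, upper: float = np.inf,
              n_nodes: int | None = None) -> QuadratureRule:
    """Build a rule for integrating ``f(z) phi(z)`` over ``(lower, upper)``.

    Parameters
    ----------
    lower, upper
        Integration bounds; either may be infinite.
    n_nodes
        Number of nodes.  Defaults to 50 (fully unbounded) or 64
        (any finite bound).

    Raises
    ------
    ValueError
        If ``lower >= upper`` or ``n_nodes < 2``.
    """
    if not lower < upper:
        raise ValueError(f"require lower < upper, got [{lower}, {upper}]")

    if np.isinf(lower) and np.isinf(upper):
        n = DEFAULT_NODES_UNBOUNDED if n_nodes is None else int(n_nodes)
        if n < 2:
            raise ValueError("n_nodes must be >= 2")
        t, w = np.polynomial.hermite.hermgauss(n)
        # int f(z) phi(z) dz = (1/sqrt(pi)) int f(sqrt(2) t) e^{-t^2} dt
        return QuadratureRule(np.sqrt(2.0) * t, w / np.sqrt(np.pi),
                              -np.inf, np.inf)

    n = DEFAULT_NODES_BOUNDED if n_nodes is None else int(n_nodes)
    if n < 2:
        raise ValueError("n_nodes must be >= 2")
    a = max(lower, -EFFECTIVE_INFINITY)
    b = min(upper, EFFECTIVE_INFINITY)
    t, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (b - a)
    nodes = a + half * (t + 1.0)
    weights = half * w * norm.pdf(nodes)
    return QuadratureRule(nodes, weights, float(lower), float(upper))


@lru_cache(maxsize=512)
def make_composite_rule(lower: float = -np.inf, upper: float = np.inf,
                        nodes_per_panel: int = 25,
                        panel_width: float = 1.0) -> QuadratureRule:
    """Panelized Gauss-Legendre rule against phi on a (clipped) interval.

    The interval is cut at integer multiples of ``panel_width`` (so a
    panel edge falls on z = 0, where the absolute weight exp(lambda |z|)
    has a kink) and each panel carries its own Gauss-Legendre nodes.
    Short panels keep the rule accurate for sharply peaked posterior
    integrands — with n ~ 100 observations the posterior of z has
    standard deviation well under 0.2, which a single global rule
    resolves poorly — wherever the peak lies.
    """
    a = max(lower, -EFFECTIVE_INFINITY)
    b = min(upper, EFFECTIVE_INFINITY)
    if not a < b:
        raise ValueError(f"require lower < upper, got [{lower}, {upper}]")
    if nodes_per_panel < 2:
        raise ValueError("nodes_per_panel must be >= 2")
    edges = panel_width * np.arange(np.ceil(a / panel_width),
                                    np.floor(b / panel_width) + 0.5)
    cuts = np.concatenate(([a], edges[(edges > a) & (edges < b)], [b]))
    t, w = np.polynomial.legendre.leggauss(int(nodes_per_panel))
    nodes, weights = [], []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        half = 0.5 * (hi - lo)
        x = lo + half * (t + 1.0)
        nodes.append(x)
        weights.append(half * w * norm.pdf(x))
    return QuadratureRule(np.concatenate(nodes), np.concatenate(weights),
                          float(lower), float(upper))


def integrate(rule: QuadratureRule, f, log_space: bool = False) -> float:
    """Apply the rule to ``f``.

    With ``log_space=True``, ``f`` must return log-values at the nodes and
    the log of the integral is returned, accumulated with log-sum-exp.

    Raises
    ------
    FloatingPointError
        If ``f`` evaluates to NaN at any node (the offending node index
        is named in the message).  ``-inf`` log-values are legal.
    """
    vals = np.asarray(f(rule.nodes), dtype=float)
    bad = np.flatnonzero(np.isnan(vals))
    if bad.size:
        raise FloatingPointError(
            f"integrand returned NaN at node index {bad[0]} "
            f"(z={rule.nodes[bad[0]]:.6g})")
    if log_space:
        return float(logsumexp(rule.log_weights + vals))
    if not np.all(np.isfinite(vals)):
        bad = np.flatnonzero(~np.isfinite(vals))
        raise FloatingPointError(
            f"integrand not finite at node index {bad[0]} "
            f"(z={rule.nodes[bad[0]]:.6g})")
    return float(np.dot(rule.weights, vals))


def integrate_signed(rule: QuadratureRule, log_abs_f: np.ndarray,
                     sign_f: np.ndarray) -> tuple[float, float]:
    """Log-space accumulation of a signed integrand.

    Parameters are the log of |f| and the sign of f evaluated at the
    nodes.  Returns ``(log |I|, sign(I))``.
    """
    log_abs, sign = logsumexp(rule.log_weights + log_abs_f,
                              b=sign_f, return_sign=True)
    return float(log_abs), float(sign)
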