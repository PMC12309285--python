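"""Canonical-link GLMM families and the distribution of the cluster total.

A canonical-link generalized linear mixed model has unit-level density

    f(y | z, x) = exp[ {y eta - a(eta)} gamma + b(y, gamma) ],
    eta = sigma_u z + beta' x,     z ~ N(0, 1),

with cumulant function ``a``, scale ``gamma`` (1 for Bernoulli and
Poisson) and inverse link g^{-1} = a'.  Because the posterior of z given
a cluster's outcomes depends on the data only through the cluster total
Y. = sum_j y_j, everything downstream (predictors, MSEP, flagging) needs
the distribution of Y. given z, which this module provides in closed
form:

* logistic with cluster-constant covariates -> binomial;
* logistic with unit-level covariates       -> Poisson-binomial;
* log-link Poisson                          -> Poisson with mean
  nu. = sum_j exp(beta' x_j + sigma_u z);
* identity-link Gaussian                    -> normal.

All pmf arithmetic is done in log space; binomial coefficients come from
log-gamma, so pmfs stay exact to ~1e-12 at cluster sizes of a few
hundred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm, poisson

__all__ = [
    "FamilySpec", "LinearPredictorSpec", "TotalDistribution",
    "bernoulli_logit", "binomial_logit", "poisson_log", "gaussian_identity",
    "get_family", "binomial_total_pmf", "poisson_binomial_pmf",
    "poisson_total_mean", "total_distribution",
]


@dataclass(frozen=True)
class FamilySpec:
    """A canonical-link exponential-family response distribution.

    ``cumulant`` is a(eta); ``inverse_link`` is g^{-1} = a' for the
    canonical link; ``scale`` is the positive factor gamma multiplying
    {y eta - a(eta)} in the log density (1 for Bernoulli/Poisson, the
    error precision for the Gaussian).
    """

    name: str
    cumulant: Callable[[np.ndarray], np.ndarray]
    inverse_link: Callable[[np.ndarray], np.ndarray]
    scale: float = 1.0
    support: str = "discrete"

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale gamma must be positive")


def _logistic_cumulant(eta):
    # log(1 + e^eta), overflow-safe
    return np.logaddexp(0.0, eta)


bernoulli_logit = FamilySpec("bernoulli_logit", _logistic_cumulant, expit)
binomial_logit = FamilySpec("binomial_logit", _logistic_cumulant, expit)
poisson_log = FamilySpec("poisson_log", np.exp, np.exp)
gaussian_identity = FamilySpec(
    "gaussian_identity", lambda eta: 0.5 * np.square(eta), lambda eta: eta,
    support="continuous")

_REGISTRY = {f.name: f for f in
             (bernoulli_logit, binomial_logit, poisson_log, gaussian_identity)}


def get_family(name: str, scale: float = 1.0) -> FamilySpec:
    """Look a family up by name, optionally overriding the scale gamma."""
    try:
        fam = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(_REGISTRY)}")
    if scale != fam.scale:
        fam = FamilySpec(fam.name, fam.cumulant, fam.inverse_link,
                         scale, fam.support)
    return fam


@dataclass(frozen=True)
class LinearPredictorSpec:
    """Cluster-level linear predictor eta_j(z) = sigma_u z + beta' x_j.

    ``X`` has one row per unit in the cluster (n x p); the intercept-only
    case mu = beta'x is expressed with a single constant column.  For
    cluster-constant covariates every row of ``X`` is identical and the
    cluster total is sufficient.
    """

    beta: np.ndarray
    X: np.ndarray
    sigma_u: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(
            np.asarray(self.beta, dtype=float)))
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        object.__setattr__(self, "X", X)
        if self.X.shape[1] != self.beta.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but beta has "
                f"{self.beta.shape[0]} entries")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")

    @classmethod
    def intercept_only(cls, mu: float, n: int,
                       sigma_u: float) -> "LinearPredictorSpec":
        """n identical units with fixed part mu (the grid scenarios)."""
        return cls(np.array([mu]), np.ones((n, 1)), sigma_u)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def fixed_part(self) -> np.ndarray:
        """beta'x_j per unit, shape (n,)."""
        return self.X @ self.beta

    def eta(self, z):
        """Linear predictor matrix, shape (n,) + shape(z)."""
        z = np.asarray(z, dtype=float)
        return self.sigma_u * z + self.fixed_part.reshape(
            (-1,) + (1,) * z.ndim)

    @property
    def cluster_constant(self) -> bool:
        fp = self.fixed_part
        return bool(np.all(fp == fp[0]))


@dataclass(frozen=True)
class TotalDistribution:
    """Distribution of the cluster total Y. conditional on z.

    For discrete families, ``support`` enumerates the (possibly
    truncated) outcome totals and ``logpmf(y, z)`` / ``cdf(y, z)``
    broadcast over both arguments.  For the Gaussian family the support
    is the real line and ``logpdf`` replaces ``logpmf``.
    """

    family: str
    support: np.ndarray          # discrete grid, or empty for continuous
    logpmf: Callable             # logpmf(y, z) (logpdf for continuous)
    cdf: Callable                # cdf(y, z)
    truncation_tolerance: float = 0.0
    continuous: bool = False
    sample: Callable | None = field(default=None, compare=False)


# ---------------------------------------------------------------------------
# closed-form totals

def binomial_log_pmf(k, n: int, mu: float, sigma_u: float, z):
    """log C(n,k) + k(mu + sigma_u z) - n log(1 + e^{mu + sigma_u z})."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError(f"count outside [0, {n}]")
    eta = mu + sigma_u * np.asarray(z, dtype=float)
    logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return logc + k * eta - n * np.logaddexp(0.0, eta)


def binomial_total_pmf(k, n: int, mu: float, sigma_u: float, z) -> np.ndarray:
    """Binomial pmf of the cluster total for the logistic model with
    cluster-constant covariates: success probability expit(mu + sigma_u z)."""
    return np.exp(binomial_log_pmf(k, n, mu, sigma_u, z))


def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact pmf over 0..n of a sum of independent Bernoulli(p_j).

    Computed by the O(n^2) dynamic-programming convolution, which is
    bit-stable at desk-scale n (the characteristic-function formula of
    Hong (2013) is the usual alternative for very large n).
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("probs must be non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for j, pj in enumerate(p):
        pmf[1:j + 2] = pmf[1:j + 2] * (1 - pj) + pmf[:j + 1] * pj
        pmf[0] *= 1 - pj
    return pmf


def poisson_total_mean(X, beta, sigma_u: float, z) -> np.ndarray:
    """nu. = sum_j exp(beta' x_j + sigma_u z) for the log-link Poisson."""
    lp = LinearPredictorSpec(beta, X, sigma_u)
    return np.exp(lp.eta(z)).sum(axis=0)


def poisson_support_bound(lp: LinearPredictorSpec, rule,
                          tol: float = 1e-12, cap: int = 2_000_000) -> int:
    """Truncation point K for the unbounded Poisson total.

    K is chosen so that the quadrature-weighted upper-tail mass
    sum_i w_i Pr{Y. > K | z_i} is below ``tol``: per node the tail is
    capped at tol / (n_nodes * w_i), so nodes carrying negligible
    normal mass do not inflate K.
    """
    nus = np.exp(lp.eta(rule.nodes)).sum(axis=0)
    eps = np.clip(tol / (rule.n_nodes * np.maximum(rule.weights, 1e-300)),
                  0.0, 1.0)
    ks = poisson.isf(eps, nus)
    K = int(np.nanmax(np.where(np.isfinite(ks), ks, 0.0))) + 1
    if K > cap:
        raise RuntimeError(
            f"Poisson truncation bound {K} exceeds cap {cap}; "
            f"requested tail tolerance {tol} not attainable")
    return K


def total_distribution(family: FamilySpec, lp: LinearPredictorSpec,
                       rule=None, truncation_tolerance: float = 1e-12
                       ) -> TotalDistribution:
    """Dispatch to the closed-form distribution of the cluster total.

    ``rule`` (a QuadratureRule) is required for the Poisson family: its
    nodes and weights determine where the infinite support can be
    truncated with quadrature-weighted tail mass below
    ``truncation_tolerance``.
    """
    name = family.name
    n = lp.n
    if name in ("bernoulli_logit", "binomial_logit"):
        if lp.cluster_constant:
            mu = float(lp.fixed_part[0])
            s = lp.sigma_u

            def logpmf(y, z, mu=mu, s=s, n=n):
                return binomial_log_pmf(y, n, mu, s, z)

            def cdf(y, z, mu=mu, s=s, n=n):
                from scipy.stats import binom
                return binom.cdf(y, n, expit(mu + s * np.asarray(z)))

            def sample(z, rng, mu=mu, s=s, n=n):
                return rng.binomial(n, expit(mu + s * np.asarray(z)))

            return TotalDistribution(name, np.arange(n + 1), logpmf, cdf,
                                     sample=sample)

        # unit-level covariates: Poisson-binomial total.  y and z may be
        # arbitrary broadcastable shapes; the pmf is rebuilt per unique z.
        def _table(z, lp=lp):
            zs = np.unique(np.asarray(z, dtype=float).ravel())
            return {zi: poisson_binomial_pmf(expit(lp.eta(zi)))
                    for zi in zs}

        def logpmf(y, z, lp=lp):
            y = np.asarray(y, dtype=int)
            zarr = np.asarray(z, dtype=float)
            tables = _table(zarr)
            yb, zb = np.broadcast_arrays(y, zarr)
            out = np.empty(yb.shape)
            for idx in np.ndindex(yb.shape):
                out[idx] = tables[zb[idx]][yb[idx]]
            with np.errstate(divide="ignore"):
                return np.log(out) if out.ndim else float(np.log(out))

        def cdf(y, z, lp=lp):
            y = np.asarray(y)
            zarr = np.asarray(z, dtype=float)
            tables = {k: np.cumsum(v) for k, v in _table(zarr).items()}
            yb, zb = np.broadcast_arrays(y, zarr)
            out = np.empty(yb.shape)
            for idx in np.ndindex(yb.shape):
                yi = int(np.floor(yb[idx]))
                out[idx] = (0.0 if yi < 0
                            else tables[zb[idx]][min(yi, lp.n)])
            return out

        def sample(z, rng, lp=lp):
            z = np.asarray(z, dtype=float)
            p = expit(lp.eta(z))           # (n, len(z))
            return rng.binomial(1, p).sum(axis=0)

        return TotalDistribution(name, np.arange(n + 1), logpmf, cdf,
                                 sample=sample)

    if name == "poisson_log":
        if rule is None:
            raise ValueError("a quadrature rule is required to truncate "
                             "the Poisson total's support")
        K = poisson_support_bound(lp, rule, truncation_tolerance)

        def nu(z, lp=lp):
            return np.exp(lp.eta(z)).sum(axis=0)

        def logpmf(y, z, nu=nu):
            return poisson.logpmf(np.asarray(y), nu(np.asarray(z)))

        def cdf(y, z, nu=nu):
            return poisson.cdf(np.asarray(y), nu(np.asarray(z)))

        def sample(z, rng, nu=nu):
            return rng.poisson(nu(np.asarray(z)))

        return TotalDistribution(name, np.arange(K + 1), logpmf, cdf,
                                 truncation_tolerance=truncation_tolerance,
                                 sample=sample)

    if name == "gaussian_identity":
        gamma = family.scale
        mean0 = float(lp.fixed_part.sum())
        s = lp.sigma_u

        def logpdf(y, z, mean0=mean0, s=s, n=n, gamma=gamma):
            m = mean0 + n * s * np.asarray(z)
            return norm.logpdf(np.asarray(y), m, np.sqrt(n / gamma))

        def cdf(y, z, mean0=mean0, s=s, n=n, gamma=gamma):
            m = mean0 + n * s * np.asarray(z)
            return norm.cdf(np.asarray(y), m, np.sqrt(n / gamma))

        def sample(z, rng, mean0=mean0, s=s, n=n, gamma=gamma):
            z = np.asarray(z, dtype=float)
            m = mean0 + n * s * z
            return m + rng.normal(0.0, np.sqrt(n / gamma), size=z.shape)

        return TotalDistribution(name, np.array([]), logpdf, cdf,
                                 continuous=True, sample=sample)

    raise NotImplementedError(
        f"cluster-total distribution not implemented for family {name!r}")
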