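"""Synthetic clustered data and the train/validate example workflow.

The generator samples the canonical-link GLMM directly: z_i ~ N(0,1)
per cluster, eta_ij = sigma_u z_i + beta' x_ij, outcomes from the
response family.  An "asthma-like" preset emulates a study of
asthma-related emergency-department revisits clustered by zip code:
248 clusters of at least 100 children each (mean ~180, about 45,000
units in total), a binary revisit outcome with baseline revisit
probability around 0.25, and two standardized cluster-level covariates
standing in for a pollution score and average income.

The example workflow mirrors a profiling analysis with no external
data: units are split in half within each cluster, a mixed-effects
logistic model is fitted to the training half by maximum likelihood
(Gauss-Hermite marginal likelihood), weighted predictors and
self-calibrated flags are computed from training totals, and the
validation half supplies surrogate "true" effects

    zhat_valid = [logit(phat_valid) - etahat] / sigmahat

against which subgroup MSEPs and flagging agreement are judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp

from .families import FamilySpec, LinearPredictorSpec, get_family
from .flagging import calibrate
from .predictors import PredictorContext, WeightSpec, predict

__all__ = ["ClusteredDataset", "FitResult", "simulate", "asthma_like",
           "split_dataset", "fit_glmm", "validation_zhat", "subgroup_msep",
           "flag_agreement", "run_example", "ExampleResult"]


@dataclass
class ClusteredDataset:
    """Clustered outcomes with per-cluster covariates.

    ``clusters`` holds one row per cluster (id, size n, covariate
    columns, outcome total y_total and, for simulated data, the true
    z).  ``units`` holds one row per unit (cluster id, outcome y).
    """

    clusters: pd.DataFrame
    units: pd.DataFrame
    covariate_cols: list[str]
    family: str
    seed: int | None = None

    def __post_init__(self):
        totals = self.units.groupby("cluster")["y"].sum()
        if not np.array_equal(
                totals.reindex(self.clusters["cluster"]).to_numpy(),
                self.clusters["y_total"].to_numpy()):
            raise ValueError("cluster totals do not match unit outcomes")

    @property
    def m(self) -> int:
        return len(self.clusters)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(0)) / x.std(0)


def simulate(family: str, m: int, sizes, beta, sigma_u: float,
             n_covariates: int = 0, seed: int = 0,
             standardize: bool = True,
             covariates: np.ndarray | None = None) -> ClusteredDataset:
    """Draw a clustered dataset from the GLMM.

    ``beta`` starts with the intercept; ``n_covariates`` cluster-level
    standard-normal covariates are generated unless an explicit
    (m x n_covariates) matrix is passed.  ``sizes`` is a scalar or a
    length-m vector of cluster sizes.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.broadcast_to(np.asarray(sizes, dtype=int), (m,)).copy()
    if np.any(sizes < 1):
        raise ValueError("cluster sizes must be >= 1")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size != n_covariates + 1:
        raise ValueError("beta must have one entry per covariate plus "
                         "the intercept")
    if covariates is None:
        x = rng.standard_normal((m, n_covariates))
    else:
        x = np.asarray(covariates, dtype=float).reshape(m, n_covariates)
    if standardize and n_covariates:
        x = _standardize(x)

    z = rng.standard_normal(m)
    eta_fixed = beta[0] + x @ beta[1:]
    eta = eta_fixed + sigma_u * z

    fam = get_family(family)
    cluster_rows, unit_cluster, unit_y = [], [], []
    for i in range(m):
        if fam.name in ("bernoulli_logit", "binomial_logit"):
            y = rng.binomial(1, expit(eta[i]), size=sizes[i])
        elif fam.name == "poisson_log":
            y = rng.poisson(math.exp(eta[i]), size=sizes[i])
        elif fam.name == "gaussian_identity":
            y = eta[i] + rng.normal(0.0, 1.0 / math.sqrt(fam.scale),
                                    size=sizes[i])
        else:
            raise ValueError(f"cannot simulate family {fam.name!r}")
        unit_cluster.append(np.full(sizes[i], i))
        unit_y.append(y)
        cluster_rows.append(dict(cluster=i, n=int(sizes[i]),
                                 y_total=float(y.sum()), z_true=z[i]))

    cov_cols = [f"x{j + 1}" for j in range(n_covariates)]
    clusters = pd.DataFrame(cluster_rows)
    for j, c in enumerate(cov_cols):
        clusters[c] = x[:, j]
    units = pd.DataFrame(dict(cluster=np.concatenate(unit_cluster),
                              y=np.concatenate(unit_y)))
    return ClusteredDataset(clusters, units, cov_cols, fam.name, seed)


#: Parameters of the asthma-like preset: baseline revisit probability
#: expit(-1.1) ~ 0.25, moderate covariate effects, sigma_u = 0.5.
ASTHMA_PARAMS = dict(mu=-1.1, beta_pollution=0.2, beta_income=-0.3,
                     sigma_u=0.5)


def asthma_like(seed: int = 0) -> ClusteredDataset:
    """Binary revisit outcomes in 248 zip-code clusters of >= 100
    children (100 + Poisson(80) units each, ~45,000 in total) with two
    standardized cluster-level covariates."""
    rng = np.random.default_rng(seed)
    m = 248
    sizes = 100 + rng.poisson(80.0, size=m)
    p = ASTHMA_PARAMS
    return simulate("bernoulli_logit", m, sizes,
                    beta=[p["mu"], p["beta_pollution"], p["beta_income"]],
                    sigma_u=p["sigma_u"], n_covariates=2,
                    seed=seed + 1, standardize=True)


def split_dataset(ds: ClusteredDataset, fraction: float = 0.5,
                  seed: int | None = None
                  ) -> tuple[ClusteredDataset, ClusteredDataset]:
    """Randomly partition units *within* each cluster into training and
    validation subsets (training gets ``fraction`` of each cluster)."""
    rng = np.random.default_rng(ds.seed if seed is None else seed)
    train_mask = np.zeros(len(ds.units), dtype=bool)
    for _, idx in ds.units.groupby("cluster").indices.items():
        k = int(round(fraction * idx.size))
        chosen = rng.choice(idx, size=k, replace=False)
        train_mask[chosen] = True

    def subset(mask):
        units = ds.units[mask].reset_index(drop=True)
        agg = units.groupby("cluster")["y"].agg(["sum", "size"])
        clusters = ds.clusters.set_index("cluster").loc[agg.index].copy()
        clusters["y_total"] = agg["sum"].to_numpy(dtype=float)
        clusters["n"] = agg["size"].to_numpy(dtype=int)
        return ClusteredDataset(clusters.reset_index(), units,
                                ds.covariate_cols, ds.family, ds.seed)

    return subset(train_mask), subset(~train_mask)


@dataclass
class FitResult:
    """Maximum-likelihood estimates of the GLMM parameters."""

    beta: np.ndarray             # intercept first
    sigma_u: float
    loglik: float
    converged: bool
    se: np.ndarray | None = None   # asymptotic SEs for (beta..., sigma_u)
    gradient_norm: float = np.nan

    @property
    def mu(self) -> float:
        return float(self.beta[0])


def _cluster_loglik(k, n, eta_fixed, sigma_u, fam: FamilySpec,
                    nodes, log_w) -> np.ndarray:
    """Marginal log-likelihood per cluster via Gauss-Hermite nodes.

    Uses the cluster total as the sufficient statistic (covariates are
    cluster-constant), including the data-dependent constant so the
    value is a proper log-likelihood.
    """
    eta = eta_fixed[:, None] + sigma_u * nodes[None, :]
    if fam.name in ("bernoulli_logit", "binomial_logit"):
        ll = (k[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta))
        const = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    elif fam.name == "poisson_log":
        ll = k[:, None] * eta - n[:, None] * np.exp(eta)
        # sum_j log(1/y_ij!) is omitted: constant in the parameters
        const = np.zeros_like(k)
    else:
        raise ValueError(f"fit not implemented for family {fam.name!r}")
    return logsumexp(ll + log_w[None, :], axis=1) + const


def fit_glmm(ds: ClusteredDataset, n_nodes: int = 31,
             compute_se: bool = True) -> FitResult:
    """Fit the random-intercept GLMM by maximizing the Gauss-Hermite
    marginal likelihood over (beta, log sigma_u)."""
    fam = get_family(ds.family)
    cl = ds.clusters
    k = cl["y_total"].to_numpy(dtype=float)
    n = cl["n"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(cl))]
                        + [cl[c].to_numpy() for c in ds.covariate_cols])
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    nodes = math.sqrt(2.0) * t
    log_w = np.log(w) - 0.5 * math.log(math.pi)

    def negll_raw(beta, sigma_u):
        return -float(_cluster_loglik(k, n, X @ beta, sigma_u, fam,
                                      nodes, log_w).sum())

    def negll(params):
        return negll_raw(params[:-1], math.exp(params[-1]))

    # start from the pooled GLM-ish fit with a small random effect
    p0 = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    start = np.zeros(X.shape[1] + 1)
    start[0] = (logit(p0) if fam.name != "poisson_log"
                else math.log(max(p0, 1e-12)))
    start[-1] = math.log(0.2)
    opt = minimize(negll, start, method="BFGS",
                   options=dict(gtol=1e-6, maxiter=500))
    beta = opt.x[:-1]
    sigma_u = float(math.exp(opt.x[-1]))

    se = None
    if compute_se:
        theta = np.append(beta, sigma_u)

        def negll_theta(th):
            return negll_raw(th[:-1], max(th[-1], 1e-8))

        H = _numeric_hessian(negll_theta, theta)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            se = None

    return FitResult(beta=beta, sigma_u=sigma_u, loglik=-float(opt.fun),
                     converged=bool(opt.success),
                     se=se, gradient_norm=float(np.linalg.norm(opt.jac)))


def _numeric_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian, adequate for asymptotic SEs."""
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
    return H


def validation_zhat(p_hat, eta_hat, sigma_hat: float):
    """Surrogate "true" effect from a validation proportion:
    [logit(phat) - etahat] / sigmahat.

    Raises on degenerate proportions (0 or 1): the workflow restricts to
    large clusters precisely so validation proportions stay interior.
    """
    p = np.asarray(p_hat, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("validation proportion of 0 or 1: cannot form "
                         "logit; restrict to larger clusters")
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    return (logit(p) - np.asarray(eta_hat, dtype=float)) / sigma_hat


def subgroup_msep(predictions, zhat_valid, n_groups: int = 10
                  ) -> pd.DataFrame:
    """Mean squared difference (prediction - zhat_valid)^2 within
    equal-size subgroups ordered by zhat_valid (decile bins by
    default)."""
    pred = np.asarray(predictions, dtype=float)
    zv = np.asarray(zhat_valid, dtype=float)
    if pred.shape != zv.shape:
        raise ValueError("predictions and validation effects must align")
    order = np.argsort(zv, kind="stable")
    chunks = np.array_split(order, n_groups)
    rows = []
    for g, idx in enumerate(chunks):
        if idx.size == 0:
            rows.append(dict(group=g + 1, n=0, msep=np.nan, empty=True))
        else:
            rows.append(dict(group=g + 1, n=int(idx.size),
                             msep=float(np.mean((pred[idx] - zv[idx]) ** 2)),
                             empty=False))
    return pd.DataFrame(rows)


def flag_agreement(flags, extreme_labels) -> dict:
    """2x2 agreement between flag decisions and "extreme" labels.

    Returns the four counts plus the empirical incorrect flagging rate
    (flagged among not-extreme) and correct flagging rate (flagged among
    extreme).
    """
    f = np.asarray(flags, dtype=bool)
    e = np.asarray(extreme_labels, dtype=bool)
    if f.shape != e.shape:
        raise ValueError("flags and labels must have equal length")
    out = dict(
        flag_extreme=int(np.sum(f & e)),
        noflag_extreme=int(np.sum(~f & e)),
        flag_not_extreme=int(np.sum(f & ~e)),
        noflag_not_extreme=int(np.sum(~f & ~e)),
    )
    n_ext = out["flag_extreme"] + out["noflag_extreme"]
    n_not = out["flag_not_extreme"] + out["noflag_not_extreme"]
    out["incorrect_rate"] = (out["flag_not_extreme"] / n_not
                             if n_not else np.nan)
    out["correct_rate"] = out["flag_extreme"] / n_ext if n_ext else np.nan
    return out


@dataclass
class ExampleResult:
    """Everything the example pipeline produces."""

    fit: FitResult
    predictions: pd.DataFrame       # per-cluster predictor values & flags
    subgroup: pd.DataFrame          # subgroup MSEP per predictor
    agreement: dict                 # rule name -> 2x2 agreement dict
    tau: float
    alpha: float
    calibration_equivalent: bool    # SQ and AB flagged identical sets
    params: dict = field(default_factory=dict)


def run_example(seed: int = 0, tau: float = 1.28, alpha: float = 0.1,
                split_fraction: float = 0.5, extreme_q: float = 0.1,
                sq_lambdas=(0.3, 0.4), ab_lambdas=(1.0, 1.4, 1.8),
                n_groups: int = 10) -> ExampleResult:
    """Full train/validate profiling workflow on the asthma-like data.

    Fits the GLMM to the training half, computes best and weighted
    predictors plus per-cluster self-calibrated SQ/AB flags from
    training totals, labels the top ``extreme_q`` fraction of validation
    proportions "extreme", and reports subgroup MSEPs and flagging
    agreement.
    """
    ds = asthma_like(seed)
    train, valid = split_dataset(ds, split_fraction)
    fit = fit_glmm(train, compute_se=False)
    fam = get_family(ds.family)

    cl = train.clusters.set_index("cluster")
    vl = valid.clusters.set_index("cluster")
    common = cl.index.intersection(vl.index)
    X = np.column_stack([np.ones(len(common))]
                        + [cl.loc[common, c].to_numpy()
                           for c in ds.covariate_cols])
    eta_hat = X @ fit.beta
    y_train = cl.loc[common, "y_total"].to_numpy()
    n_train = cl.loc[common, "n"].to_numpy(dtype=int)

    weights = ([("BP", 0.0)] + [("SQ", l) for l in sq_lambdas]
               + [("AB", l) for l in ab_lambdas])
    pred = pd.DataFrame(index=common)
    pred["y_train"] = y_train
    pred["n_train"] = n_train

    flags_cal: dict[str, list] = {"SQ": [], "AB": []}
    z_cal: dict[str, list] = {"SQ": [], "AB": []}
    for i, cid in enumerate(common):
        lp = LinearPredictorSpec.intercept_only(
            float(eta_hat[i]), int(n_train[i]), fit.sigma_u)
        for kind, lam in weights:
            ctx = PredictorContext(fam, lp, WeightSpec(kind, lam))
            col = "z_bp" if kind == "BP" else f"z_{kind.lower()}_{lam:g}"
            pred.loc[cid, col] = predict(ctx, float(y_train[i]))
        for kind in ("SQ", "AB"):
            cal = calibrate(fam, lp, kind, tau, alpha)
            flags_cal[kind].append(bool(y_train[i] > cal.threshold_y))
            lam = cal.lambda_star if cal.lambda_star is not None else 0.0
            z_cal[kind].append(predict(
                PredictorContext(fam, lp, WeightSpec(kind, lam)),
                float(y_train[i])))
    pred["flag_bp"] = pred["z_bp"] > tau
    for kind in ("SQ", "AB"):
        pred[f"z_{kind.lower()}_cal"] = z_cal[kind]
        pred[f"flag_{kind.lower()}_cal"] = flags_cal[kind]

    p_valid = (vl.loc[common, "y_total"] / vl.loc[common, "n"]).to_numpy()
    zhat = validation_zhat(p_valid, eta_hat, fit.sigma_u)
    pred["p_valid"] = p_valid
    pred["zhat_valid"] = zhat
    cutoff = np.quantile(p_valid, 1.0 - extreme_q)
    extreme = p_valid > cutoff
    pred["extreme"] = extreme

    agreement = {
        "BP": flag_agreement(pred["flag_bp"], extreme),
        "SQ": flag_agreement(pred["flag_sq_cal"], extreme),
        "AB": flag_agreement(pred["flag_ab_cal"], extreme),
    }
    sub_rows = []
    for kind, lam in weights:
        col = "z_bp" if kind == "BP" else f"z_{kind.lower()}_{lam:g}"
        sg = subgroup_msep(pred[col].to_numpy(), zhat, n_groups)
        sg.insert(0, "predictor", col)
        sub_rows.append(sg)
    subgroup = pd.concat(sub_rows, ignore_index=True)

    return ExampleResult(
        fit=fit, predictions=pred.reset_index(), subgroup=subgroup,
        agreement=agreement, tau=tau, alpha=alpha,
        calibration_equivalent=bool(
            (pred["flag_sq_cal"] == pred["flag_ab_cal"]).all()),
        params=dict(seed=seed, split_fraction=split_fraction,
                    extreme_q=extreme_q, sq_lambdas=tuple(sq_lambdas),
                    ab_lambdas=tuple(ab_lambdas)))
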