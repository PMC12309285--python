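"""Scenario-grid evaluations of MSEP differences and flagging rates.

Two grid engines mirror the package's headline numerical evaluations:

* :func:`run_msep_grid` — the difference in conditional MSEP between
  each weighted predictor (SQ at lambda 0.2/0.3/0.4, AB at 1.2/1.6/2.0)
  and the best predictor over a factorial grid of intercept mu, cluster
  size n, random-effect scale sigma_u and threshold tau;
* :func:`run_flagging_grid` — exact incorrect and correct flagging
  rates of the best-predictor rule and of self-calibrated SQ and AB
  rules over a mu x n x tau x sigma_u x alpha grid, marking infeasible
  cells (where even the best predictor's rule exceeds alpha).

Cells are mutually independent; results are emitted as tidy DataFrames
ordered by scenario key, and :func:`summarize` reduces them to the
box-plot statistics (median, quartiles, whiskers) used for reporting.
The whole path is deterministic — no randomness enters any cell.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import LinearPredictorSpec, get_family
from .flagging import calibrate, flag_rates
from .msep import msep_binary, msep_poisson
from .predictors import PredictorContext, WeightDivergenceError, WeightSpec

__all__ = ["MsepGridConfig", "FlagGridConfig", "run_msep_grid",
           "run_flagging_grid", "summarize"]

log = logging.getLogger(__name__)


def _sigma_grid(stop: float) -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.1, stop + 1e-9, 0.1), 10))


@dataclass(frozen=True)
class MsepGridConfig:
    """Grid for the MSEP-difference evaluation.

    Defaults are the binary-outcome evaluation grid; for Poisson
    outcomes use :meth:`poisson`, which stops the sigma_u grid at 1.0.
    """

    family: str = "binomial_logit"
    mus: tuple = (-2.0, -1.0)
    ns: tuple = (5, 7, 20, 100)
    sigma_us: tuple = field(default_factory=lambda: _sigma_grid(1.2))
    taus: tuple = (1.28, 1.645, 1.96, 2.33)
    sq_lambdas: tuple = (0.2, 0.3, 0.4)
    ab_lambdas: tuple = (1.2, 1.6, 2.0)

    @classmethod
    def poisson(cls, **kw) -> "MsepGridConfig":
        kw.setdefault("family", "poisson_log")
        kw.setdefault("sigma_us", _sigma_grid(1.0))
        return cls(**kw)


@dataclass(frozen=True)
class FlagGridConfig:
    """Grid for the flagging-rate evaluation.

    The default sigma_u grid runs 0.1-1.3 by 0.1: together with the five
    intercepts, four cluster sizes, four thresholds and two alpha levels
    this gives 2080 scenario-alpha cells, of which 295 (14%) are
    infeasible for binary outcomes.
    """

    family: str = "binomial_logit"
    mus: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0)
    ns: tuple = (5, 10, 20, 100)
    sigma_us: tuple = field(default_factory=lambda: _sigma_grid(1.3))
    taus: tuple = (1.28, 1.645, 1.96, 2.33)
    alphas: tuple = (0.05, 0.10)

    @classmethod
    def poisson(cls, **kw) -> "FlagGridConfig":
        kw.setdefault("family", "poisson_log")
        kw.setdefault("sigma_us", _sigma_grid(1.0))
        return cls(**kw)


def _msep_one(ctx: PredictorContext, tau: float) -> float:
    if ctx.family.name == "poisson_log":
        return msep_poisson(ctx, tau).msep
    return msep_binary(ctx, tau).msep


def run_msep_grid(config: MsepGridConfig = MsepGridConfig()) -> pd.DataFrame:
    """MSEP(weighted) - MSEP(BP) per grid cell and weighted predictor.

    Cells where the SQ integral diverges are recorded with status
    ``"divergent"`` and NaN difference rather than dropped.
    """
    family = get_family(config.family)
    weights = ([("SQ", l) for l in config.sq_lambdas]
               + [("AB", l) for l in config.ab_lambdas])
    rows = []
    cells = list(itertools.product(config.mus, config.ns,
                                   config.sigma_us, config.taus))
    for idx, (mu, n, sigma_u, tau) in enumerate(cells):
        lp = LinearPredictorSpec.intercept_only(mu, n, sigma_u)
        ctx_bp = PredictorContext(family, lp, WeightSpec.bp())
        msep_bp = _msep_one(ctx_bp, tau)
        for kind, lam in weights:
            ctx_w = ctx_bp.with_weight(WeightSpec(kind, lam))
            try:
                msep_w = _msep_one(ctx_w, tau)
                status = "ok"
            except WeightDivergenceError:
                msep_w = np.nan
                status = "divergent"
            rows.append(dict(family=family.name, mu=mu, n=n,
                             sigma_u=sigma_u, tau=tau, kind=kind,
                             lam=lam, msep=msep_w, msep_bp=msep_bp,
                             diff=msep_w - msep_bp, status=status))
        if (idx + 1) % 100 == 0:
            log.info("msep grid: %d/%d cells", idx + 1, len(cells))
    out = pd.DataFrame(rows)
    return out.sort_values(["mu", "n", "sigma_u", "tau", "kind", "lam"],
                           ignore_index=True)


def run_flagging_grid(config: FlagGridConfig = FlagGridConfig()
                      ) -> pd.DataFrame:
    """Exact flagging rates of BP and self-calibrated SQ/AB per cell.

    One row per (cell x alpha x predictor).  ``feasible`` is False where
    the BP rule's incorrect rate already exceeds alpha; calibrated rows
    of infeasible cells carry the BP rates and a missing lambda.
    """
    family = get_family(config.family)
    rows = []
    cells = list(itertools.product(config.mus, config.ns,
                                   config.sigma_us, config.taus))
    for idx, (mu, n, sigma_u, tau) in enumerate(cells):
        lp = LinearPredictorSpec.intercept_only(mu, n, sigma_u)
        ctx_bp = PredictorContext(family, lp, WeightSpec.bp())
        bp = flag_rates(ctx_bp, tau)
        base = dict(family=family.name, mu=mu, n=n, sigma_u=sigma_u, tau=tau)
        for alpha in config.alphas:
            cals = {kind: calibrate(family, lp, kind, tau, alpha)
                    for kind in ("SQ", "AB")}
            # cell-level feasibility (shared by the BP row): whether any
            # nontrivial self-calibrated rule exists at this alpha
            rows.append(dict(base, alpha=alpha, kind="BP", lam=0.0,
                             y_threshold=bp.threshold_y, y_alpha=np.nan,
                             incorrect=bp.incorrect, correct=bp.correct,
                             feasible=cals["AB"].feasible,
                             exact_boundary=np.nan))
            for kind in ("SQ", "AB"):
                cal = cals[kind]
                rows.append(dict(
                    base, alpha=alpha, kind=kind,
                    lam=np.nan if cal.lambda_star is None else cal.lambda_star,
                    y_threshold=cal.threshold_y, y_alpha=cal.y_alpha,
                    incorrect=cal.achieved_incorrect,
                    correct=cal.achieved_correct,
                    feasible=cal.feasible,
                    exact_boundary=cal.exact_boundary))
        if (idx + 1) % 100 == 0:
            log.info("flagging grid: %d/%d cells", idx + 1, len(cells))
    out = pd.DataFrame(rows)
    return out.sort_values(["mu", "n", "sigma_u", "tau", "alpha", "kind"],
                           ignore_index=True)


def summarize(table: pd.DataFrame, value: str = "incorrect",
              by: tuple = ("kind", "alpha"),
              feasible_only: bool = True) -> pd.DataFrame:
    """Box-plot statistics of one rate/difference column.

    Medians, quartiles and Tukey whiskers per group, rounded to 2
    decimals for comparison with reported values.  Summaries cover
    feasible cells only (matching the exclusion of infeasible scenarios
    from the reported plots); an empty feasible set yields a single row
    marked ``empty=True``.
    """
    df = table
    if feasible_only and "feasible" in df.columns:
        df = df[df["feasible"]]
    df = df.dropna(subset=[value])
    if df.empty:
        return pd.DataFrame([{k: np.nan for k in by}
                             | dict(empty=True, n_cells=0)])

    def stats(g):
        v = g[value].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        return pd.Series(dict(
            n_cells=len(v), median=round(med, 2), q1=round(q1, 2),
            q3=round(q3, 2), whisker_lo=round(lo, 2),
            whisker_hi=round(hi, 2)))

    out = (df.groupby(list(by), dropna=False)
             .apply(stats, include_groups=False).reset_index())
    out["empty"] = False
    return out
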