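# Methods

## Model

Outcomes are clustered: `y_ij` for unit `j = 1..n_i` in cluster
`i = 1..m`, following a canonical-link GLMM

    f(y_ij | z_i, x_ij) = exp[{y_ij η_ij − a(η_ij)} γ + b(y_ij, γ)],
    η_ij = σ_u z_i + β'x_ij,   z_i ~ N(0, 1) i.i.d.

`a` is the cumulant function of the family (log(1+e^η) for logistic,
e^η for log-link Poisson, η²/2 for Gaussian), `γ` a positive scale
(1 for Bernoulli/Poisson, the error precision for the Gaussian). The
random effect is deliberately parameterized as a scale `σ_u` times a
*standardized* effect `z`, because thresholds for "extreme" are easiest
to state on the standardized scale (|z| > 2 is unusual; z > 1.28 is the
upper decile).

Because the link is canonical, the posterior of `z_i` given a cluster's
data has kernel

    exp[γ{Y_i· σ_u z − Σ_j a(η_ij(z))} − z²/2],

which depends on the data only through the cluster total `Y_i·`. All
predictors considered here are therefore functions of the total, and
the package works with the exact distribution of `Y_· | z`: binomial
for the logistic model with cluster-constant covariates,
Poisson-binomial with unit-level covariates (exact O(n²)
dynamic-programming convolution, verified against exhaustive
enumeration), Poisson with mean ν· = Σ_j exp(β'x_j + σ_u z) for the
log link, and normal for the identity link.

## Weighted predictors and flagging

The predictor minimizing the weighted risk E[w(z)(z̃ − z)²] is
z̃_w = E[z w(z) | Y] / E[w(z) | Y]. Weight families:

| kind | w(z)        | λ range                     | role |
|------|-------------|-----------------------------|------|
| BP   | 1           | —                           | classical best predictor |
| SQ   | exp(λz²)    | λ < 1/2 for Gaussian-tailed posteriors | strong emphasis on extremes |
| AB   | exp(λ\|z\|) | any λ ≥ 0                   | moderate emphasis, always admissible |

For SQ with λ ≥ 1/2 the weighted integral diverges against the
Gaussian-tailed posteriors of binomial and Gaussian outcomes (and, via
the lower tail, Poisson); `predict` raises a divergence error rather
than silently truncating, and additionally aborts if the weighted
integrand peaks at the integration boundary.

A Cauchy–Schwarz argument shows ∂z̃_w/∂Y· ≥ 0, so z̃_w is
non-decreasing in the total and the rule "flag iff z̃_w > τ" (strict)
equals "flag iff Y· > y_{·,τ}" with `invert` finding the largest total
with z̃_w < τ by exhaustive upward scan (bracketed bisection for
continuous totals). Scans are chunked and, for Poisson, capped at a
truncation bound; if no total reaches τ the threshold is the +∞
sentinel and the rule never flags.

Flagging operating characteristics are exact one-dimensional integrals:

    incorrect = 1 − ∫_{−∞}^{τ} F(y_{·,τ} | z) φ(z) dz / Φ(τ)
    correct   = 1 − ∫_{τ}^{∞}  F(y_{·,τ} | z) φ(z) dz / (1 − Φ(τ)),

with `F` the cdf of the total given z. Normalizing masses come from the
complementary error function, not quadrature.

## Self-calibration and feasibility

A weight is self-calibrated at level α when its rule's incorrect rate
is ≤ α. Let `y_α` be the smallest y with Pr{Y· > y | z < τ} ≤ α.
Calibration solves z̃_λ(y_α) = τ by bisection on λ (the count threshold
is a non-increasing step function of λ); default brackets are
λ ∈ [0, 0.499] for SQ and λ ∈ [0, 8] for AB. When the bracket cannot
land the threshold exactly on `y_α` (discreteness, or the SQ
admissibility bound), the λ attaining the closest achievable threshold
with rate ≤ α is returned and flagged `exact_boundary=False`. Whenever
two weight families both calibrate exactly, their flagged sets coincide
(the rule is `Y· > y_α` either way) even though the predictions differ
— an equivalence the test suite asserts across the whole grid.

A scenario is *infeasible* at level α when the discreteness of `Y·`
leaves nothing to calibrate: `y_α` sits at the top of a bounded
support, i.e. even the most conservative nontrivial rule "flag only
Y· = n" exceeds α (equivalently Pr{Y· = n | z < τ} > α), so the only
conforming rule flags nothing. The best-predictor rule exceeding α is
retained as a second trigger. On the default binary grid (below) this
marks 295 of 2080 scenario-α cells (14%) infeasible — 190 at α = 0.05,
105 at α = 0.10 — all in small-n, low-threshold corners. Poisson totals
have unbounded support, so `y_α` is always interior and no Poisson cell
is infeasible. Feasibility-filtered summaries therefore exclude exactly
the cells where no self-calibrated rule exists.

## MSEP

Prediction accuracy for extremes is measured by
E[(z − z̃_w)² | z > τ], computed as a sum over the support of the total
of bounded-quadrature integrals on (τ, 8); lower-tail and two-sided
variants re-parameterize the same code. The Poisson sum is truncated
where the quadrature-weighted tail mass falls below 1e−14 per node
budget; the attained error bound is reported and must stay below
1e−10. A generic route through any `TotalDistribution` coexists with
the specialized binomial/Poisson forms and the two are tested to agree
to 1e−10; with unit-level covariates the Poisson-binomial route is
tested against brute-force enumeration of all outcome vectors.

Across the binary evaluation grid (μ ∈ {−2, −1}, n ∈ {5, 7, 20, 100},
σ_u 0.1–1.2, τ ∈ {1.28, 1.645, 1.96, 2.33}) the AB differences
MSEP(z̃_AB) − MSEP(z̃_BP) are negative in ≳ 90% of cells at every λ.
For log-link Poisson outcomes the square weight at λ = 0.4 can be
*less* accurate than the best predictor in small clusters (n ≤ 20 at
τ = 1.28), where λ = 0.3 restores the advantage; at n = 100 the
weighted predictors dominate throughout. Divergent SQ cells are
recorded as such, never silently dropped.

## Quadrature

Everything is an integral of f(z)φ(z). Tail integrals (rates, MSEP,
`y_α`) use Gauss–Legendre on the clipped interval with φ folded into
the weights — the standard bounded Gauss–Hermite construction — with
64 nodes; fully unbounded rules use classical Gauss–Hermite (50
nodes). Effectively-infinite endpoints are clipped at ±8, beyond which
the standard normal mass is < 1e−15.

Posterior integrals behind z̃_w need more care: with n = 100
observations the posterior of z has standard deviation well under 0.2
and can peak anywhere in (−3, 3), and the AB weight has a kink at
z = 0. The default rule is therefore a *panelized* Gauss–Legendre rule:
width-1 panels spanning [−8, 8] with a panel edge at 0 and 25 nodes per
panel (400 nodes total). This is machine-accurate for every
family/weight combination in the test grid and satisfies the refinement
invariant (doubling any node count moves predictors, MSEPs and rates by
far less than 1e−6). All posterior-weighted integrals are accumulated
in log space with signed log-sum-exp — exp(λz²) at λ = 0.4, z = 8
overflows double precision otherwise — and binomial coefficients come
from log-gamma.

## Scenario grids

`run_flagging_grid` reproduces the flagging evaluation: binary defaults
μ ∈ {−1, −0.5, 0, 0.5, 1}, n ∈ {5, 10, 20, 100},
τ ∈ {1.28, 1.645, 1.96, 2.33}, α ∈ {0.05, 0.10} and σ_u from 0.1 to
1.3 by 0.1 (2080 scenario-α cells in total, of which the 295 infeasible
ones are excluded from summaries); the summary medians are insensitive
to modest changes in the σ_u spacing. `run_msep_grid` uses the MSEP grids quoted in the
previous section (σ_u to 1.0 for Poisson). Cells are independent, the
numerical path has no randomness, and tables are emitted in a fixed
sort order, so grid outputs are bit-stable across runs. `summarize`
reduces a grid table to box-plot statistics (median, quartiles, Tukey
whiskers, 2-decimal rounding) over feasible cells only.

On one CPU the full binary flagging grid takes about 40 s and the
binary MSEP grid about 3 s; the full Poisson MSEP grid (large truncated
supports at n = 100) takes several minutes and is exercised in reduced
form by the test suite.

## Synthetic data and the example workflow

`simulate` draws data from the model exactly as written: z_i ~ N(0,1),
covariates cluster-level standard normal, standardized to sample mean 0
and variance 1 when requested. The `asthma_like` preset emulates a
zip-code profiling study of emergency-department revisits: m = 248
clusters, sizes 100 + Poisson(80) (≈ 45,000 children in total — the
minimum size keeps validation proportions away from 0 and 1), binary
outcome with intercept μ = −1.1 (baseline revisit probability ≈ 0.25),
pollution-score and income covariates with β = (0.2, −0.3), and
σ_u = 0.5.

`run_example` mirrors a full profiling analysis: units are split 50/50
at random within each cluster; a random-intercept logistic model is
fitted to the training half by maximizing the Gauss–Hermite marginal
likelihood (31 nodes, BFGS on (β, log σ_u); asymptotic standard errors
from a finite-difference Hessian); best, fixed-λ weighted and
per-cluster self-calibrated predictors are computed from training
totals (τ = 1.28, α = 0.1); the validation half supplies surrogate
effects ẑ = [logit(p̂) − η̂]/σ̂_u and an "extreme" label for the top
10% of validation proportions. Outputs are decile-wise MSEPs of each
predictor against ẑ and 2×2 flag/extreme agreement tables. The
generator draws covariates and sizes fresh per seed, so replicate runs
are genuine replications; everything is byte-reproducible under a fixed
seed.

What the synthetic data do *not* emulate: spatial correlation between
neighboring zip codes, covariate measurement error, within-cluster unit
heterogeneity (covariates are cluster-level), and any misspecification
of the random-effect distribution. Passing tests show the machinery is
correct under the model, not that the model fits any particular real
data set.

## Known limitations

- Gamma-family outcomes are not implemented; the continuous-outcome
  branches (inversion by bisection, normal totals) keep the contract
  open but only the Gaussian family exercises them.
- Non-canonical links and overdispersion are out of scope; without the
  sufficiency of the cluster total the count-threshold structure of the
  flagging rules would not hold.
- Estimation uncertainty is not propagated into MSEPs or flagging
  rates: scenario evaluations condition on known θ = (γ, σ_u, β), and
  the example workflow plugs in point estimates.
- The SQ weight's admissible range for Poisson outcomes is enforced
  numerically (boundary-peak detection) rather than by a closed-form
  bound.
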