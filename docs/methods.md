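# Methods

This note records the statistical models, estimators, numerical choices and
limitations behind `censdev`.  Empirical statements here are ones the test
suite or `scripts/acceptance.py` actually computes.

## 1. Censored likelihood

Each observation carries a status and cutoffs; given an outcome family with
CDF `F` and density/pmf `f`, the log-likelihood terms are

| status               | contribution            |
|----------------------|-------------------------|
| observed `y`         | `log f(y)`              |
| right-censored at `l`| `log S(l) = log(1−F(l))`|
| left-censored at `u` | `log F(u)`              |
| interval `(l, u]`    | `log(F(u) − F(l))`      |

Standing assumption: **noninformative censoring** — the censoring mechanism
is independent of the outcome model, so these terms are the full likelihood.

For count families the default convention is strict: "count below `c`"
means `Y ≤ c − 1`, so a left-censored count contributes `log F(c − 1)`
(`count_strict=False` switches to `Y ≤ c`).  Censoring events must have
positive probability; "count < 0" or "count > n" are rejected as invalid
observations rather than evaluated to `−inf`.

All terms are computed in log space (`logpdf`, `logcdf`, `logsf`); the
exponential survivor uses the exact `−λt`.  The beta-binomial CDF is a
`logsumexp` over pmf terms.

### Indicator (augmented) formulation

Censoring can be rewritten with Bernoulli indicators: `Z₁ = 1{left}` with
success probability `F(cut)` for one-sided censoring, and `Z₂ = 1` with
probability `F(u) − F(l)` for intervals; the indicators are fixed by the
censoring pattern, not sampled.  The product of these Bernoulli likelihoods
equals the exact censored likelihood.  `augmented_log_likelihood`
deliberately evaluates the probability-scale route (with clipping at
`1e−12`) so that agreement with the log-space exact route is a genuine
dual-computation check; the test suite and acceptance script verify
`|augmented − exact| < 1e−10` over 1,000 random mixed datasets spanning
every family and censoring type.

## 2. Deviance monitoring and the focus problem

The deviance is `D(θ) = −2 log L(θ)` and decomposes per observation into
`D_obs + D_cen`.  `monitor_deviance` evaluates per-observation terms at
every saved draw.  The **wrong-focus diagnostic** (`observed_only_deviance`)
zeroes the censored columns, reproducing what a deviance monitor sees when
censoring is implemented through a degenerate interval-indicator device:
censored observations then contribute likelihood 1.  On any censored
dataset, full mean deviance − observed-only mean deviance = censored-part
mean deviance (checked to `1e−8`).

## 3. Model selection

- **DIC** `= D̄ + p_D` with the plug-in `p_D = D̄ − D(θ̂)`, where `θ̂` is
  the posterior mean taken on the unconstrained sampling scale and mapped
  back (invariant to how constrained parameters are parameterized).
  Plug-in `p_D` can misbehave when the posterior is far from Gaussian; a
  negative `p_D` below `−1e−8` triggers a warning.
- **PED** `= D̄ + p_opt` with the optimism `p_opt ≥ p_D`:
  - `asymptotic`: `p_opt = 2 Σᵢ p_Dᵢ` from per-observation complexities;
  - `importance`: paired-chain self-normalized importance sampling — one
    chain supplies the plug-in values, the other the weights
    `exp(dᵢ/2) = 1/fᵢ`; observation pairs whose weight effective sample
    size falls below 5% of the draws fall back to the asymptotic form
    (with a warning naming how many did).

The saturated adverse-event model G is the stress case: its plug-in `p_D`
(~78 for 125 studies in the shipped example) understates its 125+2 free
parameters, DIC still ranks it best, and only the optimism penalty makes it
lose — the motivating pattern for reporting both criteria.

## 4. Sampler

Adaptive random-walk Metropolis-within-Gibbs:

- one Gaussian proposal per coordinate per sweep; log step sizes adapted by
  Robbins–Monro (`gain (1+it)^−0.6`, target acceptance 0.44) during burn-in
  only, then frozen, so the post-burn-in chain is a valid Markov chain;
- constrained parameters sampled on log/logit transforms with the Jacobian
  in the target;
- chain `c` is seeded `base_seed + c`; identical configuration gives
  bit-identical draws;
- `indep_block`: coordinates that are conditionally independent given the
  rest (e.g. per-study incidences given hyperparameters) are updated in one
  vectorised per-coordinate Metropolis pass per sweep, reducing sweep cost
  from O(P·N) to O(N).  It consumes the same random stream and evaluates
  the same per-coordinate targets as the scalar loop, so both paths agree
  draw-for-draw (unit-tested), and conjugate posteriors are recovered.

Default protocol: 3 chains, 30,000 burn-in, 10,000 saved per chain, thin 3.
Convergence is summarised by split-chain R̂ and a degenerate-chain flag.

## 5. Application presets

**Survival**: exponential regression, log hazard `β₀ + β₁x` for a binary
covariate, `N(0, 100²)` priors.  Observed deaths contribute
`log λ − λt`; censored follow-up `−λt`.

**Adverse-event meta-analysis** (study-level binomial counts, counts below
a study-specific cutoff left-censored, strict convention `F(cut − 1)`):

| model | structure | priors |
|-------|-----------|--------|
| A | one shared incidence | Beta(1, 1) |
| B | one per target group (PD-1 vs PD-L1) | Beta(1, 1) |
| C | one per drug | Beta(1, 1) |
| D/E/F | drug effects `link⁻¹(μ + σ z_d)`, link = logit / cloglog / probit | `μ ~ N(0, 10²)`, `z_d ~ N(0, 1)` (non-centred), `σ ~ half-Cauchy(1)` |
| G | one incidence per study, `p_i ~ Beta(a, b)` | `a, b ~ Uniform(0.01, 100)` |

Models A–C use fixed Beta(1, 1) shapes rather than hyperpriors; only G is
hierarchical on the probability scale.  In G the `Beta(a, b)` density of
each `p_i` enters through the likelihood callable (the declared priors on
`p_i` are flat on the logit scale), and the `p_i` block uses the vectorised
independent-block update.

## 6. Synthetic data generators

**Survival**: exponential event times, binary covariate on the log hazard,
administrative (fixed-time) or random-exponential censoring.

**Adverse events**: per study, a drug, a size from `size_range`, and a count
`Binomial(n, p_i)`; counts strictly below the cutoff are masked.  Study
incidences are drawn `p_i ~ Beta(κ p_drug, κ(1 − p_drug))` around the drug
mean with concentration `κ` (`heterogeneity`, default 300, ~30% coefficient
of variation at 3% incidence; `None` disables).  The default was chosen a
priori as moderate, realistic between-study variation from the
overdispersion relation `CV ≈ sqrt((1 − p)/(p(κ + 1)))`; it is the study
condition for all shipped comparisons.

The recovery harness reports per-parameter bias and credible-interval
coverage across replicates and fails if more than 20% of fits error.

## 7. Limitations

- The sampler is for small models (≲ a few hundred parameters); no
  gradient-based methods, no parallel tempering.
- Plug-in `p_D` is the only `p_D` estimator; it can be unstable for
  multimodal or heavy-tailed posteriors and needs adequate burn-in (the
  link-based models D–F show negative `p_D` under severely shortened
  protocols).
- The importance-sampling `p_opt` degenerates for parameters with near-zero
  likelihood overlap between chains (routinely for the saturated model G);
  the per-observation fallback to the asymptotic form is reported, not
  hidden.
- The quantitative reproduction of the published adverse-event comparison
  table requires the original study-level dataset, which is hosted
  externally and could not be obtained in this offline environment; the
  corresponding acceptance test verifies the qualitative pattern on
  synthetic data and fails with instructions for supplying the real table.
- Covariates in the generic likelihood layer are carried per observation
  but only the presets define regression structures.
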