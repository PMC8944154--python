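# censdev

Exact-likelihood Bayesian modelling of censored outcomes, with deviance-based
model selection that counts every observation.

## The problem

A censored observation is partial information, not missing data: a patient
still alive when a trial ends is known to have survived *past* that time; a
safety table that omits adverse-event counts below a reporting cutoff says
the count was *below* the cutoff.  The likelihood handles this exactly — an
observed value contributes its density `f(y)`, a right-censored one the
survivor function `S(t)`, a left-censored one the CDF `F(c)`, and an
interval-censored one `F(u) − F(l)`.

The subtle failure mode this package targets is downstream, in **model
selection**.  A common implementation trick represents censoring through a
degenerate interval-indicator "distribution"; it produces correct posteriors,
but the deviance monitor then sees likelihood 1 (deviance 0) for every
censored observation.  Mean deviances, DIC and penalized expected deviance
(PED) computed that way silently drop the censored subjects — the "wrong
focus".  `censdev` computes the exact per-observation deviance, decomposes it
into observed and censored parts, and also reproduces the biased
observed-only monitor so the two can be compared directly.

Components:

- `distributions` — exponential, Weibull, normal, lognormal, log-logistic,
  binomial and beta-binomial families with log-space `log f`, `log F`,
  `log S`, and logit/probit/cloglog links;
- `likelihood` — exact censored log-likelihood, the equivalent
  Bernoulli-indicator (augmented) formulation, and the deviance
  decomposition; strict count conventions (`count < c` means `Y ≤ c − 1`);
- `sampler` — adaptive random-walk Metropolis-within-Gibbs on unconstrained
  scales, bit-reproducible by seed, with a vectorised update for
  conditionally independent parameter blocks;
- `model_selection` — per-draw deviance monitors, plug-in DIC, and PED with
  an asymptotic or paired-chain importance-sampling optimism `p_opt`;
- `applications` — presets for right-censored exponential survival
  regression and seven censored-binomial adverse-event meta-analysis models
  (A: complete pooling … G: one incidence per study);
- `simulate` — censored-data generators and a parameter-recovery harness;
- a `censdev` command-line interface over the presets.

## Worked example

The classical 23-subject leukemia maintenance-chemotherapy table (18
observed deaths, 5 right-censored follow-up times) ships with the package:

```python
from censdev import McmcConfig, fit_exponential_survival, load_aml

fit = fit_exponential_survival(
    load_aml(), config=McmcConfig(n_chains=3, n_burnin=30_000,
                                  n_saved=10_000, thin=3, base_seed=1))
print(f"full mean deviance:          {fit.mean_deviance:.1f}")
print(f"observed-only mean deviance: {fit.mean_deviance_observed_only:.1f}")
print(f"effective parameters p_D:    {fit.fit.p_d:.2f}")
```

prints

```
full mean deviance:          164.6
observed-only mean deviance: 155.1
effective parameters p_D:    1.99
```

The 9.6-unit gap is the five censored subjects' deviance contribution; a
wrong-focus monitor loses it entirely.  `p_D ≈ 2` matches the two regression
coefficients.

The same effect decides model comparisons.  On 125 simulated studies of
censored adverse-event counts (`python examples/ae_model_comparison.py`):

```
        Dbar   p_D    DIC  p_opt    PED
A     624.40  1.03 625.43   4.35 628.76
B     589.45  2.04 591.49   7.00 596.45
C     565.12  5.02 570.14  17.48 582.60
D     565.38  5.23 570.61  17.42 582.80
E     565.29  5.08 570.38  16.61 581.90
F     565.30  5.06 570.36  17.11 582.42
G     490.42 78.40 568.83 195.15 685.57
```

The saturated model G (one incidence per study) buys the lowest mean
deviance with 125 free parameters; DIC's plug-in penalty still lets it win,
but the optimism penalty `p_opt ≥ p_D` in PED rejects it in favour of a
middle-complexity model.

More narrative walkthroughs live in `examples/`; modelling details,
estimator definitions and limitations are in `docs/methods.md`.

## Command line

```sh
censdev simulate survival --n 300 --seed 1 --out sim/
censdev fit-survival sim/survival.csv --wrong-focus --out fit/
censdev fit-ae studies.csv --model all --out comparison/
```

Every run writes a `manifest.json` with the full configuration; identical
settings and seed reproduce outputs byte-for-byte.

## Reproduction

```sh
python -m pytest -q tests/            # full suite, ~4 minutes
python scripts/acceptance.py --seed 1 --out results.json   # ~4 minutes
```

The acceptance script recomputes the headline quantities above (likelihood
route equivalence, the survival deviance reproduction, effective-parameter
checks, the seven-model comparison on synthetic data, recovery coverage,
conjugate-oracle errors) from the given seed and writes them as JSON.

One test, `test_ae_model_comparison_table`, deliberately fails offline: the
quantitative reproduction of the published adverse-event comparison table
needs the original study-level dataset, which is hosted externally and not
redistributable here.  The test verifies the qualitative pattern on
synthetic data first and explains how to supply the real table
(`tests/data/ae_published.csv`) to enable the numeric check.
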