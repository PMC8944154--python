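"""Checking the whole pipeline with simulated-data parameter recovery.

Generate censored survival data with known coefficients, fit it, and score
bias and credible-interval coverage across replicates.  This is the
standard calibration check for a Bayesian pipeline: ~95% of 95% intervals
should cover the generating values when everything (likelihood, sampler,
summaries) is correct.
"""

from censdev import (
    McmcConfig,
    SurvivalSimConfig,
    fit_exponential_survival,
    recovery_harness,
    simulate_censored_survival,
)


def generate(rep: int):
    return simulate_censored_survival(
        SurvivalSimConfig(n=300, beta0=-3.0, beta1=0.5,
                          censoring=("administrative", 19.0),
                          seed=7000 + rep))


cfg = McmcConfig(n_chains=2, n_burnin=1000, n_saved=1500, thin=1, base_seed=0)
result = recovery_harness(
    generate, lambda recs: fit_exponential_survival(recs, config=cfg),
    n_reps=20)

print(result)
print("\ncoverage near 0.95 and bias near zero indicate a calibrated "
      "likelihood + sampler pipeline under ~30% right-censoring.")
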