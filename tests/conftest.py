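import numpy as np
import pytest

from censdev.distributions import FamilySpec


def random_family(rng: np.random.Generator) -> FamilySpec:
    """A random family with moderate parameters (tail probabilities well
    above the clipping floor, so both likelihood routes stay comparable)."""
    family = rng.choice([
        "exponential", "weibull", "normal", "lognormal", "loglogistic",
        "binomial", "betabinomial",
    ])
    if family == "exponential":
        return FamilySpec(family, {"lam": rng.uniform(0.2, 3.0)})
    if family == "weibull":
        return FamilySpec(family, {"shape": rng.uniform(0.5, 3.0),
                                   "scale": rng.uniform(0.5, 3.0)})
    if family == "normal":
        return FamilySpec(family, {"mu": rng.uniform(-2, 2),
                                   "sigma": rng.uniform(0.3, 2.0)})
    if family == "lognormal":
        return FamilySpec(family, {"mu": rng.uniform(-1, 1),
                                   "sigma": rng.uniform(0.3, 1.5)})
    if family == "loglogistic":
        return FamilySpec(family, {"shape": rng.uniform(0.8, 4.0),
                                   "scale": rng.uniform(0.5, 3.0)})
    n = int(rng.integers(5, 40))
    if family == "binomial":
        return FamilySpec(family, {"n": n, "p": rng.uniform(0.15, 0.85)})
    return FamilySpec(family, {"n": n, "a": rng.uniform(0.5, 5.0),
                               "b": rng.uniform(0.5, 5.0)})


def random_value_in_bulk(spec: FamilySpec, rng: np.random.Generator) -> float:
    """A point in the central part of the support (quantiles 10-90%)."""
    q = rng.uniform(0.1, 0.9)
    return float(spec._frozen().ppf(q))


@pytest.fixture
def rng():
    return np.random.default_rng(20220323)
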