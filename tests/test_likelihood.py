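import numpy as np
import pytest

from censdev.distributions import FamilySpec
from censdev.likelihood import (
    ValidationError,
    augmented_log_likelihood,
    bernoulli_augment,
    deviance,
    exact_log_likelihood,
    interval_censored,
    left_censored,
    observed,
    partition_blocks,
    per_observation_log_likelihood,
    right_censored,
)

from conftest import random_family, random_value_in_bulk

EXP1 = FamilySpec("exponential", {"lam": 1.0})
EXP05 = FamilySpec("exponential", {"lam": 0.5})
STDNORM = FamilySpec("normal", {"mu": 0.0, "sigma": 1.0})


def random_dataset(rng, n_max=8):
    """A random mixed-censoring dataset with matched family specs."""
    n = int(rng.integers(1, n_max + 1))
    records, specs = [], []
    for _ in range(n):
        spec = random_family(rng)
        kind = rng.choice(["observed", "left", "right", "interval"])
        a, b = sorted([random_value_in_bulk(spec, rng),
                       random_value_in_bulk(spec, rng)])
        if spec.is_count and a == b:
            kind = "observed" if kind == "interval" else kind
        if spec.is_count:
            # keep censoring events logically possible under the strict
            # count convention: "count < 0" and "count > n" have
            # probability zero and are not valid censored observations
            b = max(b, 1.0)
            a = min(a, spec.params["n"] - 1)
        if kind == "observed":
            records.append(observed(random_value_in_bulk(spec, rng)))
        elif kind == "left":
            records.append(left_censored(b))
        elif kind == "right":
            records.append(right_censored(a))
        else:
            records.append(interval_censored(a, b))
        specs.append(spec)
    return partition_blocks(records), specs


# ---------------------------------------------------------------------------
# records and blocks

def test_partition_all_observed():
    ds = partition_blocks([observed(v) for v in (1.0, 2.0, 3.0)])
    assert ds.block_O == (0, 1, 2) and ds.block_C == () and ds.block_I == ()


def test_partition_mixed_blocks():
    ds = partition_blocks([left_censored(1.0), right_censored(2.0),
                           interval_censored(0.5, 1.5)])
    assert ds.block_C == (0, 1)
    assert ds.block_I == (2,)


def test_blocks_partition_indices(rng):
    for _ in range(25):
        ds, _ = random_dataset(rng)
        all_idx = sorted(ds.block_O + ds.block_C + ds.block_I)
        assert all_idx == list(range(len(ds)))


@pytest.mark.parametrize("bad", [
    dict(status="interval", lower=2.0, upper=1.0),
    dict(status="interval", lower=1.0, upper=1.0),   # degenerate interval
    dict(status="observed", value=None),
    dict(status="left", upper=None),
    dict(status="right", lower=None),
    dict(status="observed", value=1.0, lower=0.5),
])
def test_invalid_records_raise(bad):
    from censdev.likelihood import CensoredObservation
    with pytest.raises(ValidationError):
        CensoredObservation(**bad)


# ---------------------------------------------------------------------------
# exact likelihood

def test_empty_dataset_likelihood_zero():
    ds = partition_blocks([])
    assert exact_log_likelihood(ds, []) == 0.0
    assert deviance(ds, []) == (0.0, 0.0, 0.0)


def test_two_record_exponential_dataset():
    ds = partition_blocks([observed(1.0), right_censored(2.0)])
    ll = exact_log_likelihood(ds, [EXP1, EXP05])
    assert ll == pytest.approx(-2.0, abs=1e-12)
    total, obs, cen = deviance(ds, [EXP1, EXP05])
    assert (total, obs, cen) == pytest.approx((4.0, 2.0, 2.0), abs=1e-10)


def test_normal_interval_probability():
    ds = partition_blocks([interval_censored(-1.0, 1.0)])
    expected = np.log(0.6826894921370859)
    assert exact_log_likelihood(ds, [STDNORM]) == pytest.approx(expected,
                                                                abs=1e-9)


def test_count_strict_left_censoring_uses_cutoff_minus_one():
    spec = FamilySpec("binomial", {"n": 20, "p": 0.2})
    ds = partition_blocks([left_censored(3)])
    from censdev.distributions import log_cdf
    assert exact_log_likelihood(ds, [spec]) == pytest.approx(
        log_cdf(spec, 2), abs=1e-12)
    assert exact_log_likelihood(ds, [spec], count_strict=False) == pytest.approx(
        log_cdf(spec, 3), abs=1e-12)


def test_interval_term_bounded_by_one_sided_terms(rng):
    from censdev.distributions import log_cdf, log_survival
    for _ in range(40):
        spec = random_family(rng)
        a, b = sorted([random_value_in_bulk(spec, rng),
                       random_value_in_bulk(spec, rng)])
        if a >= b:
            continue
        ds = partition_blocks([interval_censored(a, b)])
        term = exact_log_likelihood(ds, [spec])
        assert term <= 1e-12
        assert term <= log_cdf(spec, b) + 1e-9
        assert term <= log_survival(spec, a) + 1e-9


# ---------------------------------------------------------------------------
# augmentation and Proposition-1 equivalence

def test_augment_assigns_indicators():
    ds = partition_blocks([right_censored(2.0), left_censored(1.0),
                           interval_censored(0.0, 1.0)])
    aug = bernoulli_augment(ds)
    assert aug.z1 == {0: 0, 1: 1}
    assert aug.z2 == {2: 1}
    assert aug.base is ds


def test_augmented_equals_exact_on_observed_data():
    ds = partition_blocks([observed(0.7), observed(2.2)])
    specs = [EXP1, EXP05]
    assert augmented_log_likelihood(bernoulli_augment(ds), specs) == \
        pytest.approx(exact_log_likelihood(ds, specs), abs=1e-12)


def test_right_censored_bernoulli_term():
    ds = partition_blocks([right_censored(2.0)])
    assert augmented_log_likelihood(bernoulli_augment(ds), [EXP05]) == \
        pytest.approx(-1.0, abs=1e-10)


def test_likelihood_equivalence_random_datasets(rng):
    """The indicator formulation and the exact censored likelihood agree on
    random mixed-censoring datasets across every family."""
    for _ in range(200):
        ds, specs = random_dataset(rng)
        exact = exact_log_likelihood(ds, specs)
        aug = augmented_log_likelihood(bernoulli_augment(ds), specs)
        assert abs(aug - exact) < 1e-10


def test_deviance_decomposition(rng):
    for _ in range(30):
        ds, specs = random_dataset(rng)
        total, obs, cen = deviance(ds, specs)
        assert total == pytest.approx(-2 * exact_log_likelihood(ds, specs),
                                      abs=1e-10)
        assert total == pytest.approx(obs + cen, abs=1e-10)
        terms = per_observation_log_likelihood(ds, specs)
        assert total == pytest.approx(-2 * terms.sum(), abs=1e-10)


def test_spec_count_mismatch_raises():
    ds = partition_blocks([observed(1.0)])
    with pytest.raises(ValueError):
        exact_log_likelihood(ds, [EXP1, EXP1])


def test_impossible_count_censoring_rejected():
    """Probability-zero count censoring events are data errors, not -inf
    likelihood values: 'count < 0' and 'count > n' are rejected."""
    spec = FamilySpec("binomial", {"n": 20, "p": 0.2})
    with pytest.raises(ValidationError):
        exact_log_likelihood(partition_blocks([left_censored(0)]), [spec])
    with pytest.raises(ValidationError):
        exact_log_likelihood(partition_blocks([right_censored(20)]), [spec])
    with pytest.raises(ValidationError):
        exact_log_likelihood(partition_blocks([interval_censored(20, 25)]),
                             [spec])
    with pytest.raises(ValidationError):
        augmented_log_likelihood(
            bernoulli_augment(partition_blocks([left_censored(0)])), [spec])
    # non-strict reading: "count <= 0" is possible and stays allowed
    assert np.isfinite(exact_log_likelihood(
        partition_blocks([left_censored(0)]), [spec], count_strict=False))
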