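"""Exact censored-data likelihood and its Bernoulli-indicator augmentation.

A censored outcome contributes a probability, not a density, to the
likelihood: F(u) for a value known only to lie below ``u``, the survivor
S(l) = 1 - F(l) for a value known only to exceed ``l``, and F(u) - F(l) for
a value confined to a semi-closed interval (l, u].  This module provides

* :func:`exact_log_likelihood` — the textbook censored log-likelihood,
  evaluated with dedicated log-space tail forms;
* :func:`bernoulli_augment` / :func:`augmented_log_likelihood` — the
  indicator-variable formulation in which each one-sided censored record
  carries a *fixed* Bernoulli outcome Z1 (1 = left-censored, 0 =
  right-censored) with success probability p = F(cutoff), and each interval
  record carries Z2 = 1 with success probability F(u) - F(l).  The two
  formulations have identical likelihoods; the augmented route is evaluated
  on the probability scale (as a general-purpose sampler's Bernoulli node
  would evaluate it) so the identity is a genuine cross-check, accurate to
  the ``PROB_CLIP`` floor;
* :func:`deviance` — -2 x log-likelihood split into observed and censored
  parts, the quantity a per-observation deviance monitor accumulates.

Count outcomes need a convention for a strict cutoff: "censored below c"
read strictly means Y < c, i.e. P(Y <= c - 1).  The default is strict
(matching adverse-event tables where only counts *exceeding* the cutoff are
reported); continuous families are insensitive to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distributions import (
    PROB_CLIP,
    FamilySpec,
    SupportError,
    log_cdf,
    log_density,
    log_survival,
)

__all__ = [
    "CensoredObservation",
    "CensoredDataset",
    "AugmentedDataset",
    "ValidationError",
    "observed",
    "left_censored",
    "right_censored",
    "interval_censored",
    "partition_blocks",
    "bernoulli_augment",
    "exact_log_likelihood",
    "augmented_log_likelihood",
    "per_observation_log_likelihood",
    "deviance",
]

STATUSES = ("observed", "left", "right", "interval")


class ValidationError(ValueError):
    """A record violates the censored-observation invariants."""


@dataclass(frozen=True)
class CensoredObservation:
    """One outcome with its censoring status.

    ``value`` is present iff ``status == "observed"``.  ``upper`` is the
    cutoff for left- and interval-censoring, ``lower`` for right- and
    interval-censoring (so an interval record satisfies lower < upper and
    the outcome lies in (lower, upper]).
    """

    status: str
    value: float | None = None
    lower: float | None = None
    upper: float | None = None
    covariates: tuple = ()

    def __post_init__(self) -> None:
        s = self.status
        if s not in STATUSES:
            raise ValidationError(f"unknown status {s!r}")
        if s == "observed":
            if self.value is None or self.lower is not None or self.upper is not None:
                raise ValidationError("observed record needs a value and no cutoffs")
        elif s == "left":
            if self.upper is None or self.value is not None:
                raise ValidationError("left-censored record needs an upper cutoff only")
        elif s == "right":
            if self.lower is None or self.value is not None:
                raise ValidationError("right-censored record needs a lower cutoff only")
        else:  # interval
            if self.lower is None or self.upper is None or self.value is not None:
                raise ValidationError("interval record needs both cutoffs and no value")
            if not self.lower < self.upper:
                raise ValidationError(
                    f"interval cutoffs must satisfy lower < upper, got "
                    f"({self.lower}, {self.upper})"
                )


def observed(value: float, covariates: tuple = ()) -> CensoredObservation:
    return CensoredObservation("observed", value=value, covariates=covariates)


def left_censored(upper: float, covariates: tuple = ()) -> CensoredObservation:
    return CensoredObservation("left", upper=upper, covariates=covariates)


def right_censored(lower: float, covariates: tuple = ()) -> CensoredObservation:
    return CensoredObservation("right", lower=lower, covariates=covariates)


def interval_censored(lower: float, upper: float,
                      covariates: tuple = ()) -> CensoredObservation:
    return CensoredObservation("interval", lower=lower, upper=upper,
                               covariates=covariates)


@dataclass(frozen=True)
class CensoredDataset:
    """Ordered records partitioned into blocks O (observed), C (one-sided
    censored) and I (interval-censored); the blocks hold 0-based indices into
    ``observations`` in original order."""

    observations: tuple
    block_O: tuple
    block_C: tuple
    block_I: tuple

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_observed(self) -> int:
        return len(self.block_O)

    @property
    def n_censored(self) -> int:
        return len(self.block_C) + len(self.block_I)


@dataclass(frozen=True)
class AugmentedDataset:
    """A dataset plus the fixed censoring indicators: z1[i] for each C-block
    member (1 if left-, 0 if right-censored) and z2[i] = 1 for each I-block
    member."""

    base: CensoredDataset
    z1: dict
    z2: dict


def partition_blocks(records: Iterable[CensoredObservation]) -> CensoredDataset:
    """Partition records into the O / C / I blocks by censoring status."""
    obs = tuple(records)
    for i, r in enumerate(obs):
        if not isinstance(r, CensoredObservation):
            raise ValidationError(f"record {i} is not a CensoredObservation")
    O = tuple(i for i, r in enumerate(obs) if r.status == "observed")
    C = tuple(i for i, r in enumerate(obs) if r.status in ("left", "right"))
    I = tuple(i for i, r in enumerate(obs) if r.status == "interval")
    return CensoredDataset(obs, O, C, I)


def bernoulli_augment(data: CensoredDataset) -> AugmentedDataset:
    """Attach the fixed indicator variables to a dataset."""
    z1 = {i: 1 if data.observations[i].status == "left" else 0
          for i in data.block_C}
    z2 = {i: 1 for i in data.block_I}
    return AugmentedDataset(data, z1, z2)


def _effective_cut(spec: FamilySpec, record: CensoredObservation,
                   count_strict: bool) -> float:
    """Cutoff entering F for a one-sided censored record.

    For count families a strict reading shifts the left cutoff down by one
    (Y < u  <=>  Y <= u - 1); a non-strict reading shifts the right cutoff
    (Y >= l  <=>  Y > l - 1).  Continuous families use the cutoff as given.
    """
    if record.status == "left":
        u = record.upper
        return u - 1 if (spec.is_count and count_strict) else u
    l = record.lower
    return l - 1 if (spec.is_count and not count_strict) else l


def _check_count_event_possible(spec: FamilySpec, record: CensoredObservation,
                                count_strict: bool) -> None:
    """Reject censoring events with probability zero under a count family.

    "count < 0" or "count > n" carry no information compatible with the
    model and signal a data error, not a likelihood value of -inf.
    """
    if not spec.is_count:
        return
    n = spec.params["n"]
    s = record.status
    if s == "left" and _effective_cut(spec, record, count_strict) < 0:
        raise ValidationError(
            f"left-censored count below {record.upper} is an impossible "
            "event (no nonnegative count satisfies it)")
    if s == "right" and _effective_cut(spec, record, count_strict) >= n:
        raise ValidationError(
            f"right-censored count above {record.lower} is an impossible "
            f"event for a count family with n={n}")
    if s == "interval" and (record.lower >= n or record.upper < 0):
        raise ValidationError(
            f"interval ({record.lower}, {record.upper}] contains no "
            f"support point of a count family with n={n}")


def _one_term_log(spec: FamilySpec, record: CensoredObservation,
                  count_strict: bool) -> float:
    """Exact log-likelihood contribution of a single record (log space)."""
    s = record.status
    _check_count_event_possible(spec, record, count_strict)
    if s == "observed":
        return log_density(spec, record.value)
    if s == "left":
        return log_cdf(spec, _effective_cut(spec, record, count_strict))
    if s == "right":
        return log_survival(spec, _effective_cut(spec, record, count_strict))
    # interval (l, u]: log(F(u) - F(l)) via a stable log-space difference
    lo = log_cdf(spec, record.lower)
    hi = log_cdf(spec, record.upper)
    if hi <= lo:
        return np.log(PROB_CLIP)
    with np.errstate(invalid="ignore"):
        diff = hi + np.log1p(-np.exp(lo - hi))
    return float(max(diff, np.log(PROB_CLIP)))


def _resolve_specs(data: CensoredDataset,
                   specs: Sequence[FamilySpec]) -> Sequence[FamilySpec]:
    if len(specs) != len(data):
        raise ValueError(
            f"need one FamilySpec per observation: {len(specs)} != {len(data)}"
        )
    return specs


def per_observation_log_likelihood(
    data: CensoredDataset,
    specs: Sequence[FamilySpec],
    count_strict: bool = True,
) -> np.ndarray:
    """Exact log-likelihood term of every record, in dataset order."""
    specs = _resolve_specs(data, specs)
    return np.array(
        [_one_term_log(s, r, count_strict)
         for s, r in zip(specs, data.observations)]
    )


def exact_log_likelihood(
    data: CensoredDataset,
    specs: Sequence[FamilySpec],
    count_strict: bool = True,
) -> float:
    """Sum of density terms (block O), survivor/CDF terms (block C) and
    interval-probability terms (block I)."""
    if len(data) == 0:
        return 0.0
    return float(per_observation_log_likelihood(data, specs, count_strict).sum())


def augmented_log_likelihood(
    aug: AugmentedDataset,
    specs: Sequence[FamilySpec],
    count_strict: bool = True,
) -> float:
    """Likelihood of the indicator formulation, evaluated the way a Bernoulli
    node would: success probabilities formed on the probability scale from
    F at the cutoffs, clipped to [PROB_CLIP, 1 - PROB_CLIP], then logged."""
    data = aug.base
    specs = _resolve_specs(data, specs)
    total = 0.0
    for i in data.block_O:
        total += log_density(specs[i], data.observations[i].value)
    for i in data.block_C:
        r = data.observations[i]
        _check_count_event_possible(specs[i], r, count_strict)
        p = np.exp(log_cdf(specs[i], _effective_cut(specs[i], r, count_strict)))
        p = float(np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP))
        z = aug.z1[i]
        total += z * np.log(p) + (1 - z) * np.log1p(-p)
    for i in data.block_I:
        r = data.observations[i]
        _check_count_event_possible(specs[i], r, count_strict)
        p = np.exp(log_cdf(specs[i], r.upper)) - np.exp(log_cdf(specs[i], r.lower))
        p = float(np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP))
        total += aug.z2[i] * np.log(p)
    return float(total)


def deviance(
    data: CensoredDataset,
    specs: Sequence[FamilySpec],
    count_strict: bool = True,
) -> tuple[float, float, float]:
    """(total, observed-part, censored-part) deviance, total = -2 log L.

    The observed part sums over block O only; the censored part over C and I.
    The observed part alone is what a deviance monitor with the wrong focus
    reports when censored records contribute likelihood 1.
    """
    if len(data) == 0:
        return 0.0, 0.0, 0.0
    terms = per_observation_log_likelihood(data, specs, count_strict)
    obs_idx = np.fromiter(data.block_O, dtype=int, count=len(data.block_O))
    d_obs = -2.0 * terms[obs_idx].sum() if len(obs_idx) else 0.0
    total = -2.0 * terms.sum()
    return float(total), float(d_obs), float(total - d_obs)
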