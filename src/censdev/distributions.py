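"""Log-space distribution primitives for censored-outcome models.

Every parametric family used by the censored-likelihood machinery is exposed
through a single :class:`FamilySpec` value plus three evaluators —
:func:`log_density`, :func:`log_cdf` and :func:`log_survival` — all computed
directly in log space so that extreme tail terms (e.g. an exponential
survivor probability of ``exp(-50)``) never round-trip through a probability
that would underflow.

Families
--------
``exponential``
    rate ``lam > 0``; S(y) = exp(-lam * y).
``weibull``
    ``shape k > 0``, ``scale > 0``; S(y) = exp(-(y/scale)**k).
``normal`` / ``lognormal``
    ``mu``, ``sigma > 0`` (for lognormal, parameters of log(Y)).
``loglogistic``
    ``shape > 0``, ``scale > 0``; F(y) = 1 / (1 + (y/scale)**(-shape)).
``binomial``
    ``n`` (size), ``p`` in (0, 1).
``betabinomial``
    ``n``, shapes ``a > 0``, ``b > 0``; CDF by explicit summation of the
    pmf (study-level n is small).

For the count families, ``log_cdf(spec, y)`` is P(Y <= floor(y)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, logsumexp, ndtr, ndtri, expit, logit as _logit

__all__ = [
    "FamilySpec",
    "ParameterError",
    "SupportError",
    "log_density",
    "log_cdf",
    "log_survival",
    "sample",
    "inverse_link",
    "forward_link",
    "LINKS",
    "CONTINUOUS_FAMILIES",
    "COUNT_FAMILIES",
    "PROB_CLIP",
]

#: Probabilities fed to a log on the probability scale are clipped into
#: [PROB_CLIP, 1 - PROB_CLIP] to keep a single degenerate term from
#: poisoning a deviance sum with -inf.
PROB_CLIP = 1e-12

CONTINUOUS_FAMILIES = frozenset(
    {"exponential", "weibull", "normal", "lognormal", "loglogistic"}
)
COUNT_FAMILIES = frozenset({"binomial", "betabinomial"})


class ParameterError(ValueError):
    """A family parameter is outside its domain (e.g. a rate <= 0)."""


class SupportError(ValueError):
    """An outcome value lies outside the family's support."""


@dataclass(frozen=True)
class FamilySpec:
    """A parametric family with fixed parameter values.

    Parameters
    ----------
    family
        One of ``exponential, weibull, normal, lognormal, loglogistic,
        binomial, betabinomial``.
    params
        Mapping of parameter names to values; see the module docstring for
        the names each family expects.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in CONTINUOUS_FAMILIES | COUNT_FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))
        _validate_params(self.family, self.params)

    @property
    def is_count(self) -> bool:
        return self.family in COUNT_FAMILIES

    def _frozen(self):
        return _frozen_dist(self.family, self.params)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _validate_params(family: str, p: Mapping[str, float]) -> None:
    if family == "exponential":
        _require(p.get("lam", -1) > 0, "exponential rate lam must be > 0")
    elif family == "weibull":
        _require(p.get("shape", -1) > 0 and p.get("scale", -1) > 0,
                 "weibull shape and scale must be > 0")
    elif family in ("normal", "lognormal"):
        _require(p.get("sigma", -1) > 0, f"{family} sigma must be > 0")
        _require(np.isfinite(p.get("mu", np.nan)), f"{family} mu must be finite")
    elif family == "loglogistic":
        _require(p.get("shape", -1) > 0 and p.get("scale", -1) > 0,
                 "loglogistic shape and scale must be > 0")
    elif family == "binomial":
        n = p.get("n", -1)
        _require(n == int(n) and n >= 0, "binomial n must be a nonneg integer")
        _require(0 < p.get("p", -1) < 1, "binomial p must lie in (0, 1)")
    elif family == "betabinomial":
        n = p.get("n", -1)
        _require(n == int(n) and n >= 0, "betabinomial n must be a nonneg integer")
        _require(p.get("a", -1) > 0 and p.get("b", -1) > 0,
                 "betabinomial shapes a, b must be > 0")


def _frozen_dist(family: str, p: Mapping[str, float]):
    if family == "exponential":
        return stats.expon(scale=1.0 / p["lam"])
    if family == "weibull":
        return stats.weibull_min(c=p["shape"], scale=p["scale"])
    if family == "normal":
        return stats.norm(loc=p["mu"], scale=p["sigma"])
    if family == "lognormal":
        return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
    if family == "loglogistic":
        return stats.fisk(c=p["shape"], scale=p["scale"])
    if family == "binomial":
        return stats.binom(n=int(p["n"]), p=p["p"])
    if family == "betabinom" or family == "betabinomial":
        return stats.betabinom(n=int(p["n"]), a=p["a"], b=p["b"])
    raise ParameterError(f"unknown family {family!r}")


def _check_support(spec: FamilySpec, y: float) -> None:
    if not np.isfinite(y):
        raise SupportError(f"outcome {y!r} is not finite")
    if spec.family in ("exponential", "weibull", "lognormal", "loglogistic"):
        if y < 0:
            raise SupportError(f"{spec.family} outcome must be >= 0, got {y}")
    elif spec.is_count:
        n = int(spec.params["n"])
        if y != int(y) or not (0 <= y <= n):
            raise SupportError(
                f"{spec.family} outcome must be an integer in [0, {n}], got {y}"
            )


def log_density(spec: FamilySpec, y: float) -> float:
    """Natural log of the density (pdf) or mass (pmf) at ``y``."""
    _check_support(spec, y)
    # closed forms for the hot paths; scipy for the rest
    p = spec.params
    if spec.family == "exponential":
        return float(np.log(p["lam"]) - p["lam"] * y)
    if spec.family == "normal":
        z = (y - p["mu"]) / p["sigma"]
        return float(-0.5 * z * z - 0.5 * np.log(2.0 * np.pi) - np.log(p["sigma"]))
    d = spec._frozen()
    if spec.is_count:
        return float(d.logpmf(int(y)))
    return float(d.logpdf(y))


def log_cdf(spec: FamilySpec, y: float) -> float:
    """log F(y); for count families, log P(Y <= floor(y))."""
    p = spec.params
    if spec.is_count:
        k = int(np.floor(y))
        n = int(p["n"])
        if k < 0:
            return -np.inf
        if k >= n:
            return 0.0
        if spec.family == "betabinomial":
            # explicit log-space summation over 0..k (n is study-sized)
            d = spec._frozen()
            return float(logsumexp(d.logpmf(np.arange(k + 1))))
        return float(spec._frozen().logcdf(k))
    if not np.isfinite(y):
        return 0.0 if y > 0 else -np.inf
    if spec.family == "exponential":
        return float(np.log1p(-np.exp(-p["lam"] * y))) if y > 0 else -np.inf
    if spec.family == "normal":
        return float(log_ndtr((y - p["mu"]) / p["sigma"]))
    return float(spec._frozen().logcdf(y))


def log_survival(spec: FamilySpec, y: float) -> float:
    """log(1 - F(y)), via dedicated stable tail forms (never 1 - exp(logF))."""
    p = spec.params
    if spec.is_count:
        k = int(np.floor(y))
        n = int(p["n"])
        if k < 0:
            return 0.0
        if k >= n:
            return -np.inf
        d = spec._frozen()
        if spec.family == "betabinomial":
            return float(logsumexp(d.logpmf(np.arange(k + 1, n + 1))))
        return float(d.logsf(k))
    if spec.family == "exponential":
        return float(-p["lam"] * y)
    if spec.family == "weibull":
        return float(-((y / p["scale"]) ** p["shape"]))
    if spec.family == "normal":
        return float(log_ndtr(-(y - p["mu"]) / p["sigma"]))
    return float(spec._frozen().logsf(y))


def sample(spec: FamilySpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` variates; used by simulation and Monte-Carlo checks."""
    return spec._frozen().rvs(size=size, random_state=rng)


# ---------------------------------------------------------------------------
# link functions

def _cloglog_inv(x: np.ndarray) -> np.ndarray:
    return -np.expm1(-np.exp(x))


def _cloglog_fwd(p: np.ndarray) -> np.ndarray:
    return np.log(-np.log1p(-p))


LINKS = {
    "logit": (_logit, expit),
    "probit": (ndtri, ndtr),
    "cloglog": (_cloglog_fwd, _cloglog_inv),
    "identity": (lambda p: p, lambda x: x),
}


def inverse_link(link: str, x):
    """Map the real line to a probability; clipped away from exact 0/1.

    ``logit``: 1/(1+e^-x); ``probit``: standard-normal CDF; ``cloglog``:
    1 - exp(-exp(x)); ``identity`` passes through (then clips).
    """
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}")
    x = np.asarray(x, dtype=float)
    p = LINKS[link][1](x)
    out = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(out) if out.ndim == 0 else out


def forward_link(link: str, p):
    """Map a probability in (0,1) to the real line (inverse of inverse_link)."""
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}")
    p = np.asarray(p, dtype=float)
    out = LINKS[link][0](np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP))
    return float(out) if out.ndim == 0 else out
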