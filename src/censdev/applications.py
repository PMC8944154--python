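"""Preset models: exponential survival regression and censored-binomial
adverse-event meta-analysis.

Survival preset
---------------
Event times follow an exponential distribution with hazard
``lambda_i = exp(beta0 + beta1 * x_i)`` for a binary covariate ``x_i``
(``beta0`` is the log baseline hazard, ``beta1`` the log hazard ratio).
An observed death at ``t`` contributes ``log(lambda) - lambda * t``; a
right-censored time contributes the log survivor ``-lambda * t``.  The fit
reports both the correct posterior mean deviance (observed + censored
parts) and the wrong-focus observed-only mean for comparison.

Adverse-event (AE) preset
-------------------------
Study-level binomial counts of a rare AE; studies whose count did not
exceed a study-specific reporting cutoff appear with the count left-censored
below that cutoff, contributing ``P(Y <= cutoff - 1)``.  Seven model
structures are provided:

=====  =====================================================================
A      one incidence shared by all studies (complete pooling), Beta prior
B      one incidence per target group (PD-1 vs PD-L1 inhibitors)
C      one incidence per drug, Beta priors on the probability scale
D/E/F  drug effects as random deviations on the logit / cloglog / probit
       scale, half-Cauchy prior on the effect standard deviation
G      one incidence per study (no pooling), Beta(a, b) with uniform
       hyperpriors on the shapes
=====  =====================================================================
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .distributions import PROB_CLIP, FamilySpec, inverse_link
from .likelihood import (
    CensoredDataset,
    ValidationError,
    left_censored,
    observed,
    partition_blocks,
    right_censored,
)
from .sampler import (
    McmcConfig,
    PosteriorSamples,
    Prior,
    beta_prior,
    flat_prior,
    half_cauchy_prior,
    normal_prior,
    run_mcmc,
    uniform_prior,
)
from .selection import ModelFit, compute_dic, compute_ped, monitor_deviance

__all__ = [
    "SurvivalRecord",
    "AeStudyRecord",
    "DRUG_GROUPS",
    "AE_MODELS",
    "fit_exponential_survival",
    "fit_ae_model",
    "read_survival_csv",
    "read_ae_csv",
    "write_survival_csv",
    "write_ae_csv",
    "load_aml",
    "survival_to_dataset",
    "ae_to_dataset",
]


# ---------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up ``time`` (weeks), ``event`` (1 = observed
    death, 0 = right-censored) and binary covariate ``maintained``."""

    time: float
    event: int
    maintained: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"time must be > 0, got {self.time}")
        if self.event not in (0, 1) or self.maintained not in (0, 1):
            raise ValidationError("event and maintained must be 0/1")


#: PD-1 inhibitors target the receptor, PD-L1 inhibitors its ligand.
DRUG_GROUPS = {
    "nivolumab": "PD-1",
    "pembrolizumab": "PD-1",
    "atezolizumab": "PD-L1",
    "avelumab": "PD-L1",
    "durvalumab": "PD-L1",
}

AE_MODELS = ("A", "B", "C", "D", "E", "F", "G")
_LINK_FOR_MODEL = {"D": "logit", "E": "cloglog", "F": "probit"}


@dataclass(frozen=True)
class AeStudyRecord:
    """One study arm: ``n`` treated, AE ``count`` if reported, or
    ``censored=1`` with the study's reporting ``cutoff`` (the count is then
    known only to be below the cutoff)."""

    study: str
    drug: str
    n: int
    count: int | None = None
    censored: int = 0
    cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.drug.lower() not in DRUG_GROUPS:
            raise ValidationError(f"unknown drug {self.drug!r}")
        if self.n <= 0:
            raise ValidationError("n treated must be positive")
        if self.censored:
            if self.count is not None:
                raise ValidationError("censored study must not carry a count")
            if self.cutoff is None or not 1 <= self.cutoff <= self.n:
                raise ValidationError("censored study needs 1 <= cutoff <= n")
        else:
            if self.count is None or not 0 <= self.count <= self.n:
                raise ValidationError("reported study needs 0 <= count <= n")

    @property
    def group(self) -> str:
        return DRUG_GROUPS[self.drug.lower()]


# ---------------------------------------------------------------------------
# conversions to the generic censored-dataset representation

def survival_to_dataset(records: Sequence[SurvivalRecord]) -> CensoredDataset:
    """Observed deaths become observed values, censored follow-up becomes
    right-censoring at the last seen time."""
    obs = [observed(r.time, (r.maintained,)) if r.event
           else right_censored(r.time, (r.maintained,)) for r in records]
    return partition_blocks(obs)


def ae_to_dataset(records: Sequence[AeStudyRecord]) -> CensoredDataset:
    """Reported counts become observed values; censored studies become
    left-censored below their cutoff (count < cutoff, strict)."""
    obs = [left_censored(r.cutoff) if r.censored else observed(r.count)
           for r in records]
    return partition_blocks(obs)


def _fingerprint(records) -> str:
    return hashlib.sha256(repr(tuple(records)).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# survival fit

@dataclass(frozen=True)
class SurvivalFit:
    """An exponential survival regression fit with its deviance diagnostics."""

    fit: ModelFit
    mean_deviance: float
    mean_deviance_observed_only: float
    mean_deviance_censored_part: float

    @property
    def samples(self) -> PosteriorSamples:
        return self.fit.samples


def fit_exponential_survival(
    records: Sequence[SurvivalRecord],
    priors: Sequence[tuple[str, Prior]] | None = None,
    config: McmcConfig = McmcConfig(),
    popt_estimator: str = "asymptotic",
) -> SurvivalFit:
    """Fit the exponential regression and monitor the exact deviance.

    Requires at least one observed event; all-censored data still define a
    valid likelihood but the fit is prior-driven (warned, not refused).
    """
    records = list(records)
    t = np.array([r.time for r in records])
    d = np.array([r.event for r in records], dtype=float)
    x = np.array([r.maintained for r in records], dtype=float)
    if d.sum() == 0:
        warnings.warn("no observed events; posterior is prior-dominated",
                      stacklevel=2)

    if priors is None:
        priors = [("beta0", normal_prior(0.0, 100.0)),
                  ("beta1", normal_prior(0.0, 100.0))]

    def per_obs(theta: np.ndarray) -> np.ndarray:
        eta = theta[0] + theta[1] * x
        return d * eta - np.exp(eta) * t

    def loglik(theta: np.ndarray) -> float:
        return float(per_obs(theta).sum())

    samples = run_mcmc(loglik, priors, config)
    dev = monitor_deviance(samples, per_obs, d.astype(bool))
    dbar, p_d, dic = compute_dic(dev, samples, per_obs)
    p_opt, ped, label = compute_ped(dev, samples, per_obs, popt_estimator)
    fit = ModelFit("exponential-survival", samples, dev, dbar, p_d, dic,
                   p_opt, ped, "plugin", label, _fingerprint(records))
    return SurvivalFit(
        fit,
        mean_deviance=dbar,
        mean_deviance_observed_only=float(dev.observed_part().mean()),
        mean_deviance_censored_part=float(dev.censored_part().mean()),
    )


# ---------------------------------------------------------------------------
# AE meta-analysis fits

def _binom_logpmf_terms(y, n, p):
    coef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    p = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
    return coef + y * np.log(p) + (n - y) * np.log1p(-p)


def _ae_arrays(records: Sequence[AeStudyRecord]):
    n = np.array([r.n for r in records], dtype=float)
    cen = np.array([bool(r.censored) for r in records])
    y = np.array([0 if r.censored else r.count for r in records], dtype=float)
    cut = np.array([r.cutoff if r.censored else 0 for r in records], dtype=float)
    return n, cen, y, cut


def _ae_per_obs_factory(records: Sequence[AeStudyRecord], p_of_theta):
    """Per-study exact log-likelihood terms as a function of theta.

    Reported studies use the binomial pmf; censored studies the binomial
    CDF at cutoff - 1 (strict 'count below cutoff').
    """
    n, cen, y, cut = _ae_arrays(records)
    rep = ~cen
    coef = gammaln(n[rep] + 1) - gammaln(y[rep] + 1) - gammaln(n[rep] - y[rep] + 1)

    def per_obs(theta: np.ndarray) -> np.ndarray:
        p = np.clip(p_of_theta(theta), PROB_CLIP, 1 - PROB_CLIP)
        out = np.empty(len(n))
        out[rep] = coef + y[rep] * np.log(p[rep]) \
            + (n[rep] - y[rep]) * np.log1p(-p[rep])
        if cen.any():
            with np.errstate(divide="ignore"):
                lc = stats.binom.logcdf(cut[cen] - 1, n[cen], p[cen])
            out[cen] = np.maximum(lc, np.log(PROB_CLIP))
        return out

    return per_obs


def _ae_model_structure(model: str, records: Sequence[AeStudyRecord],
                        half_cauchy_scale: float,
                        beta_shape: tuple[float, float]):
    """Return (priors, p_of_theta, extra_log_prior, init, per_coord_prior)
    for one model; ``per_coord_prior`` (model G only) gives each study-level
    probability's own conditional prior term for the sampler's vectorised
    independent-block update."""
    model = model.upper()
    K = len(records)
    a0, b0 = beta_shape
    groups = np.array([r.group == "PD-1" for r in records])
    drug_names = sorted({r.drug.lower() for r in records})
    drug_idx = np.array([drug_names.index(r.drug.lower()) for r in records])

    if model == "A":
        priors = [("p", beta_prior(a0, b0))]
        return priors, lambda th: np.full(K, th[0]), None, None, None
    if model == "B":
        priors = [("p_PD1", beta_prior(a0, b0)), ("p_PDL1", beta_prior(a0, b0))]
        return priors, lambda th: np.where(groups, th[0], th[1]), None, None, None
    if model == "C":
        priors = [(f"p_{dname}", beta_prior(a0, b0)) for dname in drug_names]
        return priors, lambda th: th[drug_idx], None, None, None
    if model in _LINK_FOR_MODEL:
        link = _LINK_FOR_MODEL[model]
        D = len(drug_names)
        priors = [("mu", normal_prior(0.0, 10.0))]
        priors += [(f"z_{dname}", normal_prior(0.0, 1.0)) for dname in drug_names]
        priors += [("sigma", half_cauchy_prior(half_cauchy_scale))]

        def p_of_theta(th, link=link, D=D):
            eta = th[0] + th[D + 1] * th[1:D + 1]
            return inverse_link(link, eta)[drug_idx]

        return priors, p_of_theta, None, None, None
    if model == "G":
        priors = [("a", uniform_prior(0.01, 100.0)),
                  ("b", uniform_prior(0.01, 100.0))]
        priors += [(f"p_{r.study}", flat_prior("logit")) for r in records]

        def beta_terms(th):
            a, b = th[0], th[1]
            p = th[2:]
            return ((a - 1) * np.log(p) + (b - 1) * np.log1p(-p)
                    + gammaln(a + b) - gammaln(a) - gammaln(b))

        def extra(th):
            return float(beta_terms(th).sum())

        init = np.concatenate([[1.0, 10.0], np.full(K, 0.05)])
        return priors, lambda th: th[2:], extra, init, beta_terms
    raise ValueError(f"unknown AE model {model!r}; choose one of {AE_MODELS}")


def fit_ae_model(
    records: Sequence[AeStudyRecord],
    model: str,
    config: McmcConfig = McmcConfig(),
    popt_estimator: str = "asymptotic",
    half_cauchy_scale: float = 1.0,
    beta_shape: tuple[float, float] = (1.0, 1.0),
) -> ModelFit:
    """Fit one of the AE meta-analysis models A..G.

    ``half_cauchy_scale`` is the prior scale on the drug-effect standard
    deviation (models D-F); ``beta_shape`` the Beta prior shapes used on
    probability-scale incidences (models A-C).
    """
    records = list(records)
    if model.upper() == "G":
        ids = [r.study for r in records]
        if len(set(ids)) != len(ids):
            raise ValidationError("model G needs unique study ids")
    priors, p_of_theta, extra, init, per_coord_prior = _ae_model_structure(
        model, records, half_cauchy_scale, beta_shape)
    per_obs = _ae_per_obs_factory(records, p_of_theta)

    if extra is None:
        def loglik(theta: np.ndarray) -> float:
            return float(per_obs(theta).sum())
    else:
        def loglik(theta: np.ndarray) -> float:
            return float(per_obs(theta).sum()) + extra(theta)

    if per_coord_prior is None:
        indep_block = None
    else:
        # study-level probabilities are conditionally independent given the
        # hyperparameters: each coordinate's own target term is its study's
        # data contribution plus its conditional prior density
        indep_block = (2, lambda th: per_obs(th) + per_coord_prior(th))

    samples = run_mcmc(loglik, priors, config, init=init,
                       indep_block=indep_block)
    cen = np.array([bool(r.censored) for r in records])
    dev = monitor_deviance(samples, per_obs, ~cen)
    dbar, p_d, dic = compute_dic(dev, samples, per_obs)
    p_opt, ped, label = compute_ped(dev, samples, per_obs, popt_estimator)
    return ModelFit(model.upper(), samples, dev, dbar, p_d, dic, p_opt, ped,
                    "plugin", label, _fingerprint(records))


# ---------------------------------------------------------------------------
# CSV interfaces

def read_survival_csv(path) -> list[SurvivalRecord]:
    """Read a table with columns ``time,status,x`` (status 1 = observed,
    0 = right-censored; x = binary covariate)."""
    df = pd.read_csv(path)
    missing = {"time", "status", "x"} - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    extra = set(df.columns) - {"time", "status", "x"}
    if extra:
        warnings.warn(f"ignoring extra columns {sorted(extra)}", stacklevel=2)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SurvivalRecord(float(row["time"]), int(row["status"]),
                                      int(row["x"])))
        except (ValueError, ValidationError) as e:
            raise ValidationError(f"row {i + 1}: {e}") from e
    return out


def write_survival_csv(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame(
        {"time": [r.time for r in records],
         "status": [r.event for r in records],
         "x": [r.maintained for r in records]}
    ).to_csv(path, index=False)


def read_ae_csv(path) -> list[AeStudyRecord]:
    """Read a table with columns ``study,drug,n,count,censored,cutoff``;
    ``count`` must be empty iff ``censored`` is 1 (then ``cutoff`` is the
    study's reporting threshold)."""
    df = pd.read_csv(path)
    missing = {"study", "drug", "n", "count", "censored", "cutoff"} - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            cen = int(row["censored"])
            if cen and not pd.isna(row["count"]):
                raise ValidationError("censored study must not carry a count")
            if not cen and pd.isna(row["count"]):
                raise ValidationError("reported study needs a count")
            out.append(AeStudyRecord(
                study=str(row["study"]),
                drug=str(row["drug"]),
                n=int(row["n"]),
                count=None if cen else int(row["count"]),
                censored=cen,
                cutoff=int(row["cutoff"]) if cen else None,
            ))
        except (ValueError, ValidationError) as e:
            raise ValidationError(f"row {i + 1}: {e}") from e
    return out


def write_ae_csv(records: Sequence[AeStudyRecord], path) -> None:
    pd.DataFrame(
        {"study": [r.study for r in records],
         "drug": [r.drug for r in records],
         "n": [r.n for r in records],
         "count": [r.count if not r.censored else "" for r in records],
         "censored": [r.censored for r in records],
         "cutoff": [r.cutoff if r.censored else "" for r in records]}
    ).to_csv(path, index=False)


def load_aml() -> list[SurvivalRecord]:
    """The classical acute myeloid leukemia maintenance-chemotherapy table:
    23 subjects, 18 observed deaths, 5 right-censored follow-up times, with
    x = 1 for the maintained-chemotherapy arm."""
    from importlib.resources import files

    path = files("censdev.datasets").joinpath("aml.csv")
    with path.open("r") as fh:
        return read_survival_csv(fh)
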