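"""Deviance monitoring and deviance-based model selection.

For a model with parameters theta and data y_1..y_N, the deviance is
D(theta) = -2 sum_i log L_i(theta), where a censored observation's term is
its CDF / survivor / interval probability, never a constant.  From posterior
draws this module computes

* ``Dbar``  — posterior mean deviance;
* ``p_D``   — effective number of parameters, plug-in form
  ``Dbar - D(theta_hat)`` with theta_hat the posterior mean taken on the
  unconstrained scale;
* ``DIC = Dbar + p_D``;
* ``p_opt`` — the optimism penalty of the penalized expected deviance,
  either the asymptotic form ``2 * sum_i p_Di`` or a paired-chain
  importance-sampling estimate of the leave-one-out expected deviance;
* ``PED = Dbar + p_opt``.

It also exposes the *wrong-focus* diagnostic: the per-draw deviance of the
observed block only, which is what a deviance monitor reports when censored
outcomes contribute likelihood 1.  On any dataset with real censoring the
full mean deviance strictly exceeds this observed-only mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples

__all__ = [
    "DevianceSamples",
    "ComparisonReport",
    "monitor_deviance",
    "observed_only_deviance",
    "compute_dic",
    "compute_ped",
    "compare_models",
    "ModelFit",
]


@dataclass(frozen=True)
class DevianceSamples:
    """Per-draw, per-observation deviance.

    ``matrix`` has shape (n_chains, n_draws, N); entry (c, t, i) is -2 times
    observation i's exact log-likelihood term at draw t of chain c.
    ``observed_mask`` marks the observed (uncensored) block.
    """

    matrix: np.ndarray
    observed_mask: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[2]

    def totals(self) -> np.ndarray:
        """Per-draw total deviance, shape (n_chains, n_draws)."""
        return self.matrix.sum(axis=2)

    def observed_part(self) -> np.ndarray:
        return self.matrix[:, :, self.observed_mask].sum(axis=2)

    def censored_part(self) -> np.ndarray:
        return self.matrix[:, :, ~self.observed_mask].sum(axis=2)

    def pooled_matrix(self) -> np.ndarray:
        """(total draws, N) with chains concatenated."""
        c, t, n = self.matrix.shape
        return self.matrix.reshape(c * t, n)


def monitor_deviance(
    samples: PosteriorSamples,
    per_obs_loglik: Callable[[np.ndarray], np.ndarray],
    observed_mask: np.ndarray,
) -> DevianceSamples:
    """Evaluate the per-observation deviance at every saved draw.

    ``per_obs_loglik`` maps a parameter vector (constrained scale, sampler
    order) to the length-N vector of exact log-likelihood terms — censored
    observations contribute their log CDF / survivor / interval terms.
    """
    observed_mask = np.asarray(observed_mask, dtype=bool)
    c, t, _ = samples.draws.shape
    n = observed_mask.size
    out = np.empty((c, t, n))
    for ci in range(c):
        for ti in range(t):
            terms = per_obs_loglik(samples.draws[ci, ti])
            if terms.shape != (n,):
                raise ValueError(
                    f"per_obs_loglik returned shape {terms.shape}, expected ({n},)"
                )
            out[ci, ti] = -2.0 * terms
    return DevianceSamples(out, observed_mask)


def observed_only_deviance(dev: DevianceSamples) -> np.ndarray:
    """Per-draw deviance with every censored column zeroed — the wrong-focus
    number a default censoring-indicator monitor reports.  Diagnostic only;
    never enters a comparison report."""
    return dev.observed_part()


def _per_obs_pd(
    dev: DevianceSamples,
    samples: PosteriorSamples,
    per_obs_loglik: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    theta_hat = samples.plugin_estimate()
    d_hat = -2.0 * per_obs_loglik(theta_hat)
    return dev.pooled_matrix().mean(axis=0) - d_hat


def compute_dic(
    dev: DevianceSamples,
    samples: PosteriorSamples,
    per_obs_loglik: Callable[[np.ndarray], np.ndarray],
) -> tuple[float, float, float]:
    """(Dbar, p_D, DIC) with the plug-in effective number of parameters.

    A negative p_D (a known pathology of the plug-in estimator under
    strong posterior asymmetry) is reported with a warning, never clipped.
    """
    dbar = float(dev.totals().mean())
    p_d = float(_per_obs_pd(dev, samples, per_obs_loglik).sum())
    if p_d < -1e-8:
        warnings.warn(f"plug-in p_D is negative ({p_d:.3f})", stacklevel=2)
    return dbar, p_d, dbar + p_d


def compute_ped(
    dev: DevianceSamples,
    samples: PosteriorSamples,
    per_obs_loglik: Callable[[np.ndarray], np.ndarray],
    estimator: str = "asymptotic",
    min_ess_fraction: float = 0.05,
) -> tuple[float, float, str]:
    """(p_opt, PED, estimator-label).

    ``asymptotic``: p_opt = 2 * sum_i p_Di (the large-sample relation
    between optimism and the effective number of parameters).

    ``importance``: for each unordered chain pair (a, b) and observation i,
    the leave-one-out posterior expectation E_{-i}[d_i] is estimated by
    self-normalised importance sampling over chain a with weights
    w_t = 1 / f_i(y_i | theta_t) = exp(d_i(theta_t) / 2) (the full posterior
    reweighted to the posterior without y_i), and the posterior mean of d_i
    is taken from the *other* chain; p_opt,i is their difference, averaged
    over both orderings of every pair.  Observations whose importance
    weights degenerate (effective sample size below ``min_ess_fraction`` of
    the draws) fall back to the asymptotic 2*p_Di with a warning.
    """
    p_di = _per_obs_pd(dev, samples, per_obs_loglik)
    dbar = float(dev.totals().mean())
    if estimator == "asymptotic":
        p_opt = float(2.0 * p_di.sum())
        return p_opt, dbar + p_opt, "asymptotic"
    if estimator != "importance":
        raise ValueError(f"unknown p_opt estimator {estimator!r}")

    c = dev.matrix.shape[0]
    if c < 2:
        raise ValueError("importance-sampling p_opt needs at least 2 chains")
    n = dev.n_obs
    n_draws = dev.matrix.shape[1]
    contrib = np.zeros(n)
    counts = np.zeros(n)
    n_fallback = 0
    for a in range(c):
        for b in range(c):
            if a == b:
                continue
            da = dev.matrix[a]          # (draws, N) — values + weights chain
            db_mean = dev.matrix[b].mean(axis=0)
            logw = 0.5 * da            # log weights per draw, per obs
            logw = logw - logw.max(axis=0, keepdims=True)
            w = np.exp(logw)
            wsum = w.sum(axis=0)
            ess = wsum**2 / (w**2).sum(axis=0)
            est = (w * da).sum(axis=0) / wsum - db_mean
            bad = ess < min_ess_fraction * n_draws
            est[bad] = 2.0 * p_di[bad]
            n_fallback += int(bad.sum())
            contrib += est
            counts += 1
    if n_fallback:
        warnings.warn(
            f"importance weights degenerate for {n_fallback} observation-pair "
            "estimates; fell back to the asymptotic form there",
            stacklevel=2,
        )
    p_opt = float((contrib / counts).sum())
    return p_opt, dbar + p_opt, "importance"


@dataclass(frozen=True)
class ModelFit:
    """One fitted model, carrying everything a comparison report needs."""

    name: str
    samples: PosteriorSamples
    dev: DevianceSamples
    dbar: float
    p_d: float
    dic: float
    p_opt: float
    ped: float
    p_d_estimator: str = "plugin"
    p_opt_estimator: str = "asymptotic"
    dataset_fingerprint: str = ""
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model selection statistics in a fixed column order
    (Dbar, p_D, DIC, p_opt, PED), with minimum-DIC / minimum-PED flags."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_text(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.2f}"
                                    if isinstance(v, float) else str(v))


def compare_models(fits: Sequence[ModelFit]) -> ComparisonReport:
    """Assemble the comparison table; all fits must be on the same dataset."""
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.dataset_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were made on different datasets")
    rows = []
    for f in fits:
        rows.append({
            "model": f.name,
            "Dbar": f.dbar,
            "p_D": f.p_d,
            "DIC": f.dic,
            "p_opt": f.p_opt,
            "PED": f.ped,
            "p_D_estimator": f.p_d_estimator,
            "p_opt_estimator": f.p_opt_estimator,
        })
    df = pd.DataFrame(rows).set_index("model")
    df["min_DIC"] = df["DIC"] == df["DIC"].min()
    df["min_PED"] = df["PED"] == df["PED"].min()
    return ComparisonReport(df)
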