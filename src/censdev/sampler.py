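"""Adaptive random-walk Metropolis-within-Gibbs posterior sampler.

The models this package targets are small (a handful to ~10^2 parameters),
so a deterministic, dependency-free sampler is preferred over black-box
engines: each parameter is updated in turn with a Gaussian random-walk
proposal whose log step size is adapted by Robbins-Monro during burn-in
(toward a target acceptance rate) and frozen afterwards, which keeps the
post-burn-in chain a valid Markov chain.

Parameters with constrained support are sampled on an unconstrained scale
(log for positive parameters, logit for probabilities / bounded intervals)
with the Jacobian included in the target, so mixing does not degrade near
the boundary and plug-in posterior estimates can be formed on the
unconstrained scale.

Chains are seeded as ``base_seed + chain`` — identical configuration and
seed give bit-identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln as _betaln, expit, logit

__all__ = [
    "Prior",
    "normal_prior",
    "half_cauchy_prior",
    "beta_prior",
    "uniform_prior",
    "flat_prior",
    "McmcConfig",
    "PosteriorSamples",
    "run_mcmc",
    "posterior_summary",
    "kernel_density",
    "split_rhat",
]


# ---------------------------------------------------------------------------
# priors and their unconstrained transforms

@dataclass(frozen=True)
class Prior:
    """A univariate prior with its unconstrained sampling transform.

    ``kind`` is one of ``normal(mean, sd)``, ``half_cauchy(scale)``,
    ``beta(a, b)``, ``uniform(lo, hi)``.  ``transform`` is ``identity``,
    ``log`` or ``logit`` (logit is affinely rescaled for a general
    uniform(lo, hi) support).
    """

    kind: str
    hyper: tuple
    transform: str
    bounds: tuple | None = None

    def log_pdf(self, x: float) -> float:
        """Log prior density on the constrained scale."""
        if self.kind == "flat":
            if self.transform == "logit":
                lo, hi = self._bounds()
                return 0.0 if lo < x < hi else -np.inf
            if self.transform == "log":
                return 0.0 if x > 0 else -np.inf
            return 0.0
        if self.kind == "normal":
            m, s = self.hyper
            return float(stats.norm.logpdf(x, m, s))
        if self.kind == "half_cauchy":
            (s,) = self.hyper
            if x <= 0:
                return -np.inf
            return float(np.log(2.0) + stats.cauchy.logpdf(x, 0.0, s))
        if self.kind == "beta":
            a, b = self.hyper
            return float(stats.beta.logpdf(x, a, b))
        lo, hi = self.hyper
        return -np.log(hi - lo) if lo < x < hi else -np.inf

    def median(self) -> float:
        if self.kind == "normal":
            return self.hyper[0]
        if self.kind == "half_cauchy":
            return self.hyper[0]  # scale * tan(pi/4)
        if self.kind == "beta":
            return float(stats.beta.median(*self.hyper))
        if self.kind == "flat":
            if self.transform == "logit":
                lo, hi = self._bounds()
                return 0.5 * (lo + hi)
            return 1.0 if self.transform == "log" else 0.0
        lo, hi = self.hyper
        return 0.5 * (lo + hi)

    # -- transform machinery (constrained x <-> unconstrained z) ------------
    def to_unconstrained(self, x: float) -> float:
        if self.transform == "identity":
            return float(x)
        if self.transform == "log":
            return float(np.log(x))
        lo, hi = self._bounds()
        return float(logit((x - lo) / (hi - lo)))

    def to_constrained(self, z: float) -> float:
        if self.transform == "identity":
            return float(z)
        if self.transform == "log":
            return float(np.exp(z))
        lo, hi = self._bounds()
        return float(lo + (hi - lo) * expit(z))

    def log_jacobian(self, z: float) -> float:
        """log |dx/dz| at unconstrained value z."""
        if self.transform == "identity":
            return 0.0
        if self.transform == "log":
            return float(z)
        lo, hi = self._bounds()
        # d/dz [lo + (hi-lo) sigmoid(z)] = (hi-lo) sigmoid(z)(1-sigmoid(z))
        s = expit(z)
        return float(np.log(hi - lo) + np.log(s) + np.log1p(-s))

    def _bounds(self) -> tuple:
        if self.bounds is not None:
            return self.bounds
        if self.kind == "beta":
            return 0.0, 1.0
        if self.kind == "uniform":
            return self.hyper
        raise ValueError(f"{self.kind} prior has no bounded support")


def normal_prior(mean: float = 0.0, sd: float = 100.0) -> Prior:
    if sd <= 0:
        raise ValueError("normal prior sd must be > 0")
    return Prior("normal", (float(mean), float(sd)), "identity")


def half_cauchy_prior(scale: float = 1.0) -> Prior:
    if scale <= 0:
        raise ValueError("half-Cauchy scale must be > 0")
    return Prior("half_cauchy", (float(scale),), "log")


def beta_prior(a: float = 1.0, b: float = 1.0) -> Prior:
    if a <= 0 or b <= 0:
        raise ValueError("beta prior shapes must be > 0")
    return Prior("beta", (float(a), float(b)), "logit")


def uniform_prior(lo: float, hi: float) -> Prior:
    if not lo < hi:
        raise ValueError("uniform prior needs lo < hi")
    return Prior("uniform", (float(lo), float(hi)), "logit")


def flat_prior(transform: str = "identity",
               bounds: tuple | None = None) -> Prior:
    """An improper/constant prior used when the actual prior density is
    supplied inside the likelihood callable (hierarchical parameters); the
    transform still controls the sampling scale."""
    if transform == "logit" and bounds is None:
        bounds = (0.0, 1.0)
    return Prior("flat", (), transform, bounds)


# ---------------------------------------------------------------------------
# configuration and sample container

@dataclass(frozen=True)
class McmcConfig:
    """Sampling protocol; the defaults are 3 chains, 30,000 burn-in
    iterations, 10,000 saved draws per chain with thinning by 3."""

    n_chains: int = 3
    n_burnin: int = 30_000
    n_saved: int = 10_000
    thin: int = 3
    base_seed: int = 20220323
    target_acceptance: float = 0.44

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_saved < 1 or self.thin < 1:
            raise ValueError("n_chains, n_saved and thin must be positive")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be nonnegative")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")


@dataclass(frozen=True)
class PosteriorSamples:
    """Draws on the constrained scale, shaped (chain, draw, parameter)."""

    draws: np.ndarray
    names: tuple
    priors: tuple
    config: McmcConfig
    step_sizes: np.ndarray = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def pooled(self, name: str | None = None) -> np.ndarray:
        """All chains concatenated; one column per parameter, or a single
        parameter's vector when ``name`` is given."""
        flat = self.draws.reshape(-1, self.draws.shape[2])
        if name is None:
            return flat
        return flat[:, self.names.index(name)]

    def plugin_estimate(self) -> np.ndarray:
        """Posterior mean taken on the unconstrained scale, mapped back.

        Keeps plug-in deviance estimates invariant to how constrained
        parameters are parameterized.
        """
        flat = self.pooled()
        out = np.empty(flat.shape[1])
        for j, prior in enumerate(self.priors):
            z = np.array([prior.to_unconstrained(x) for x in flat[:, j]])
            out[j] = prior.to_constrained(float(z.mean()))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (chain, iteration, parameter, value)."""
        c, d, p = self.draws.shape
        chains = np.repeat(np.arange(c), d * p)
        iters = np.tile(np.repeat(np.arange(d), p), c)
        params = np.tile(np.array(self.names), c * d)
        return pd.DataFrame({
            "chain": chains,
            "iteration": iters,
            "parameter": params,
            "value": self.draws.reshape(-1),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, config: McmcConfig | None = None) -> "PosteriorSamples":
        df = pd.read_csv(path)
        names = tuple(df.loc[df["chain"] == 0].loc[df["iteration"] == 0, "parameter"])
        c = df["chain"].nunique()
        d = df["iteration"].nunique()
        draws = df["value"].to_numpy().reshape(c, d, len(names))
        cfg = config or McmcConfig(n_chains=c, n_burnin=0, n_saved=d, thin=1)
        return PosteriorSamples(draws, names, tuple([None] * len(names)), cfg)


# ---------------------------------------------------------------------------
# the sampler

class _PriorBundle:
    """Vectorised evaluation of a stack of independent priors.

    Per-coordinate Metropolis evaluates the full prior at every proposal, so
    the prior term must cost O(P) numpy work, not P scipy calls.
    """

    def __init__(self, priors: Sequence[Prior]):
        self.priors = tuple(priors)
        kinds = np.array([p.kind for p in priors])
        self.tr = np.array([p.transform for p in priors])
        self.is_norm = kinds == "normal"
        self.is_hc = kinds == "half_cauchy"
        self.is_beta = kinds == "beta"
        self.is_unif = kinds == "uniform"
        h = lambda m, k: (np.array([p.hyper[k] for p, keep in zip(priors, m)
                                    if keep]) if m.any() else None)
        self.nm, self.ns = h(self.is_norm, 0), h(self.is_norm, 1)
        self.hcs = h(self.is_hc, 0)
        self.ba, self.bb = h(self.is_beta, 0), h(self.is_beta, 1)
        self.ulo, self.uhi = h(self.is_unif, 0), h(self.is_unif, 1)
        self.is_log = self.tr == "log"
        self.is_logit = self.tr == "logit"
        lo = np.zeros(len(self.priors))
        hi = np.ones(len(self.priors))
        for j, p in enumerate(priors):
            if p.transform == "logit":
                lo[j], hi[j] = p._bounds()
        self.lo, self.hi = lo, hi

    def to_constrained(self, z: np.ndarray) -> np.ndarray:
        x = z.copy()
        if self.is_log.any():
            x[self.is_log] = np.exp(z[self.is_log])
        if self.is_logit.any():
            m = self.is_logit
            x[m] = self.lo[m] + (self.hi[m] - self.lo[m]) * expit(z[m])
        return x

    def to_unconstrained(self, x: np.ndarray) -> np.ndarray:
        z = x.astype(float).copy()
        if self.is_log.any():
            z[self.is_log] = np.log(x[self.is_log])
        if self.is_logit.any():
            m = self.is_logit
            z[m] = logit((x[m] - self.lo[m]) / (self.hi[m] - self.lo[m]))
        return z

    def log_target_terms(self, z: np.ndarray, x: np.ndarray) -> float:
        """Sum of log prior densities (constrained scale) + log Jacobians."""
        total = 0.0
        if self.is_norm.any():
            r = (x[self.is_norm] - self.nm) / self.ns
            total += float(np.sum(-0.5 * r * r - np.log(self.ns)))
        if self.is_hc.any():
            v = x[self.is_hc]
            if np.any(v <= 0):
                return -np.inf
            total += float(np.sum(-np.log1p((v / self.hcs) ** 2) - np.log(self.hcs)))
        if self.is_beta.any():
            v = x[self.is_beta]
            if np.any((v <= 0) | (v >= 1)):
                return -np.inf
            total += float(np.sum((self.ba - 1) * np.log(v)
                                  + (self.bb - 1) * np.log1p(-v)
                                  - _betaln(self.ba, self.bb)))
        if self.is_unif.any():
            v = x[self.is_unif]
            if np.any((v <= self.ulo) | (v >= self.uhi)):
                return -np.inf
            total += float(-np.sum(np.log(self.uhi - self.ulo)))
        # Jacobians
        if self.is_log.any():
            total += float(np.sum(z[self.is_log]))
        if self.is_logit.any():
            m = self.is_logit
            s = expit(z[m])
            total += float(np.sum(np.log(self.hi[m] - self.lo[m])
                                  + np.log(s) + np.log1p(-s)))
        return total

    def jacobian_terms(self, z: np.ndarray, idx: slice) -> np.ndarray:
        """Per-coordinate log |dx/dz| for a contiguous coordinate range."""
        out = np.zeros(z[idx].shape)
        logm = self.is_log[idx]
        if logm.any():
            out[logm] = z[idx][logm]
        lgm = self.is_logit[idx]
        if lgm.any():
            s = expit(z[idx][lgm])
            out[lgm] = (np.log(self.hi[idx][lgm] - self.lo[idx][lgm])
                        + np.log(s) + np.log1p(-s))
        return out


def run_mcmc(
    log_likelihood: Callable[[np.ndarray], float],
    priors: Sequence[tuple],
    config: McmcConfig = McmcConfig(),
    init: np.ndarray | None = None,
    indep_block: tuple[int, Callable[[np.ndarray], np.ndarray]] | None = None,
) -> PosteriorSamples:
    """Sample the posterior of a model built on ``log_likelihood``.

    Parameters
    ----------
    log_likelihood
        Maps a parameter vector (constrained scale, in the order of
        ``priors``) to the log-likelihood.  May return ``-inf``.
    priors
        Sequence of ``(name, Prior)`` pairs, one per parameter.
    config
        Chains / burn-in / thinning protocol and base seed.
    init
        Optional starting point on the constrained scale; defaults to the
        per-parameter prior median.
    indep_block
        Optional ``(start, per_coord_logp)`` declaring that coordinates
        ``start..P-1`` are conditionally independent given the rest (their
        joint conditional factorizes), e.g. unit-level parameters given
        hyperparameters.  ``per_coord_logp(x)`` returns each such
        coordinate's own log-target contribution (its data terms plus its
        conditional prior density, which must be part of
        ``log_likelihood``'s total; transforms are handled by the sampler).
        These coordinates must carry flat declared priors.  They are still
        updated with per-coordinate Metropolis accept/reject, but the whole
        block's proposals are evaluated in one vectorised pass per sweep,
        reducing sweep cost from O(P * N) to O(N).

    Raises
    ------
    ValueError
        If the posterior is not finite at the starting point.
    """
    names = tuple(n for n, _ in priors)
    prs = tuple(p for _, p in priors)
    P = len(prs)
    bundle = _PriorBundle(prs)

    if init is None:
        init = np.array([p.median() for p in prs])
    init = np.asarray(init, dtype=float)
    if init.shape != (P,):
        raise ValueError(f"init must have shape ({P},)")

    def log_target(z: np.ndarray, x: np.ndarray) -> float:
        lp = bundle.log_target_terms(z, x)
        if not np.isfinite(lp):
            return -np.inf
        ll = log_likelihood(x)
        return lp + ll if np.isfinite(ll) else -np.inf

    z0 = bundle.to_unconstrained(init)
    x0 = bundle.to_constrained(z0)
    if not np.isfinite(log_target(z0, x0)):
        raise ValueError("log posterior is not finite at the initial point")

    if indep_block is None:
        n_scalar, block_logp = P, None
    else:
        n_scalar, block_logp = indep_block
        if not 0 <= n_scalar < P:
            raise ValueError("indep_block start must lie in [0, P)")
        if any(p.kind != "flat" for p in prs[n_scalar:]):
            raise ValueError("indep_block coordinates must use flat priors")
    blk = slice(n_scalar, P)

    all_draws = np.empty((config.n_chains, config.n_saved, P))
    all_steps = np.empty((config.n_chains, P))

    for chain in range(config.n_chains):
        rng = np.random.default_rng(config.base_seed + chain)
        z = z0.copy()
        x = x0.copy()
        lt = log_target(z, x)
        log_step = np.zeros(P)

        n_total = config.n_burnin + config.n_saved * config.thin
        saved = 0
        for it in range(n_total):
            adapting = it < config.n_burnin
            # Robbins-Monro gain; decays so adaptation settles before freeze
            gamma = 1.0 / (1.0 + it) ** 0.6 if adapting else 0.0
            noise = rng.standard_normal(P)
            logu = np.log(rng.random(P))
            for j in range(n_scalar):
                zj_old, xj_old = z[j], x[j]
                z[j] = zj_old + np.exp(log_step[j]) * noise[j]
                x[j] = prs[j].to_constrained(z[j])
                lt_new = log_target(z, x)
                log_alpha = lt_new - lt
                if logu[j] < log_alpha:
                    lt = lt_new
                else:
                    z[j], x[j] = zj_old, xj_old
                if adapting:
                    alpha = min(1.0, np.exp(min(log_alpha, 0.0)))
                    log_step[j] += gamma * (alpha - config.target_acceptance)
            if block_logp is not None:
                # one vectorised per-coordinate Metropolis pass over the block
                t_cur = block_logp(x) + bundle.jacobian_terms(z, blk)
                z_new = z.copy()
                z_new[blk] = z[blk] + np.exp(log_step[blk]) * noise[blk]
                x_new = x.copy()
                x_new[blk] = bundle.to_constrained(z_new)[blk]
                t_new = block_logp(x_new) + bundle.jacobian_terms(z_new, blk)
                with np.errstate(invalid="ignore"):
                    delta = t_new - t_cur
                delta = np.where(np.isnan(delta), -np.inf, delta)
                acc = logu[blk] < delta
                zb, xb = z[blk], x[blk]
                zb[acc] = z_new[blk][acc]
                xb[acc] = x_new[blk][acc]
                z[blk], x[blk] = zb, xb
                lt += float(delta[acc].sum())
                if adapting:
                    alpha = np.exp(np.minimum(delta, 0.0))
                    log_step[blk] += gamma * (alpha - config.target_acceptance)
            if not adapting and (it - config.n_burnin) % config.thin == config.thin - 1:
                all_draws[chain, saved] = x
                saved += 1
        all_steps[chain] = np.exp(log_step)

    return PosteriorSamples(all_draws, names, prs, config, all_steps)


# ---------------------------------------------------------------------------
# summaries

def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Constant chains give 1.0.
    """
    c, d = chains.shape
    half = d // 2
    if half < 2:
        return np.nan
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    W = variances.mean()
    if W == 0.0:
        return 1.0
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter mean, sd, 2.5/50/97.5 percentiles, split R-hat and a
    degenerate-chain flag (exactly constant draws)."""
    if samples.n_draws == 0:
        raise ValueError("no draws to summarise")
    rows = []
    for j, name in enumerate(samples.names):
        flat = samples.draws[:, :, j].reshape(-1)
        degenerate = bool(np.all(flat == flat[0]))
        rhat = split_rhat(samples.draws[:, :, j]) if samples.n_chains >= 2 else np.nan
        q = np.percentile(flat, [2.5, 50.0, 97.5])
        rows.append({
            "parameter": name,
            "mean": flat.mean(),
            "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
            "q2.5": q[0],
            "median": q[1],
            "q97.5": q[2],
            "rhat": 1.0 if degenerate else rhat,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows).set_index("parameter")


def kernel_density(
    samples: PosteriorSamples, parameter: str, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density (Silverman bandwidth) of one parameter's
    pooled draws; returns (grid, heights) with unit integral on the grid."""
    x = samples.pooled(parameter)
    if x.size < 100:
        raise ValueError("kernel density needs at least 100 draws")
    if np.all(x == x[0]):
        raise ValueError("draws are constant; density is a degenerate spike")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    return grid, kde(grid)
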