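import numpy as np
import pytest
from scipy import stats

from censdev.sampler import (
    McmcConfig,
    PosteriorSamples,
    beta_prior,
    flat_prior,
    half_cauchy_prior,
    kernel_density,
    normal_prior,
    posterior_summary,
    run_mcmc,
    split_rhat,
    uniform_prior,
)

FAST = McmcConfig(n_chains=3, n_burnin=1500, n_saved=2000, thin=1, base_seed=42)


def _betabinom_loglik(y=3, n=10):
    def loglik(theta):
        p = theta[0]
        return y * np.log(p) + (n - y) * np.log1p(-p)
    return loglik


def test_conjugate_beta_binomial_posterior():
    """With a Beta(1,1) prior and y=3 of n=10, the posterior is Beta(4, 8)."""
    s = run_mcmc(_betabinom_loglik(), [("p", beta_prior(1, 1))], FAST)
    post = stats.beta(4, 8)
    draws = s.pooled("p")
    assert abs(draws.mean() - post.mean()) < 0.01
    assert abs(draws.std() - post.std()) < 0.01


def test_normal_known_variance_conjugate():
    """y_i ~ N(mu, 1), prior mu ~ N(0, tau): posterior is conjugate normal."""
    rng = np.random.default_rng(1)
    y = rng.normal(0.8, 1.0, size=25)
    tau = 2.0

    def loglik(theta):
        return float(-0.5 * np.sum((y - theta[0]) ** 2))

    s = run_mcmc(loglik, [("mu", normal_prior(0.0, tau))], FAST)
    prec = len(y) + 1.0 / tau**2
    post_mean, post_sd = y.sum() / prec, 1.0 / np.sqrt(prec)
    draws = s.pooled("mu")
    assert abs(draws.mean() - post_mean) < 3 * post_sd / np.sqrt(200)
    assert abs(draws.std() - post_sd) < 0.05 * post_sd + 0.01


def test_exponential_mode_matches_mle():
    rng = np.random.default_rng(2)
    t = rng.exponential(1 / 0.7, size=400)

    def loglik(theta):
        return float(len(t) * np.log(theta[0]) - theta[0] * t.sum())

    s = run_mcmc(loglik, [("lam", flat_prior("log"))], FAST)
    mle = len(t) / t.sum()
    # posterior is Gamma(n+... ) — tight at n=400; mean ~ mode here
    assert abs(s.pooled("lam").mean() - mle) / mle < 0.02


def test_same_seed_bit_identical():
    pri = [("p", beta_prior(1, 1))]
    a = run_mcmc(_betabinom_loglik(), pri, FAST)
    b = run_mcmc(_betabinom_loglik(), pri, FAST)
    assert np.array_equal(a.draws, b.draws)


def test_different_chains_differ():
    s = run_mcmc(_betabinom_loglik(), [("p", beta_prior(1, 1))], FAST)
    assert not np.array_equal(s.draws[0], s.draws[1])


def test_nonfinite_at_init_raises():
    def loglik(theta):
        return -np.inf
    with pytest.raises(ValueError):
        run_mcmc(loglik, [("p", beta_prior(1, 1))], FAST)


def test_constrained_draws_in_support():
    def loglik(theta):
        return 0.0
    s = run_mcmc(loglik, [("s", half_cauchy_prior(1.0)),
                          ("u", uniform_prior(-2.0, 3.0))],
                 McmcConfig(3, 500, 500, 1, 7))
    assert np.all(s.pooled("s") > 0)
    u = s.pooled("u")
    assert np.all((u > -2) & (u < 3))


# ---------------------------------------------------------------------------
# summaries

def _fake_samples(draws, names=("x",)):
    draws = np.asarray(draws, dtype=float)
    cfg = McmcConfig(draws.shape[0], 0, draws.shape[1], 1, 0)
    return PosteriorSamples(draws, tuple(names),
                            tuple(normal_prior() for _ in names), cfg)


def test_summary_degenerate_chains_flagged():
    s = _fake_samples(np.full((2, 50, 1), 5.0))
    row = posterior_summary(s).loc["x"]
    assert row["mean"] == 5.0 and row["sd"] == 0.0
    assert row["rhat"] == 1.0 and bool(row["degenerate"])


def test_summary_iid_normal_draws():
    rng = np.random.default_rng(3)
    s = _fake_samples(rng.standard_normal((3, 10_000, 1)))
    row = posterior_summary(s).loc["x"]
    assert abs(row["mean"]) < 0.02
    assert row["q2.5"] <= row["median"] <= row["q97.5"]
    assert row["rhat"] == pytest.approx(1.0, abs=0.01)


def test_rhat_detects_disagreeing_chains():
    rng = np.random.default_rng(4)
    chains = rng.standard_normal((2, 2000))
    chains[1] += 5.0
    assert split_rhat(chains) > 1.5


def test_chain_permutation_invariance():
    rng = np.random.default_rng(5)
    draws = rng.standard_normal((3, 500, 1))
    a = posterior_summary(_fake_samples(draws)).loc["x"]
    b = posterior_summary(_fake_samples(draws[[2, 0, 1]])).loc["x"]
    for col in ("mean", "sd", "q2.5", "median", "q97.5"):
        assert a[col] == pytest.approx(b[col], abs=1e-12)


def test_plugin_estimate_is_mean_on_unconstrained_scale():
    rng = np.random.default_rng(6)
    draws = rng.lognormal(0.0, 1.0, size=(2, 3000, 1))
    cfg = McmcConfig(2, 0, 3000, 1, 0)
    s = PosteriorSamples(draws, ("s",), (half_cauchy_prior(1.0),), cfg)
    expected = np.exp(np.log(draws.reshape(-1)).mean())
    assert s.plugin_estimate()[0] == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# kernel density

def test_kde_normal_mode_near_zero():
    rng = np.random.default_rng(7)
    s = _fake_samples(rng.standard_normal((2, 5000, 1)))
    grid, h = kernel_density(s, "x")
    assert abs(grid[np.argmax(h)]) < 0.1
    assert np.trapezoid(h, grid) == pytest.approx(1.0, abs=1e-3)


def test_kde_rejects_few_or_constant_draws():
    with pytest.raises(ValueError):
        kernel_density(_fake_samples(np.zeros((1, 50, 1))), "x")
    with pytest.raises(ValueError):
        kernel_density(_fake_samples(np.ones((2, 200, 1))), "x")


def test_posterior_csv_round_trip(tmp_path):
    s = run_mcmc(_betabinom_loglik(), [("p", beta_prior(1, 1))],
                 McmcConfig(2, 200, 300, 1, 9))
    path = tmp_path / "post.csv"
    s.to_csv(path)
    back = PosteriorSamples.from_csv(path)
    assert back.names == s.names
    np.testing.assert_allclose(back.draws, s.draws, rtol=0, atol=1e-12)


# ---------------------------------------------------------------------------
# vectorised independent-block updates

def test_indep_block_matches_scalar_path():
    """Coordinates updated through the vectorised block pass draw the same
    random numbers and evaluate the same per-coordinate targets as the
    scalar loop, so the two paths agree draw-for-draw."""
    rng = np.random.default_rng(10)
    n = rng.integers(20, 80, 6)
    y = rng.binomial(n, 0.1)

    def per_coord(p):
        return y * np.log(p) + (n - y) * np.log1p(-p)

    def loglik(p):
        return float(per_coord(p).sum())

    priors = [(f"p{i}", flat_prior("logit")) for i in range(6)]
    cfg = McmcConfig(n_chains=2, n_burnin=800, n_saved=600, thin=1,
                     base_seed=13)
    blocked = run_mcmc(loglik, priors, cfg, indep_block=(0, per_coord))
    scalar = run_mcmc(loglik, priors, cfg)
    np.testing.assert_allclose(blocked.draws, scalar.draws, atol=1e-12)


def test_indep_block_conjugate_posteriors():
    """With fixed Beta(2, 50) conditional priors each coordinate's posterior
    is Beta(2 + y, 50 + n - y); the block sampler recovers every mean to a
    fraction of the posterior sd."""
    rng = np.random.default_rng(11)
    K = 15
    n = rng.integers(50, 300, K)
    y = rng.binomial(n, rng.beta(2, 50, K))

    def per_coord(p):
        return ((y + 1) * np.log(p) + (n - y + 49) * np.log1p(-p))

    priors = [(f"p{i}", flat_prior("logit")) for i in range(K)]
    cfg = McmcConfig(n_chains=2, n_burnin=2500, n_saved=3000, thin=1,
                     base_seed=17)
    s = run_mcmc(lambda p: float(per_coord(p).sum()), priors, cfg,
                 init=np.full(K, 0.05), indep_block=(0, per_coord))
    post = stats.beta(2 + y, 50 + n - y)
    err = (s.pooled().mean(axis=0) - post.mean()) / post.std()
    assert np.abs(err).max() < 0.2


def test_indep_block_requires_flat_priors():
    with pytest.raises(ValueError):
        run_mcmc(lambda p: 0.0, [("a", beta_prior(1, 1)),
                                 ("p", beta_prior(1, 1))],
                 McmcConfig(1, 10, 10, 1, 0),
                 indep_block=(1, lambda p: np.zeros(1)))
    with pytest.raises(ValueError):
        run_mcmc(lambda p: 0.0, [("p", flat_prior("logit"))],
                 McmcConfig(1, 10, 10, 1, 0),
                 indep_block=(1, lambda p: np.zeros(0)))
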