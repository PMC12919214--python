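"""Kernel-level distributional oracles and whole-chain behavior."""

import math

import numpy as np
import pytest
from scipy import stats

from mitosel import (
    CloneTruth,
    GroupData,
    GroupParams,
    MCMCConfig,
    NoiseParam,
    PriorConfig,
    ProposalConfig,
    SimulationSpec,
    mh_step_a,
    mh_step_b,
    run_chain,
    run_mcmc,
    simulate_dataset,
    summarize,
    update_pi,
    update_sigma2,
)
from mitosel.model_core import log_conditional_a

from conftest import random_group


def _grid_cdf(grid, log_density):
    """Normalized CDF of an unnormalized log-density tabulated on a grid."""
    w = np.exp(log_density - log_density.max())
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
    return cdf / cdf[-1]


def _ks_against_grid(draws, grid, log_density):
    cdf = _grid_cdf(grid, log_density)
    ecdf_at = np.searchsorted(np.sort(draws), grid, side="right") / len(draws)
    return float(np.max(np.abs(ecdf_at - cdf)))


class TestUpdatePi:
    def test_long_run_mean_matches_beta_update(self, rng):
        group = GroupData(v=np.zeros(7), n=np.full(7, 0.5), n_total=10, n_zero=3)
        prior = PriorConfig(alpha=2.0, beta=2.0)
        draws = update_pi(group, prior, rng, size=200_000)
        assert np.mean(draws) == pytest.approx(5.0 / 14.0, abs=2e-3)

    def test_all_zero_group_shifts_mass_up(self, rng):
        group = GroupData(v=np.array([]), n=np.array([]), n_total=10, n_zero=10)
        prior = PriorConfig(alpha=2.0, beta=2.0)
        draws = update_pi(group, prior, rng, size=50_000)
        assert np.mean(draws) == pytest.approx(12.0 / 14.0, abs=3e-3)

    def test_draws_match_grid_posterior(self, rng):
        """ECDF of draws vs. the brute-force normalized Bernoulli x Beta posterior."""
        group = GroupData(v=np.zeros(12), n=np.full(12, 0.5), n_total=20, n_zero=8)
        prior = PriorConfig(alpha=2.0, beta=3.0)
        draws = update_pi(group, prior, rng, size=100_000)
        grid = np.linspace(1e-6, 1 - 1e-6, 4001)
        logp = (
            group.n_zero * np.log(grid)
            + (group.n_total - group.n_zero) * np.log1p(-grid)
            + (prior.alpha - 1) * np.log(grid)
            + (prior.beta - 1) * np.log1p(-grid)
        )
        assert _ks_against_grid(draws, grid, logp) < 0.01


class TestUpdateSigma2:
    def test_zero_residuals_reduce_to_prior_scale(self, rng):
        v = np.array([0.2, 0.8, 0.5])
        a, b = 0.4, 0.1
        group = GroupData(v=v, n=a * v + b, n_total=3, n_zero=0)
        prior = PriorConfig(kappa=3.0, theta=2.0)
        params = {"g": GroupParams(0.5, a, b)}
        draws = np.array(
            [update_sigma2({"g": group}, params, prior, rng) for _ in range(50_000)]
        )
        # Inv-Gamma(kappa + 3/2, theta) mean = theta / (kappa + 1/2)
        assert np.mean(draws) == pytest.approx(2.0 / 3.5, rel=0.02)

    def test_no_nonzero_records_falls_back_to_prior(self, rng):
        group = GroupData(v=np.array([]), n=np.array([]), n_total=5, n_zero=5)
        prior = PriorConfig(kappa=4.0, theta=2.0)
        draws = np.array(
            [update_sigma2({"g": group}, {"g": GroupParams(0.5, 0.5, 0.0)}, prior, rng)
             for _ in range(50_000)]
        )
        assert np.mean(draws) == pytest.approx(2.0 / 3.0, rel=0.03)  # theta/(kappa-1)

    def test_draws_match_grid_posterior(self, rng):
        group = random_group(rng, n=15)
        prior = PriorConfig(kappa=2.0, theta=0.5)
        params = {"g": GroupParams(0.3, 0.4, 0.1)}
        draws = np.array(
            [update_sigma2({"g": group}, params, prior, rng) for _ in range(100_000)]
        )
        rss = group.residual_ss(0.4, 0.1)
        k1 = group.n_nonzero
        grid = np.linspace(1e-4, np.percentile(draws, 99.9) * 2, 8001)
        logp = (
            -(k1 / 2) * np.log(grid)
            - rss / (2 * grid)
            - (prior.kappa + 1) * np.log(grid)
            - prior.theta / grid
        )
        assert _ks_against_grid(draws, grid, logp) < 0.01


class TestMHKernels:
    def test_uphill_moves_always_accepted_for_b(self, rng):
        """A proposal with a higher conditional is accepted with probability 1."""

        class DownhillToModeRNG:
            # proposes a fixed step toward the mode; uniform 1.0 would veto
            # any move that needed a coin flip
            def standard_normal(self):
                return -1.0

            def random(self):
                return 1.0 - 1e-12

        group = random_group(rng, n=30)
        prior = PriorConfig()
        noise = NoiseParam(0.05)
        prop = ProposalConfig(step_b=0.05)
        b = 5.0  # far above the mode, so b - 0.05 is always uphill
        for _ in range(20):
            b_new, ok = mh_step_b(b, group, 0.4, noise, prior, prop, DownhillToModeRNG())
            assert ok and b_new == pytest.approx(b - 0.05)
            b = b_new

    def test_degenerate_step_freezes_chain(self, rng):
        group = random_group(rng, n=10)
        prop = ProposalConfig(step_b=1e-300)
        b0 = 0.2
        b, _ = mh_step_b(b0, group, 0.4, NoiseParam(0.1), PriorConfig(), prop, rng)
        assert b == pytest.approx(b0, abs=1e-250)

    @pytest.mark.parametrize("mode,step", [("logit-walk", 0.8), ("beta-independence", 6.0)])
    def test_stationary_law_of_a_matches_grid_conditional(self, mode, step):
        """Long MH run vs. the grid-normalized conditional (KS distance)."""
        rng = np.random.default_rng(11)
        group = random_group(rng, n=20, sigma=0.5)
        prior = PriorConfig(alpha_a=2.0, beta_a=2.0)
        noise = NoiseParam(0.25)
        prop = ProposalConfig(step_a=step, mode_a=mode, adapt=False)
        a = 0.5
        draws = np.empty(200_000)
        for i in range(len(draws)):
            a, _ = mh_step_a(a, group, 0.1, noise, prior, prop, rng)
            draws[i] = a
        grid = np.linspace(1e-4, 1 - 1e-4, 4001)
        logp = np.array(
            [log_conditional_a(x, group, 0.1, noise, prior) for x in grid]
        )
        assert _ks_against_grid(draws[2000:], grid, logp) < 0.02

    def test_stationary_law_of_b_matches_closed_form_gaussian(self):
        """MH for b targets the completion-of-squares Gaussian conditional."""
        rng = np.random.default_rng(12)
        group = random_group(rng, n=20)
        prior = PriorConfig(sigma_b2=0.5)
        a, s2 = 0.4, 0.09
        k1 = group.n_nonzero
        var = 1.0 / (k1 / s2 + 1.0 / prior.sigma_b2)
        mean = var * (group.sum_n - a * group.sum_v) / s2
        prop = ProposalConfig(step_b=2.5 * math.sqrt(var), adapt=False)
        b = mean + 3 * math.sqrt(var)
        draws = np.empty(200_000)
        for i in range(len(draws)):
            b, _ = mh_step_b(b, group, a, NoiseParam(s2), prior, prop, rng)
            draws[i] = b
        kept = draws[2000:]
        assert np.mean(kept) == pytest.approx(mean, abs=4 * math.sqrt(var / 1e4))
        assert np.var(kept) == pytest.approx(var, rel=0.05)


def _three_clone_spec(seed=7, n_cells=90, mpc=60):
    return SimulationSpec(
        n_cells=n_cells,
        clones=(
            CloneTruth(0.3, 0.1, -0.2),
            CloneTruth(0.3, 0.3, 0.0),
            CloneTruth(0.3, 0.9, 0.2),
        ),
        mutations_per_cell=mpc,
        sigma=0.1,
        seed=seed,
    )


class TestChains:
    def test_same_seed_gives_bitwise_identical_chain(self):
        obs, _ = simulate_dataset(_three_clone_spec())
        cfg = MCMCConfig(n_iter=300, burn_in=100, n_chains=1, seed=5)
        r1 = run_chain(obs, PriorConfig(), ProposalConfig(), cfg, chain_seed=42)
        r2 = run_chain(obs, PriorConfig(), ProposalConfig(), cfg, chain_seed=42)
        for k in r1.draws:
            np.testing.assert_array_equal(r1.draws[k], r2.draws[k])
        assert r1.accept == r2.accept

    def test_minimal_retention(self):
        obs, _ = simulate_dataset(_three_clone_spec(n_cells=12, mpc=10))
        cfg = MCMCConfig(n_iter=51, burn_in=50, thin=1, n_chains=1, seed=1)
        r = run_chain(obs, PriorConfig(), ProposalConfig(), cfg, chain_seed=9)
        assert all(len(v) == 1 for v in r.draws.values())

    def test_distinct_chain_seeds_give_distinct_draws(self):
        obs, _ = simulate_dataset(_three_clone_spec(n_cells=12, mpc=10))
        cfg = MCMCConfig(n_iter=200, burn_in=50, n_chains=2, seed=3)
        s = run_mcmc(obs, config=cfg)
        assert s.n_chains == 2
        assert not np.array_equal(s.draws["sigma2"][0], s.draws["sigma2"][1])

    def test_support_preserved_in_all_draws(self):
        obs, _ = simulate_dataset(_three_clone_spec(n_cells=30, mpc=20))
        cfg = MCMCConfig(n_iter=400, burn_in=100, n_chains=2, seed=8,
                         init_mode="prior-draw")
        s = run_mcmc(obs, config=cfg)
        for g in s.group_ids:
            assert np.all((s.draws[f"pi[{g}]"] > 0) & (s.draws[f"pi[{g}]"] < 1))
            assert np.all((s.draws[f"a[{g}]"] > 0) & (s.draws[f"a[{g}]"] < 1))
        assert np.all(s.draws["sigma2"] > 0)

    def test_acceptance_counters_bounded_by_iterations(self):
        obs, _ = simulate_dataset(_three_clone_spec(n_cells=20, mpc=10))
        cfg = MCMCConfig(n_iter=250, burn_in=100, n_chains=1, seed=2)
        s = run_mcmc(obs, config=cfg)
        for counts in s.accept_counts.values():
            assert np.all(counts <= cfg.n_iter)

    def test_recovery_within_three_posterior_sds(self):
        obs, gt = simulate_dataset(_three_clone_spec(n_cells=150, mpc=100, seed=21))
        cfg = MCMCConfig(n_iter=2000, burn_in=600, n_chains=2, seed=13)
        summ = summarize(run_mcmc(obs, config=cfg), obs).table.set_index(
            ["group", "parameter"]
        )
        for _, t in gt.truth_table.iterrows():
            row = summ.loc[(t.group, "a")]
            assert abs(row["mean"] - t.true_a) < 3 * row["sd"] + 1e-3

    def test_sigma2_trace_has_no_linear_trend(self):
        """Post-burn-in variance trace is flat (stable equilibrium)."""
        obs, _ = simulate_dataset(_three_clone_spec(n_cells=100, mpc=60, seed=31))
        cfg = MCMCConfig(n_iter=3000, burn_in=1000, n_chains=1, seed=17)
        s = run_mcmc(obs, config=cfg)
        trace = s.draws["sigma2"][0]
        fit = stats.linregress(np.arange(len(trace)), trace)
        assert fit.pvalue > 0.01


class TestSummarize:
    def test_constant_chain_degenerates_cleanly(self):
        from mitosel.sampler import PosteriorSamples

        x = np.full((2, 50), 0.37)
        s = PosteriorSamples(
            draws={"pi[A]": x, "a[A]": x, "b[A]": x, "sigma2": np.full((2, 50), 0.1)},
            accept_counts={"a[A]": np.array([10.0, 10.0]), "b[A]": np.array([5.0, 5.0])},
            n_proposed=100,
            group_ids=["A"],
            prior=PriorConfig(),
            proposal=ProposalConfig(),
            config=MCMCConfig(n_iter=100, burn_in=50, n_chains=2),
        )
        t = summarize(s).table.set_index(["group", "parameter"]).loc[("A", "a")]
        assert t["mean"] == pytest.approx(0.37)
        assert t["median"] == pytest.approx(0.37)
        assert t["sd"] == pytest.approx(0.0, abs=1e-15)
        assert t["ci_lo"] == pytest.approx(0.37)
        assert t["ci_hi"] == pytest.approx(0.37)

    def test_simple_mean_median(self):
        from mitosel.sampler import PosteriorSamples

        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        inb = np.full((2, 2), 0.5)
        s = PosteriorSamples(
            draws={"pi[A]": inb, "a[A]": inb, "b[A]": x, "sigma2": inb},
            accept_counts={"a[A]": np.array([1.0, 1.0]), "b[A]": np.array([1.0, 1.0])},
            n_proposed=2,
            group_ids=["A"],
            prior=PriorConfig(),
            proposal=ProposalConfig(),
            config=MCMCConfig(n_iter=4, burn_in=2, n_chains=2),
        )
        row = summarize(s).table.set_index(["group", "parameter"]).loc[("A", "b")]
        assert row["mean"] == pytest.approx(2.5)
        assert row["median"] == pytest.approx(2.5)

    def test_ci_ordering_invariant(self):
        obs, _ = simulate_dataset(_three_clone_spec(n_cells=30, mpc=20))
        cfg = MCMCConfig(n_iter=400, burn_in=100, n_chains=2, seed=4)
        t = summarize(run_mcmc(obs, config=cfg), obs).table
        assert (t["ci_lo"] <= t["median"]).all()
        assert (t["median"] <= t["ci_hi"]).all()

    def test_cell_pressure_is_group_posterior_mean(self):
        obs, _ = simulate_dataset(_three_clone_spec(n_cells=12, mpc=10))
        cfg = MCMCConfig(n_iter=300, burn_in=100, n_chains=2, seed=6)
        s = run_mcmc(obs, config=cfg)
        summ = summarize(s, obs)
        mean_a = {g: float(np.mean(s.pooled(f"a[{g}]"))) for g in s.group_ids}
        c2g = obs.cell_to_group()
        for cell, val in summ.cell_pressure.items():
            assert val == pytest.approx(mean_a[c2g[cell]])
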