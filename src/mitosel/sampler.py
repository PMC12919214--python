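"""MH-within-Gibbs sampler for the zero-inflated selection model.

Each sweep updates, for every group (clone): the zero-inflation
probability ``pi`` by its conjugate Beta draw, the selection pressure
``a`` and baseline ``b`` by Metropolis-Hastings, and finally the shared
residual variance ``sigma2`` by its conjugate Inverse-Gamma draw over
all nonzero-score records.  The latent zero indicators are never
sampled: a record sits in the point-mass component iff its score is
exactly zero, so the zero counts entering the Beta update are fixed by
the data.

Proposals for ``a`` default to a Gaussian random walk on logit(a) with
the Jacobian folded into the acceptance ratio (so the chain targets the
conditional on the original (0,1) scale); an independence Beta proposal
with an explicit Hastings correction is available.  ``b`` uses a
symmetric Gaussian random walk.  Both step sizes are adapted
multiplicatively during burn-in toward an acceptance rate of 0.44 and
frozen afterwards, which keeps the post-burn-in kernel a valid,
non-adaptive MH kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .data_io import GLOBAL_GROUP, ObservationSet
from .model_core import (
    GroupData,
    GroupParams,
    NoiseParam,
    PriorConfig,
    log_conditional_a,
    log_conditional_b,
)

__all__ = [
    "ProposalConfig",
    "MCMCConfig",
    "ChainResult",
    "PosteriorSamples",
    "PosteriorSummary",
    "update_pi",
    "update_sigma2",
    "mh_step_a",
    "mh_step_b",
    "run_chain",
    "run_mcmc",
    "summarize",
]

_ADAPT_WINDOW = 50
_STEP_BOUNDS = (1e-4, 50.0)


@dataclass(frozen=True)
class ProposalConfig:
    """MH proposal settings.

    step_a : random-walk scale on the logit scale (logit-walk mode) or the
             Beta concentration (beta-independence mode).
    step_b : s.d. tau of the Gaussian random walk for b.
    mode_a : "logit-walk" (default) or "beta-independence".
    adapt  : tune both steps during burn-in toward ``target_accept``.
    """

    step_a: float = 0.5
    step_b: float = 0.1
    mode_a: str = "logit-walk"
    adapt: bool = True
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.step_a <= 0 or self.step_b <= 0:
            raise ValueError("proposal scales must be strictly positive")
        if self.mode_a not in ("logit-walk", "beta-independence"):
            raise ValueError(f"unknown a-proposal mode {self.mode_a!r}")


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 5000
    burn_in: int = 2000
    thin: int = 1
    n_chains: int = 4
    seed: int = 0
    init_mode: str = "data-driven"  # or "prior-draw"

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_retained < 1:
            raise ValueError("no retained draws: increase n_iter or reduce thinning")
        if self.init_mode not in ("data-driven", "prior-draw"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


# ---------------------------------------------------------------- kernels


def update_pi(
    group: GroupData,
    prior: PriorConfig,
    rng: np.random.Generator,
    size: Optional[int] = None,
):
    """Conjugate Gibbs draw for pi: Beta(alpha + Z, beta + K - Z).

    Z counts the group's exact-zero scores among its K records.
    """
    return rng.beta(
        prior.alpha + group.n_zero,
        prior.beta + (group.n_total - group.n_zero),
        size=size,
    )


def update_sigma2(
    groups: Mapping[str, GroupData],
    all_params: Mapping[str, GroupParams],
    prior: PriorConfig,
    rng: np.random.Generator,
) -> float:
    """Conjugate Gibbs draw for the shared residual variance.

    Inverse-Gamma(kappa + N1/2, theta + RSS/2) where N1 and RSS run over
    the nonzero-score records of every group at the groups' current
    (a, b).  With no nonzero records anywhere this falls back to a prior
    draw.
    """
    n1 = 0
    rss = 0.0
    for gid, gd in groups.items():
        n1 += gd.n_nonzero
        if gd.n_nonzero:
            p = all_params[gid]
            rss += gd.residual_ss(p.a, p.b)
    shape = prior.kappa + 0.5 * n1
    rate = prior.theta + 0.5 * max(rss, 0.0)
    return rate / rng.standard_gamma(shape)


def _logit(x: float) -> float:
    return math.log(x) - math.log1p(-x)


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _mh_a(
    a: float,
    group: GroupData,
    b: float,
    sigma2: float,
    prior: PriorConfig,
    step: float,
    mode: str,
    rng: np.random.Generator,
) -> Tuple[float, bool]:
    noise = NoiseParam(sigma2)
    if mode == "logit-walk":
        theta_new = _logit(a) + step * rng.standard_normal()
        a_new = _expit(theta_new)
        if a_new <= 0.0 or a_new >= 1.0:  # underflow at extreme proposals
            rng.random()  # keep the draw count fixed for reproducibility
            return a, False
        # symmetric walk in logit space; Jacobian a(1-a) maps the target back
        log_ratio = (
            log_conditional_a(a_new, group, b, noise, prior)
            + math.log(a_new) + math.log1p(-a_new)
            - log_conditional_a(a, group, b, noise, prior)
            - math.log(a) - math.log1p(-a)
        )
    else:  # beta-independence: a' ~ Beta(c/2, c/2), c = step
        half = 0.5 * step
        a_new = float(rng.beta(half, half))
        if a_new <= 0.0 or a_new >= 1.0:
            rng.random()
            return a, False
        # Hastings ratio q(a)/q(a'); the Beta normalizer cancels
        log_ratio = (
            log_conditional_a(a_new, group, b, noise, prior)
            - log_conditional_a(a, group, b, noise, prior)
            + (half - 1.0) * (math.log(a) + math.log1p(-a))
            - (half - 1.0) * (math.log(a_new) + math.log1p(-a_new))
        )
    if log_ratio >= 0.0 or math.log(max(rng.random(), 1e-300)) < log_ratio:
        return a_new, True
    return a, False


def _mh_b(
    b: float,
    group: GroupData,
    a: float,
    sigma2: float,
    prior: PriorConfig,
    step: float,
    rng: np.random.Generator,
) -> Tuple[float, bool]:
    noise = NoiseParam(sigma2)
    b_new = b + step * rng.standard_normal()
    log_ratio = log_conditional_b(b_new, group, a, noise, prior) - log_conditional_b(
        b, group, a, noise, prior
    )
    if log_ratio >= 0.0 or math.log(max(rng.random(), 1e-300)) < log_ratio:
        return b_new, True
    return b, False


def mh_step_a(
    current: float,
    group: GroupData,
    b: float,
    noise: NoiseParam,
    prior: PriorConfig,
    proposal: ProposalConfig,
    rng: np.random.Generator,
) -> Tuple[float, bool]:
    """One MH update of the selection pressure; returns (value, accepted)."""
    return _mh_a(current, group, b, noise.sigma2, prior, proposal.step_a, proposal.mode_a, rng)


def mh_step_b(
    current: float,
    group: GroupData,
    a: float,
    noise: NoiseParam,
    prior: PriorConfig,
    proposal: ProposalConfig,
    rng: np.random.Generator,
) -> Tuple[float, bool]:
    """One MH update of the baseline; symmetric Gaussian random walk."""
    return _mh_b(current, group, a, noise.sigma2, prior, proposal.step_b, rng)


# ---------------------------------------------------------------- driver


@dataclass
class ChainResult:
    draws: Dict[str, np.ndarray]          # param name -> retained draws
    accept: Dict[str, int]                # MH kernel name -> accepted count
    n_proposed: int                       # proposals per kernel (= n_iter)
    final_steps: Dict[str, float]         # adapted proposal scales


def _init_state(
    groups: Mapping[str, GroupData],
    prior: PriorConfig,
    init_mode: str,
    rng: np.random.Generator,
) -> Tuple[Dict[str, List[float]], float]:
    """Starting values per group plus sigma2.

    data-driven: pi0 = zero fraction clamped to (0.01, 0.99); (a0, b0) by
    least squares on the nonzero records clamped into support; sigma2_0 =
    residual variance.  prior-draw: independent draws from the priors,
    giving overdispersed starts for convergence diagnostics.
    """
    state: Dict[str, List[float]] = {}
    sigma2 = prior.theta / max(prior.kappa - 1.0, 0.5)  # prior-mean-ish fallback
    if init_mode == "prior-draw":
        for gid in groups:
            pi0 = float(np.clip(rng.beta(prior.alpha, prior.beta), 1e-3, 1 - 1e-3))
            a0 = float(np.clip(rng.beta(prior.alpha_a, prior.beta_a), 1e-3, 1 - 1e-3))
            b0 = float(rng.normal(0.0, math.sqrt(prior.sigma_b2)))
            state[gid] = [pi0, a0, b0]
        sigma2 = float(np.clip(prior.theta / rng.standard_gamma(prior.kappa), 1e-8, 1e8))
        return state, sigma2

    rss_tot, n1_tot = 0.0, 0
    for gid, gd in groups.items():
        pi0 = float(np.clip(gd.n_zero / max(gd.n_total, 1), 0.01, 0.99))
        k1 = gd.n_nonzero
        if k1 >= 2:
            vbar, nbar = gd.sum_v / k1, gd.sum_n / k1
            svv = gd.sum_v2 - k1 * vbar * vbar
            svn = gd.sum_vn - k1 * vbar * nbar
            a0 = svn / svv if svv > 1e-12 else 0.5
            a0 = float(np.clip(a0, 0.01, 0.99))
            b0 = nbar - a0 * vbar
            rss_tot += max(gd.residual_ss(a0, b0), 0.0)
            n1_tot += k1
        else:
            a0 = prior.alpha_a / (prior.alpha_a + prior.beta_a)
            b0 = 0.0
        state[gid] = [pi0, a0, float(b0)]
    if n1_tot >= 2:
        sigma2 = max(rss_tot / n1_tot, 1e-8)
    return state, sigma2


def run_chain(
    obs: ObservationSet,
    prior: PriorConfig,
    proposal: ProposalConfig,
    config: MCMCConfig,
    chain_seed: int,
) -> ChainResult:
    """Run one chain; fully determined by ``chain_seed``."""
    rng = np.random.default_rng(chain_seed)
    groups = obs.group_data_map()
    gids = obs.group_ids
    state, sigma2 = _init_state(groups, prior, config.init_mode, rng)

    steps_a = {g: proposal.step_a for g in gids}
    steps_b = {g: proposal.step_b for g in gids}
    acc_a = {g: 0 for g in gids}
    acc_b = {g: 0 for g in gids}
    win_a = {g: 0 for g in gids}
    win_b = {g: 0 for g in gids}

    n_ret = config.n_retained
    out = {f"pi[{g}]": np.empty(n_ret) for g in gids}
    out.update({f"a[{g}]": np.empty(n_ret) for g in gids})
    out.update({f"b[{g}]": np.empty(n_ret) for g in gids})
    out["sigma2"] = np.empty(n_ret)

    kept = 0
    for it in range(config.n_iter):
        for g in gids:
            gd = groups[g]
            st = state[g]
            st[0] = float(update_pi(gd, prior, rng))
            st[1], ok_a = _mh_a(
                st[1], gd, st[2], sigma2, prior, steps_a[g], proposal.mode_a, rng
            )
            st[2], ok_b = _mh_b(st[2], gd, st[1], sigma2, prior, steps_b[g], rng)
            acc_a[g] += ok_a
            acc_b[g] += ok_b
            win_a[g] += ok_a
            win_b[g] += ok_b
        params = {
            g: GroupParams(pi=state[g][0], a=state[g][1], b=state[g][2]) for g in gids
        }
        sigma2 = update_sigma2(groups, params, prior, rng)

        if proposal.adapt and it < config.burn_in and (it + 1) % _ADAPT_WINDOW == 0:
            for g in gids:
                for steps, win in ((steps_a, win_a), (steps_b, win_b)):
                    rate = win[g] / _ADAPT_WINDOW
                    steps[g] = float(
                        np.clip(
                            steps[g] * math.exp(rate - proposal.target_accept),
                            *_STEP_BOUNDS,
                        )
                    )
                    win[g] = 0

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            for g in gids:
                out[f"pi[{g}]"][kept] = state[g][0]
                out[f"a[{g}]"][kept] = state[g][1]
                out[f"b[{g}]"][kept] = state[g][2]
            out["sigma2"][kept] = sigma2
            kept += 1

    accept = {f"a[{g}]": acc_a[g] for g in gids}
    accept.update({f"b[{g}]": acc_b[g] for g in gids})
    final = {f"a[{g}]": steps_a[g] for g in gids}
    final.update({f"b[{g}]": steps_b[g] for g in gids})
    return ChainResult(
        draws=out, accept=accept, n_proposed=config.n_iter, final_steps=final
    )


@dataclass
class PosteriorSamples:
    """Multi-chain posterior draws plus the configuration that produced them."""

    draws: Dict[str, np.ndarray]               # param -> (n_chains, n_draws)
    accept_counts: Dict[str, np.ndarray]       # kernel -> per-chain accepted
    n_proposed: int
    group_ids: List[str]
    prior: PriorConfig
    proposal: ProposalConfig
    config: MCMCConfig

    @property
    def param_names(self) -> List[str]:
        return list(self.draws.keys())

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def acceptance_rates(self) -> Dict[str, float]:
        return {
            k: float(v.sum()) / (self.n_proposed * len(v))
            for k, v in self.accept_counts.items()
        }


def run_mcmc(
    obs: ObservationSet,
    prior: PriorConfig = PriorConfig(),
    proposal: ProposalConfig = ProposalConfig(),
    config: MCMCConfig = MCMCConfig(),
) -> PosteriorSamples:
    """Run ``config.n_chains`` independent chains with seeds seed, seed+1, ..."""
    chains = [
        run_chain(obs, prior, proposal, config, config.seed + c)
        for c in range(config.n_chains)
    ]
    draws = {
        name: np.stack([c.draws[name] for c in chains]) for name in chains[0].draws
    }
    accept = {
        k: np.array([c.accept[k] for c in chains], dtype=float)
        for k in chains[0].accept
    }
    return PosteriorSamples(
        draws=draws,
        accept_counts=accept,
        n_proposed=config.n_iter,
        group_ids=list(obs.group_ids),
        prior=prior,
        proposal=proposal,
        config=config,
    )


# ---------------------------------------------------------------- summaries


@dataclass
class PosteriorSummary:
    """Pooled-across-chains posterior summaries.

    ``table`` has one row per (group, parameter) with mean, median, sd and
    the central 95% credible interval; the shared variance appears under
    the pseudo-group ``_global_``.  ``cell_pressure`` maps each cell to
    the posterior mean selection pressure of its clone.
    """

    table: pd.DataFrame
    group_ids: List[str]
    cell_pressure: Optional[pd.Series]
    acceptance: Dict[str, float]


def _summary_row(group: str, parameter: str, x: np.ndarray) -> dict:
    lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
    return {
        "group": group,
        "parameter": parameter,
        "mean": float(np.mean(x)),
        "median": float(med),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "ci_lo": float(lo),
        "ci_hi": float(hi),
    }


def summarize(samples: PosteriorSamples, obs: Optional[ObservationSet] = None) -> PosteriorSummary:
    """Posterior mean/median/SD and 95% credible intervals per parameter."""
    if samples.n_draws == 0:
        raise ValueError("cannot summarize empty samples")
    rows = []
    for g in samples.group_ids:
        for p in ("pi", "a", "b"):
            rows.append(_summary_row(g, p, samples.pooled(f"{p}[{g}]")))
    rows.append(_summary_row(GLOBAL_GROUP, "sigma2", samples.pooled("sigma2")))
    table = pd.DataFrame(rows)

    cell_pressure = None
    if obs is not None:
        mean_a = {g: float(np.mean(samples.pooled(f"a[{g}]"))) for g in samples.group_ids}
        c2g = obs.cell_to_group()
        cell_pressure = pd.Series(
            {cell: mean_a[grp] for cell, grp in c2g.items()}, name="selection_pressure"
        )
    return PosteriorSummary(
        table=table,
        group_ids=list(samples.group_ids),
        cell_pressure=cell_pressure,
        acceptance=samples.acceptance_rates(),
    )
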