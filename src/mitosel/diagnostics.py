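"""Convergence and mixing diagnostics: PSRF, ESS, acceptance, traces."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sampler import PosteriorSamples

__all__ = [
    "DiagnosticsReport",
    "psrf",
    "effective_sample_size",
    "acceptance_report",
    "diagnostics_report",
]


def psrf(chains: Sequence[np.ndarray] | np.ndarray, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor.

    With m >= 2 chains of n draws each: W is the mean within-chain
    variance, B/n the variance of the chain means, and

        Vhat = ((n - 1)/n) * W + B/n,     PSRF = sqrt(Vhat / W).

    Values near 1 (conventionally < 1.1) indicate the chains have mixed
    into a common distribution.  ``split=True`` halves every chain first,
    which also catches within-chain drift.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    if split:
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n = arr.shape
    if m < 2:
        raise ValueError("PSRF needs at least 2 chains")
    if n < 2:
        raise ValueError("PSRF needs at least 2 draws per chain")
    w = float(np.mean(np.var(arr, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(arr, axis=1), ddof=1))
    if w == 0.0:
        # identical constant chains: converged by construction
        return 1.0 if b_over_n == 0.0 else np.inf
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based effective sample size of one chain.

    Uses Geyer's initial-monotone-sequence truncation: consecutive
    autocorrelation pairs are summed while positive and forced
    non-increasing, and ESS = n / (1 + 2 * sum rho_k).  The estimate is
    capped at n; a constant chain warns and reports n.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 draws for an ESS estimate")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        warnings.warn("degenerate (constant) chain: ESS reported as n", stacklevel=2)
        return float(n)

    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    rho = acov / acov[0]

    # Geyer pairs: Gamma_t = rho_{2t} + rho_{2t+1}
    n_pairs = n // 2
    gammas = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    tau = -1.0
    running_min = np.inf
    for g in gammas:
        if g <= 0.0:
            break
        running_min = min(running_min, g)
        tau += 2.0 * running_min
    if tau <= 0.0:
        return float(n)
    return float(min(n, n / tau))


def acceptance_report(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-kernel MH acceptance rates (accepted / proposed), pooled over chains."""
    rows = []
    for kernel, rate in samples.acceptance_rates().items():
        param, group = kernel.split("[", 1)
        rows.append({"kernel": param, "group": group.rstrip("]"), "rate": rate})
    return pd.DataFrame(rows)


@dataclass
class DiagnosticsReport:
    table: pd.DataFrame        # parameter, psrf, ess
    acceptance: pd.DataFrame   # kernel, group, rate
    traces: pd.DataFrame       # chain, parameter, mean, slope, slope_p


def diagnostics_report(samples: PosteriorSamples, split: bool = False) -> DiagnosticsReport:
    """PSRF + ESS per parameter, acceptance rates, and per-chain trace summaries.

    ESS is estimated per chain and summed (then capped at the total
    retained draw count).  Trace summaries include the least-squares
    slope of each post-burn-in trace and its p-value: a flat trace
    (large p) is what a converged, well-mixed chain should show.
    """
    total = samples.n_chains * samples.n_draws
    rows, trace_rows = [], []
    multi = samples.n_chains >= 2
    its = np.arange(samples.n_draws, dtype=float)
    for name in samples.param_names:
        arr = samples.draws[name]
        r = psrf(arr, split=split) if multi else np.nan
        ess = min(float(sum(effective_sample_size(c) for c in arr)), float(total))
        rows.append({"parameter": name, "psrf": r, "ess": ess})
        for c in range(samples.n_chains):
            chain = arr[c]
            if np.ptp(chain) == 0.0:
                slope, p = 0.0, 1.0
            else:
                fit = stats.linregress(its, chain)
                slope, p = float(fit.slope), float(fit.pvalue)
            trace_rows.append(
                {
                    "chain": c,
                    "parameter": name,
                    "mean": float(chain.mean()),
                    "slope": slope,
                    "slope_p": p,
                }
            )
    return DiagnosticsReport(
        table=pd.DataFrame(rows),
        acceptance=acceptance_report(samples),
        traces=pd.DataFrame(trace_rows),
    )
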