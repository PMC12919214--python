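"""Zero-inflated Gaussian likelihood and log full-conditionals.

The model links, for every mutation ``k`` carried by clone ``c`` in cell
``s``, a variant allele frequency ``v`` in [0, 1] with the cell's
disease-relevance score ``n``.  Scores are zero-inflated: with
probability ``pi`` an observation is an exact zero (the mutation does not
contribute to the phenotype); otherwise the score is Gaussian with mean
``a * v + b`` and shared residual variance ``sigma2``::

    p(n | v) = pi * delta_0(n) + (1 - pi) * N(n | a*v + b, sigma2)

``a`` is the clone-specific selection pressure (slope linking
heteroplasmy to the disease score, restricted to (0, 1) by its Beta
prior), ``b`` the clone's baseline contribution, and ``pi`` the
zero-inflation probability.  Priors: ``pi ~ Beta(alpha, beta)``,
``a ~ Beta(alpha_a, beta_a)``, ``b ~ N(0, sigma_b2)``,
``sigma2 ~ Inv-Gamma(kappa, theta)``.

Because a continuous Gaussian places no mass at zero, a record belongs to
the point-mass component if and only if its score equals zero exactly;
all Gaussian-component sums therefore run over the nonzero-score records
of a group only.  The log-conditionals are unnormalized (constants in the
target variable are dropped), which is all Metropolis-Hastings needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GroupParams",
    "NoiseParam",
    "PriorConfig",
    "GroupData",
    "mixture_mean",
    "log_density_one",
    "log_likelihood",
    "log_conditional_a",
    "log_conditional_b",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GroupParams:
    """Per-clone parameters: zero-inflation ``pi``, slope ``a``, baseline ``b``."""

    pi: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must lie in (0, 1), got {self.pi}")
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"a must lie in (0, 1), got {self.a}")
        if not math.isfinite(self.b):
            raise ValueError(f"b must be finite, got {self.b}")


@dataclass(frozen=True)
class NoiseParam:
    """Residual variance of the Gaussian score component."""

    sigma2: float

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0.0 and math.isfinite(self.sigma2)):
            raise ValueError(f"sigma2 must be positive and finite, got {self.sigma2}")


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the hierarchical priors.

    alpha, beta      : Beta prior on the zero-inflation probability pi.
    alpha_a, beta_a  : Beta prior on the selection pressure a.
    sigma_b2         : variance of the zero-mean Normal prior on b.
    kappa, theta     : shape/scale of the Inverse-Gamma prior on sigma2.
    """

    alpha: float = 2.0
    beta: float = 2.0
    alpha_a: float = 2.0
    beta_a: float = 2.0
    sigma_b2: float = 1.0
    kappa: float = 2.0
    theta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "alpha_a", "beta_a", "sigma_b2", "kappa", "theta"):
            val = getattr(self, name)
            if not (val > 0.0 and math.isfinite(val)):
                raise ValueError(f"prior hyperparameter {name} must be > 0, got {val}")


@dataclass
class GroupData:
    """One group's records in sampler-ready form.

    Stores the nonzero-score records (the only ones the Gaussian component
    sees) plus the zero count, and caches the sufficient statistics the
    conditionals need so a full MH-within-Gibbs sweep costs O(1) per group.
    """

    v: np.ndarray          # VAFs of nonzero-score records
    n: np.ndarray          # nonzero scores
    n_total: int           # K:  all records in the group
    n_zero: int            # Z:  records with score exactly 0
    sum_v: float = field(init=False)
    sum_v2: float = field(init=False)
    sum_n: float = field(init=False)
    sum_n2: float = field(init=False)
    sum_vn: float = field(init=False)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.v.shape != self.n.shape:
            raise ValueError("v and n must have equal length")
        if self.n_zero + len(self.v) != self.n_total:
            raise ValueError("n_zero + nonzero records must equal n_total")
        self.sum_v = float(self.v.sum())
        self.sum_v2 = float((self.v * self.v).sum())
        self.sum_n = float(self.n.sum())
        self.sum_n2 = float((self.n * self.n).sum())
        self.sum_vn = float((self.v * self.n).sum())

    @property
    def n_nonzero(self) -> int:
        return int(len(self.v))

    @classmethod
    def from_records(cls, vaf: np.ndarray, score: np.ndarray) -> "GroupData":
        """Split a group's (vaf, score) records on the exact-zero rule."""
        vaf = np.asarray(vaf, dtype=float)
        score = np.asarray(score, dtype=float)
        nz = score != 0.0
        return cls(v=vaf[nz], n=score[nz], n_total=len(score), n_zero=int((~nz).sum()))

    def residual_ss(self, a: float, b: float) -> float:
        """Sum of squared Gaussian residuals sum_(nonzero) (n - a*v - b)^2."""
        k1 = self.n_nonzero
        return (
            self.sum_n2
            + a * a * self.sum_v2
            + b * b * k1
            - 2.0 * a * self.sum_vn
            - 2.0 * b * self.sum_n
            + 2.0 * a * b * self.sum_v
        )


def mixture_mean(vaf: float, params: GroupParams) -> float:
    """Mean of the Gaussian score component, ``a * vaf + b``."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must lie in [0, 1], got {vaf}")
    return params.a * vaf + params.b


def log_density_one(score: float, vaf: float, params: GroupParams, noise: NoiseParam) -> float:
    """Log density of a single observation under the zero-inflated mixture.

    Returns ``log pi`` on the point mass (score exactly 0), else
    ``log(1-pi) + log N(score | a*vaf + b, sigma2)``.
    """
    if score == 0.0:
        return math.log(params.pi)
    mu = mixture_mean(vaf, params)
    resid = score - mu
    return (
        math.log1p(-params.pi)
        - 0.5 * (_LOG_2PI + math.log(noise.sigma2))
        - resid * resid / (2.0 * noise.sigma2)
    )


def log_likelihood(
    obs: "ObservationSet",
    all_params: Mapping[str, GroupParams],
    noise: NoiseParam,
) -> float:
    """Joint log-likelihood: sum of `log_density_one` over every record.

    ``all_params`` may list extra groups (they contribute nothing); a group
    present in ``obs`` but missing from ``all_params`` is a configuration
    error.
    """
    total = 0.0
    for gid in obs.group_ids:
        if gid not in all_params:
            raise KeyError(f"no parameters supplied for group {gid!r}")
        p = all_params[gid]
        gd = obs.group_data(gid)
        total += gd.n_zero * math.log(p.pi)
        k1 = gd.n_nonzero
        if k1:
            total += k1 * (math.log1p(-p.pi) - 0.5 * (_LOG_2PI + math.log(noise.sigma2)))
            total -= gd.residual_ss(p.a, p.b) / (2.0 * noise.sigma2)
    return total


def log_conditional_a(
    a: float,
    group: GroupData,
    b: float,
    noise: NoiseParam,
    prior: PriorConfig,
) -> float:
    """Unnormalized log full-conditional of the selection pressure ``a``.

        -(1/2 sigma2) * [a^2 sum v^2 - 2 a sum v (n - b)]
        + (alpha_a - 1) log a + (beta_a - 1) log(1 - a)

    with sums over the group's nonzero-score records.  Values outside the
    open support return ``-inf``; with a flat Beta(1,1) prior the boundary
    itself remains finite (the likelihood term is continuous there).
    """
    flat = prior.alpha_a == 1.0 and prior.beta_a == 1.0
    if a < 0.0 or a > 1.0 or ((a == 0.0 or a == 1.0) and not flat):
        return -math.inf
    quad = -(a * a * group.sum_v2 - 2.0 * a * (group.sum_vn - b * group.sum_v)) / (
        2.0 * noise.sigma2
    )
    if flat:
        return quad
    return quad + (prior.alpha_a - 1.0) * math.log(a) + (prior.beta_a - 1.0) * math.log1p(-a)


def log_conditional_b(
    b: float,
    group: GroupData,
    a: float,
    noise: NoiseParam,
    prior: PriorConfig,
) -> float:
    """Unnormalized log full-conditional of the baseline ``b``.

        -(1/2 sigma2) * [b^2 K1 - 2 b sum (n - a v)]  -  b^2 / (2 sigma_b2)

    with sums over the nonzero-score records (count K1).  Completing the
    square shows this is a Gaussian in ``b`` with variance
    ``(K1/sigma2 + 1/sigma_b2)^-1``; the sampler still treats it by MH.
    """
    k1 = group.n_nonzero
    quad = -(b * b * k1 - 2.0 * b * (group.sum_n - a * group.sum_v)) / (2.0 * noise.sigma2)
    return quad - b * b / (2.0 * prior.sigma_b2)
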