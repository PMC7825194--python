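"""Conjugate Beta-binomial machinery for trial-design evaluation.

The response endpoint in one arm is binomial, ``m ~ Bin(n, theta)``; with a
Beta(alpha, beta) prior on ``theta`` the posterior is
``Beta(alpha + m, beta + n - m)``.  The prior-predictive (preposterior)
distribution of future data is obtained by drawing ``theta`` from the prior
and ``m`` from the binomial likelihood.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pkpd import InvalidInputError

__all__ = [
    "BetaDistribution",
    "TrialData",
    "SampleSizeGrid",
    "DEFAULT_GRID",
    "posterior_update",
    "prior_predictive_draw",
    "posterior_point",
]


@dataclass(frozen=True)
class BetaDistribution:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise InvalidInputError(f"{name} must be positive and finite, got {val!r}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass(frozen=True)
class TrialData:
    """Observed (or simulated) responder count ``m`` out of ``n`` subjects."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and isinstance(self.n, (int, np.integer))):
            raise InvalidInputError("m and n must be integers")
        if not 0 <= self.m <= self.n:
            raise InvalidInputError(f"need 0 <= m <= n, got m={self.m}, n={self.n}")


DEFAULT_GRID = (50, 100, 150, 200, 300, 400, 500, 600)


@dataclass(frozen=True)
class SampleSizeGrid:
    """Strictly increasing per-arm sample sizes (total trial size is twice each)."""

    sizes: tuple[int, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if not sizes or any(s <= 0 for s in sizes):
            raise InvalidInputError("sample sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise InvalidInputError("sample sizes must be strictly increasing")
        object.__setattr__(self, "sizes", sizes)

    def __iter__(self):
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)


def posterior_update(prior: BetaDistribution, data: TrialData) -> BetaDistribution:
    """Conjugate update: Beta(alpha + m, beta + n - m)."""
    return BetaDistribution(prior.alpha + data.m, prior.beta + data.n - data.m)


def prior_predictive_draw(
    prior: BetaDistribution, n: int, seed
) -> tuple[float, TrialData]:
    """Draw theta from the prior and m ~ Bin(n, theta); returns (theta, data)."""
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = float(rng.beta(prior.alpha, prior.beta))
    m = int(rng.binomial(n, theta))
    return theta, TrialData(m=m, n=int(n))


def posterior_point(posterior: BetaDistribution) -> float:
    """Posterior point estimate fed to the economic model: the mean alpha/(alpha+beta)."""
    return posterior.mean
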