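"""Lognormal input/output distributions for the probabilistic exposure model.

Every stochastic quantity in the simulation — per-food concentration and
intake, cigarettes per day, tobacco cadmium content — is modelled as a
lognormal, a point mass (degenerate, zero spread) or a Bernoulli-lognormal
mixture whose Bernoulli component puts its mass at exactly zero
(non-consumers / non-smokers).  The reported output exposure distributions
are lognormal as well, so the same container describes both ends.

Two parameterizations are supported:

``from_moments``      sigma^2 = ln(1 + (std/mean)^2), mu = ln(mean) - sigma^2/2
``from_mean_median``  mu = ln(median),                sigma = sqrt(2 ln(mean/median))

The first is the natural fit to a summary table printing mean and std; the
second inverts the printed (mean, median) pair of a reported output model.
They coincide exactly when fed consistent moments of one lognormal.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .tables import ValidationError

__all__ = [
    "FittedDistribution",
    "lognormal_from_moments",
    "lognormal_from_mean_median",
    "point_mass",
    "zero_inflated",
    "dist_cdf",
    "dist_quantile",
    "sample",
]


@dataclass(frozen=True)
class FittedDistribution:
    """A lognormal / point-mass / zero-inflated-lognormal distribution.

    ``mu`` and ``sigma`` are the log-scale location and spread; for a point
    mass ``sigma`` is 0 and the mass sits at ``exp(mu)``.  ``mix_p`` is the
    probability of the positive (lognormal) branch of the mixture; the
    remaining mass sits at exactly zero.
    """

    family: str  # lognormal | point_mass | bernoulli_lognormal_mixture
    mu: float
    sigma: float
    mix_p: float | None = None
    provenance: str = "direct"  # from_moments | from_mean_median | direct

    def __post_init__(self) -> None:
        if self.family not in {
            "lognormal",
            "point_mass",
            "bernoulli_lognormal_mixture",
        }:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.family == "point_mass" and self.sigma != 0:
            raise ValidationError("point mass requires sigma = 0")
        if self.family == "lognormal" and self.sigma == 0:
            raise ValidationError("lognormal with sigma 0: use point_mass")
        if self.family == "bernoulli_lognormal_mixture":
            if self.mix_p is None or not 0.0 <= self.mix_p <= 1.0:
                raise ValidationError("mixture requires mix_p in [0, 1]")
        elif self.mix_p is not None:
            raise ValidationError("mix_p only valid for the mixture family")

    # -- moments ----------------------------------------------------------
    def mean(self) -> float:
        m = math.exp(self.mu + self.sigma**2 / 2.0)
        return m * self.mix_p if self.family == "bernoulli_lognormal_mixture" else m

    def median(self) -> float:
        if self.family == "bernoulli_lognormal_mixture":
            return self.quantile(0.5)
        return math.exp(self.mu)

    def std(self) -> float:
        if self.family == "point_mass":
            return 0.0
        ln_mean = math.exp(self.mu + self.sigma**2 / 2.0)
        if self.family == "lognormal":
            # expm1 avoids cancellation at small sigma
            return ln_mean * math.sqrt(math.expm1(self.sigma**2))
        m2 = self.mix_p * math.exp(2 * self.mu + 2 * self.sigma**2)
        return math.sqrt(m2 - self.mean() ** 2)

    # -- cdf / quantile ----------------------------------------------------
    def cdf(self, x: float) -> float:
        if x < 0:
            raise ValidationError("cdf argument must be >= 0")
        if self.family == "point_mass":
            value = math.exp(self.mu)
            return 1.0 if x >= value or math.isclose(x, value, rel_tol=1e-12) else 0.0
        tail = stats.norm.cdf((math.log(x) - self.mu) / self.sigma) if x > 0 else 0.0
        if self.family == "bernoulli_lognormal_mixture":
            return (1.0 - self.mix_p) + self.mix_p * tail
        return tail

    def quantile(self, p: float) -> float:
        if not 0.0 < p < 1.0:
            raise ValidationError("quantile probability must be in (0, 1)")
        if self.family == "point_mass":
            return math.exp(self.mu)
        if self.family == "bernoulli_lognormal_mixture":
            zero_mass = 1.0 - self.mix_p
            if p <= zero_mass:
                return 0.0
            p = (p - zero_mass) / self.mix_p
        return math.exp(self.mu + self.sigma * stats.norm.ppf(p))

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self))
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "FittedDistribution":
        return cls(**json.loads(payload))


def point_mass(value: float, provenance: str = "direct") -> FittedDistribution:
    """Degenerate distribution at ``value`` (> 0)."""
    if value <= 0:
        raise ValidationError("point mass value must be positive")
    return FittedDistribution("point_mass", math.log(value), 0.0, provenance=provenance)


def lognormal_from_moments(mean: float, std: float) -> FittedDistribution:
    """Method-of-moments lognormal; ``std = 0`` degenerates to a point mass."""
    if mean <= 0:
        raise ValidationError("lognormal mean must be positive")
    if std < 0:
        raise ValidationError("std must be >= 0")
    if std == 0:
        return point_mass(mean, provenance="from_moments")
    sigma2 = math.log1p((std / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return FittedDistribution(
        "lognormal", mu, math.sqrt(sigma2), provenance="from_moments"
    )


def lognormal_from_mean_median(mean: float, median: float) -> FittedDistribution:
    """Lognormal inverted from its mean and median.

    A lognormal's mean always exceeds its median (by exp(sigma^2/2)), so
    ``mean < median`` is rejected and ``mean == median`` is a point mass.
    """
    if median <= 0:
        raise ValidationError("median must be positive")
    if mean < median:
        raise ValidationError("a lognormal cannot have mean < median")
    if mean == median:
        return point_mass(mean, provenance="from_mean_median")
    mu = math.log(median)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    return FittedDistribution("lognormal", mu, sigma, provenance="from_mean_median")


def zero_inflated(dist: FittedDistribution, positive_p: float) -> FittedDistribution:
    """Mixture putting ``1 - positive_p`` mass at zero around a lognormal."""
    if dist.family == "bernoulli_lognormal_mixture":
        raise ValidationError("cannot nest mixtures")
    if positive_p >= 1.0:
        return dist
    return FittedDistribution(
        "bernoulli_lognormal_mixture",
        dist.mu,
        dist.sigma,
        mix_p=positive_p,
        provenance=dist.provenance,
    )


def dist_cdf(dist: FittedDistribution, x: float) -> float:
    """Cumulative probability of ``dist`` at ``x``."""
    return dist.cdf(x)


def dist_quantile(dist: FittedDistribution, p: float) -> float:
    """Inverse CDF of ``dist`` at probability ``p``."""
    return dist.quantile(p)


def sample(
    dist: FittedDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from ``dist``."""
    if n < 1:
        raise ValidationError("sample size must be >= 1")
    if dist.family == "point_mass":
        return np.full(n, math.exp(dist.mu))
    draws = rng.lognormal(dist.mu, dist.sigma, size=n)
    if dist.family == "bernoulli_lognormal_mixture":
        draws = draws * (rng.random(n) < dist.mix_p)
    return draws
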