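"""Uncertainty distributions fitted from printed mean/SD pairs.

Model inputs are published as a mean and a standard deviation together
with a distribution family (Beta for probabilities and utilities, Gamma
for costs, log-normal for relative effects).  This module converts those
moments into sampleable distribution parameters by the method of moments
and provides seeded, labelled random streams so every analysis is exactly
reproducible.

A recurring defect of published input tables is a Beta SD that is
infeasible for its mean (``sd**2 >= mean*(1-mean)``).  Such SDs are capped
at ``BETA_SD_CAP_FACTOR * sqrt(mean*(1-mean))`` and the fit is flagged so
runs can report which inputs were capped.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistributionSpec",
    "BetaParams",
    "GammaParams",
    "LogNormalParams",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_from_moments",
    "sample_parameter",
    "rng_stream",
    "BETA_SD_CAP_FACTOR",
]

FAMILIES = ("beta", "gamma", "lognormal", "fixed")

#: Infeasible Beta SDs are replaced by this fraction of the feasibility bound.
BETA_SD_CAP_FACTOR = 0.95


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float
    #: True when the input SD was infeasible and had to be capped.
    sd_capped: bool = False


@dataclass(frozen=True)
class GammaParams:
    shape: float
    scale: float


@dataclass(frozen=True)
class LogNormalParams:
    mu: float
    sigma: float


@dataclass(frozen=True)
class DistributionSpec:
    """A model input: mean and SD in natural units plus a family.

    ``family='fixed'`` (or ``sd == 0``) marks a degenerate input that is
    never sampled; ``kind`` distinguishes relative-risk from hazard-ratio
    effects (both are applied on the constant-rate scale, so the flag is
    descriptive only).
    """

    family: str
    mean: float
    sd: float = 0.0
    kind: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.family == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ValueError(
                f"beta family requires mean in [0, 1], got {self.mean}"
            )
        if self.family in ("gamma", "lognormal") and self.mean <= 0:
            raise ValueError(
                f"{self.family} family requires mean > 0, got {self.mean}"
            )

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed" or self.sd == 0.0

    def fitted(self):
        """Method-of-moments parameters for the declared family."""
        if self.is_fixed:
            return None
        if self.family == "beta":
            return beta_from_moments(self.mean, self.sd)
        if self.family == "gamma":
            return gamma_from_moments(self.mean, self.sd)
        return lognormal_from_moments(self.mean, self.sd)

    @property
    def sd_capped(self) -> bool:
        """Whether sampling this spec requires capping its Beta SD."""
        if self.is_fixed or self.family != "beta":
            return False
        return self.sd**2 >= self.mean * (1.0 - self.mean)


def beta_from_moments(mean: float, sd: float) -> BetaParams:
    """Fit ``Beta(alpha, beta)`` to a (mean, sd) pair.

    Uses ``nu = mean*(1-mean)/sd**2 - 1``, ``alpha = mean*nu``,
    ``beta = (1-mean)*nu``.  An SD at or above the feasibility bound
    ``sqrt(mean*(1-mean))`` is capped (see module docstring) and the
    returned params carry ``sd_capped=True``.
    """
    if not (0.0 < mean < 1.0):
        if mean in (0.0, 1.0):
            raise ValueError(
                "degenerate beta mean (0 or 1): use a fixed spec instead"
            )
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError("beta sd must be positive; use a fixed spec for sd=0")
    bound = math.sqrt(mean * (1.0 - mean))
    capped = False
    if sd >= bound:
        sd = BETA_SD_CAP_FACTOR * bound
        capped = True
        warnings.warn(
            f"beta SD infeasible for mean {mean:g}; capped at {sd:.6g}",
            stacklevel=2,
        )
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return BetaParams(alpha=mean * nu, beta=(1.0 - mean) * nu, sd_capped=capped)


def gamma_from_moments(mean: float, sd: float) -> GammaParams:
    """Fit ``Gamma(shape, scale)``: shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if sd <= 0:
        raise ValueError("gamma sd must be positive; use a fixed spec for sd=0")
    return GammaParams(shape=mean**2 / sd**2, scale=sd**2 / mean)


def lognormal_from_moments(
    mean: float, sd: float, convention: str = "arithmetic"
) -> LogNormalParams:
    """Fit a log-normal to a (mean, sd) pair on the natural scale.

    ``convention='arithmetic'`` (default) treats the printed value as the
    arithmetic mean: ``sigma^2 = ln(1 + sd^2/mean^2)``,
    ``mu = ln(mean) - sigma^2/2``.  ``convention='median'`` treats it as
    the median: ``mu = ln(mean)`` with the same sigma.
    """
    if mean <= 0:
        raise ValueError(f"lognormal mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return LogNormalParams(mu=math.log(mean), sigma=0.0)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    if convention == "arithmetic":
        mu = math.log(mean) - sigma2 / 2.0
    elif convention == "median":
        mu = math.log(mean)
    else:
        raise ValueError(f"unknown lognormal convention {convention!r}")
    return LogNormalParams(mu=mu, sigma=math.sqrt(sigma2))


def sample_parameter(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: int | tuple[int, ...] | None = None,
    lognormal_convention: str = "arithmetic",
):
    """Draw from the fitted distribution of ``spec``.

    Fixed specs return the mean exactly.  Beta draws lie in [0, 1];
    gamma and log-normal draws are positive.
    """
    if spec.is_fixed:
        if size is None:
            return float(spec.mean)
        return np.full(size, float(spec.mean))
    if spec.family == "beta":
        p = beta_from_moments(spec.mean, spec.sd)
        return rng.beta(p.alpha, p.beta, size=size)
    if spec.family == "gamma":
        p = gamma_from_moments(spec.mean, spec.sd)
        return rng.gamma(p.shape, p.scale, size=size)
    p = lognormal_from_moments(spec.mean, spec.sd, convention=lognormal_convention)
    return rng.lognormal(p.mu, p.sigma, size=size)


def rng_stream(seed: int, label: str) -> np.random.Generator:
    """A named, reproducible random stream.

    The same (seed, label) pair always yields the same generator; distinct
    labels under one seed are statistically independent.
    """
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))
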