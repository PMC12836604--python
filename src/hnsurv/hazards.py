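"""Closed-form hazard machinery for parametric proportional-hazards models.

Four baseline families on the rate convention (lambda is a rate per year, so
the log-logistic baseline median is 1/lambda):

===========  ==========================================  ==============================
family       hazard h0(t)                                cumulative hazard H0(t)
===========  ==========================================  ==============================
exponential  λ                                           λt
weibull      λγ(λt)^(γ−1)                                (λt)^γ
gompertz     λ·exp(γt)                                   (λ/γ)(exp(γt)−1)
loglogistic  λγ(λt)^(γ−1) / (1+(λt)^γ)                   log(1+(λt)^γ)
===========  ==========================================  ==============================

Covariates act multiplicatively on the hazard: h(t|x) = h0(t)·θ with
θ = exp(β·x), hence S(t|x) = exp(−H0(t)·θ) and every exp(β_j) is a hazard
ratio. All functions broadcast over numpy arrays of t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic")


class HazardDomainError(ValueError):
    """Argument outside the domain of a hazard function."""


@dataclass(frozen=True)
class HazardParams:
    """Baseline hazard family with its scale-rate λ (per year) and shape γ.

    γ is ignored for the exponential family (may be None).
    """

    family: str
    lam: float
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise HazardDomainError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not self.lam > 0:
            raise HazardDomainError(f"lambda must be > 0, got {self.lam}")
        if self.family != "exponential":
            if self.gamma is None or not self.gamma > 0:
                raise HazardDomainError(
                    f"{self.family} requires gamma > 0, got {self.gamma}"
                )

    @property
    def n_params(self) -> int:
        return 1 if self.family == "exponential" else 2


@dataclass(frozen=True)
class LinearPredictor:
    """η = β·x and the hazard multiplier θ = exp(η); θ = 1 at reference."""

    eta: float

    @property
    def theta(self) -> float:
        return float(np.exp(self.eta))

    @classmethod
    def from_beta(cls, beta, x) -> "LinearPredictor":
        return cls(eta=float(np.dot(beta, x)))


def _as_positive(t, name="t", strict=True):
    t = np.asarray(t, dtype=float)
    if strict and np.any(t <= 0):
        raise HazardDomainError(f"{name} must be > 0")
    if not strict and np.any(t < 0):
        raise HazardDomainError(f"{name} must be >= 0")
    return t


def hazard(params: HazardParams, t):
    """Baseline hazard h0(t) in events per year; t > 0."""
    t = _as_positive(t)
    lam, gam = params.lam, params.gamma
    if params.family == "exponential":
        return np.broadcast_to(lam, t.shape).copy() if t.shape else np.float64(lam)
    if params.family == "weibull":
        return lam * gam * (lam * t) ** (gam - 1.0)
    if params.family == "gompertz":
        return lam * np.exp(gam * t)
    # log-logistic
    w = (lam * t) ** gam
    return lam * gam * (lam * t) ** (gam - 1.0) / (1.0 + w)


def cumulative_hazard(params: HazardParams, t):
    """Baseline cumulative hazard H0(t) = ∫0^t h0(s) ds; t ≥ 0, H0(0)=0."""
    t = _as_positive(t, strict=False)
    lam, gam = params.lam, params.gamma
    if params.family == "exponential":
        return lam * t
    if params.family == "weibull":
        return (lam * t) ** gam
    if params.family == "gompertz":
        return (lam / gam) * np.expm1(gam * t)
    return np.log1p((lam * t) ** gam)


def survival(params: HazardParams, t, theta: float = 1.0):
    """S(t|x) = exp(−H0(t)·θ) for hazard multiplier θ = exp(β·x)."""
    if np.any(np.asarray(theta) <= 0):
        raise HazardDomainError("theta must be > 0")
    return np.exp(-cumulative_hazard(params, t) * theta)


def survival_quantile(params: HazardParams, q, theta: float = 1.0):
    """Time t at which S(t|x) = q, i.e. the inverse survival function.

    Closed form in every family; for the log-logistic,
    t = (1/λ)·(q^(−1/θ) − 1)^(1/γ). Used both for median overall survival
    and for inverse-CDF event-time sampling (q ~ Uniform(0,1)).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise HazardDomainError("q must lie strictly inside (0, 1)")
    if np.any(np.asarray(theta) <= 0):
        raise HazardDomainError("theta must be > 0")
    lam, gam = params.lam, params.gamma
    # solve H0(t) = z with z = −log(q)/θ
    z = -np.log(q) / theta
    if params.family == "exponential":
        return z / lam
    if params.family == "weibull":
        return z ** (1.0 / gam) / lam
    if params.family == "gompertz":
        return np.log1p(gam * z / lam) / gam
    # log-logistic: (λt)^γ = e^z − 1  ⇔  t = (q^(−1/θ) − 1)^(1/γ) / λ
    return np.expm1(z) ** (1.0 / gam) / lam


def median_survival(params: HazardParams, theta: float = 1.0) -> float:
    """Median survival time: survival_quantile at q = 0.5."""
    return float(survival_quantile(params, 0.5, theta))
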