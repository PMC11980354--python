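"""Gompertz and Gompertz-Makeham adult-mortality hazards.

The Gompertz hazard ``h(t) = alpha * exp(beta * t)`` describes senescent
mortality rising exponentially with age; the Gompertz-Makeham variant adds a
constant age-independent component, ``h(t) = a1 + a2 * exp(beta * t)``.  A
proportional-hazards covariate multiplies the whole baseline hazard by
``exp(x * rho)``, so a binary covariate (e.g. sex, coded 0/1) shifts mortality
risk uniformly across age.

Age is measured on the study time scale ``t = calendar age - 15`` (entry at
15 years): assemblages analysed with these models include only individuals
who survived to 15, and defining the hazard on ``t >= 0`` makes that left
truncation exact without an explicit conditioning term.

All functions accept scalar or array ``t`` and are vectorised with numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "ENTRY_AGE",
    "BETA_LIMIT",
    "GompertzParams",
    "GompertzMakehamParams",
    "PHParams",
    "MortalityModel",
    "hazard",
    "cumulative_hazard",
    "survival",
    "density",
]

#: Entry age in calendar years; internal time is t = age - ENTRY_AGE.
ENTRY_AGE = 15.0

#: Below this |beta| the (exp(beta*t)-1)/beta terms switch to their beta -> 0
#: series limit to avoid catastrophic cancellation.
BETA_LIMIT = 1e-8


@dataclass(frozen=True)
class GompertzParams:
    """Two-parameter Gompertz senescent hazard h(t) = alpha * exp(beta*t).

    Parameters
    ----------
    alpha : float
        Level of senescent mortality at t = 0 (per year, > 0).
    beta : float
        Exponential rate of mortality increase with age (per year, >= 0).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Three-parameter Gompertz-Makeham hazard h(t) = a1 + a2 * exp(beta*t).

    Parameters
    ----------
    a1 : float
        Makeham term: constant age-independent risk of adult mortality
        (per year, >= 0).
    a2 : float
        Level of the senescent component at t = 0 (per year, > 0).
    beta : float
        Exponential rate of the senescent component (per year, >= 0).
    """

    a1: float
    a2: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a1) and self.a1 >= 0):
            raise ValueError(f"a1 must be finite and >= 0, got {self.a1}")
        if not (np.isfinite(self.a2) and self.a2 > 0):
            raise ValueError(f"a2 must be finite and > 0, got {self.a2}")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")


MortalityModel = Union[GompertzParams, GompertzMakehamParams]


@dataclass(frozen=True)
class PHParams:
    """A baseline mortality model plus a proportional-hazards covariate effect.

    The covariate x multiplies the baseline hazard by exp(x * rho); rho is the
    log hazard ratio (dimensionless), so for a 0/1 sex code (0 = male,
    1 = female) positive rho means higher female mortality risk.
    """

    baseline: MortalityModel
    rho: float = 0.0
    covariate_name: str = "sex"

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho):
            raise ValueError(f"rho must be finite, got {self.rho}")


def _components(model: MortalityModel) -> tuple[float, float, float]:
    """Return (a1, a2, beta); a Gompertz model is GM with a1 = 0."""
    if isinstance(model, GompertzMakehamParams):
        return model.a1, model.a2, model.beta
    if isinstance(model, GompertzParams):
        return 0.0, model.alpha, model.beta
    raise TypeError(f"not a mortality model: {model!r}")


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (years since entry age 15)")
    return t


def hazard(model: MortalityModel, t):
    """Instantaneous death rate h(t) at t years past the entry age.

    Strictly positive and non-decreasing in t for valid parameters.
    """
    a1, a2, beta = _components(model)
    t = _check_t(t)
    return a1 + a2 * np.exp(beta * t)


def cumulative_hazard(model: MortalityModel, t):
    """Integrated hazard H(t) = a1*t + (a2/beta)*(exp(beta*t) - 1).

    For |beta| below ``BETA_LIMIT`` the constant-hazard limit (a1 + a2)*t is
    used. H(0) = 0 and H is non-decreasing.
    """
    a1, a2, beta = _components(model)
    t = _check_t(t)
    if abs(beta) < BETA_LIMIT:
        return (a1 + a2) * t
    return a1 * t + (a2 / beta) * np.expm1(beta * t)


def survival(model: MortalityModel, t, x=0.0, rho: float = 0.0):
    """PH survival S(t | x) = exp(-exp(x*rho) * H(t)).

    With ``x = 0`` or ``rho = 0`` this is the baseline survival exp(-H(t)).
    """
    H = cumulative_hazard(model, t)
    return np.exp(-np.exp(np.asarray(x, dtype=float) * rho) * H)


def density(model: MortalityModel, t, x=0.0, rho: float = 0.0):
    """Age-at-death density f(t | x) = exp(x*rho) * h(t) * S(t | x).

    Integrates to 1 over [0, inf) whenever survival vanishes in the tail
    (always true for beta > 0 or a positive Makeham term).
    """
    mult = np.exp(np.asarray(x, dtype=float) * rho)
    return mult * hazard(model, t) * survival(model, t, x=x, rho=rho)
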