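"""Closed-form kinetic model families for batch fermentation.

Four families describe the observables of a batch L-arabinose-isomerase
(l-AI) fermentation of *Lactobacillus plantarum* WU14:

* **Boltzmann sigmoid** — a four-parameter S-curve
  ``y = (A1 - A2)/(1 + exp((t - x0)/dx)) + A2`` with asymptotes ``A1``
  (early) and ``A2`` (late), inflection time ``x0`` and time scale ``dx``.
  Used for biomass (OD600) and enzyme activity.
* **Power-logistic** — ``y = (A1 - A2)/(1 + (t/x0)^p) + A2``, a
  four-parameter transition on t >= 0; used for reducing-sugar decline.
* **Logistic growth** — the closed-form solution of
  ``dX/dt = mu_m * X * (1 - X/Xmax)``.
* **Luedeking-Piret** — product formation ``dP/dt = alpha*dX/dt + beta*X``
  partitioned into a growth-associated term (``alpha``) and a
  non-growth-associated term (``beta``), integrated in closed form against
  logistic growth.

All evaluation functions are vectorised over ``t`` (scalar in, scalar out;
array in, array out) and guard against exponential overflow so extreme
times return the exact asymptote.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "ModelFamily",
    "BoltzmannParams",
    "PowerLogisticParams",
    "LogisticGrowthParams",
    "LuedekingPiretParams",
    "boltzmann_eval",
    "power_logistic_eval",
    "logistic_growth_eval",
    "logistic_growth_rate",
    "logistic_growth_integral",
    "luedeking_piret_eval",
    "luedeking_piret_rate",
    "growth_association_fraction",
    "WU14_GROWTH_BOLTZMANN",
    "WU14_LAI_BOLTZMANN",
    "WU14_SUBSTRATE_POWER_LOGISTIC",
    "WU14_SUBSTRATE_BOLTZMANN_REJECTED",
    "WU14_GROWTH_LOGISTIC",
    "WU14_LAI_LUEDEKING_PIRET",
]

# exp() overflows near 710; clamping at +/-700 pins the sigmoid to its
# asymptote exactly instead of propagating inf/nan
_EXP_CLAMP = 700.0


class ModelFamily(str, enum.Enum):
    """Closed set of model families; each maps to one parameter record."""

    BOLTZMANN = "boltzmann"
    POWER_LOGISTIC = "power_logistic"
    LOGISTIC_GROWTH = "logistic_growth"
    LUEDEKING_PIRET = "luedeking_piret"


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise DomainError(f"{name}: non-finite parameter value {v!r}")


@dataclass(frozen=True)
class BoltzmannParams:
    """Boltzmann sigmoid parameters.

    A1, A2 : early / late asymptotes (units of the observable)
    x0     : inflection time (hr)
    dx     : time-scale constant (hr), nonzero
    """

    A1: float
    A2: float
    x0: float
    dx: float

    def __post_init__(self) -> None:
        _require_finite("BoltzmannParams", self.A1, self.A2, self.x0, self.dx)
        if self.dx == 0:
            raise DomainError("BoltzmannParams: dx must be nonzero")


@dataclass(frozen=True)
class PowerLogisticParams:
    """Power-logistic parameters.

    A1, A2 : initial / final level (observable units)
    x0     : half-transition time (hr), > 0
    p      : shape exponent (dimensionless)
    """

    A1: float
    A2: float
    x0: float
    p: float

    def __post_init__(self) -> None:
        _require_finite("PowerLogisticParams", self.A1, self.A2, self.x0, self.p)
        if self.x0 <= 0:
            raise DomainError("PowerLogisticParams: x0 must be positive")


@dataclass(frozen=True)
class LogisticGrowthParams:
    """Logistic growth parameters: dX/dt = mu_m * X * (1 - X/Xmax).

    X0   : initial biomass (OD600), 0 < X0 < Xmax
    Xmax : carrying capacity (OD600)
    mu_m : maximum specific growth rate (1/hr), > 0
    """

    X0: float
    Xmax: float
    mu_m: float

    def __post_init__(self) -> None:
        _require_finite("LogisticGrowthParams", self.X0, self.Xmax, self.mu_m)
        if not 0 < self.X0 < self.Xmax:
            raise DomainError(
                f"LogisticGrowthParams: need 0 < X0 < Xmax, got X0={self.X0}, Xmax={self.Xmax}"
            )
        if self.mu_m <= 0:
            raise DomainError("LogisticGrowthParams: mu_m must be positive")


@dataclass(frozen=True)
class LuedekingPiretParams:
    """Luedeking-Piret product-formation parameters.

    alpha  : growth-associated coefficient (product units per biomass unit)
    beta   : non-growth-associated coefficient (product units per biomass
             unit per hr)
    growth : the underlying logistic growth parameters
    P0     : initial product level (product units), >= 0
    """

    alpha: float
    beta: float
    growth: LogisticGrowthParams
    P0: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("LuedekingPiretParams", self.alpha, self.beta, self.P0)
        if self.P0 < 0:
            raise DomainError("LuedekingPiretParams: P0 must be non-negative")


def _as_finite_time(t, allow_negative: bool = True):
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("t must be finite")
    if not allow_negative and np.any(arr < 0):
        raise DomainError("t must be non-negative")
    return arr


def _maybe_scalar(arr, t):
    return float(arr) if np.isscalar(t) or np.ndim(t) == 0 else arr


def boltzmann_eval(params: BoltzmannParams, t):
    """Evaluate the Boltzmann sigmoid at time(s) ``t`` (hr).

    Tends to A1 as t -> -inf and to A2 as t -> +inf (for dx > 0).
    """
    tt = _as_finite_time(t)
    z = np.clip((tt - params.x0) / params.dx, -_EXP_CLAMP, _EXP_CLAMP)
    y = (params.A1 - params.A2) / (1.0 + np.exp(z)) + params.A2
    return _maybe_scalar(y, t)


def power_logistic_eval(params: PowerLogisticParams, t):
    """Evaluate the power-logistic curve at time(s) ``t`` (hr, >= 0).

    Value at t = 0 is A1 (for p > 0); tends to A2 as t -> +inf.
    Negative times are a domain error: fractional powers of negative
    numbers are undefined in the reals.
    """
    tt = _as_finite_time(t, allow_negative=False)
    with np.errstate(over="ignore"):
        ratio = np.power(tt / params.x0, params.p)
    ratio = np.where(np.isinf(ratio), np.finfo(float).max, ratio)
    y = (params.A1 - params.A2) / (1.0 + ratio) + params.A2
    return _maybe_scalar(y, t)


def logistic_growth_eval(params: LogisticGrowthParams, t):
    """Biomass X(t) from the closed-form logistic solution.

    X(t) = X0*Xmax*e^(mu_m t) / (Xmax - X0 + X0*e^(mu_m t)); strictly
    increasing and bounded in (0, Xmax).
    """
    tt = _as_finite_time(t)
    X0, Xmax, mu = params.X0, params.Xmax, params.mu_m
    z = np.clip(mu * tt, -_EXP_CLAMP, _EXP_CLAMP)
    e = np.exp(z)
    x = X0 * Xmax * e / (Xmax - X0 + X0 * e)
    return _maybe_scalar(x, t)


def logistic_growth_rate(params: LogisticGrowthParams, t):
    """Growth rate dX/dt = mu_m * X * (1 - X/Xmax) at time(s) ``t``."""
    x = np.asarray(logistic_growth_eval(params, t))
    r = params.mu_m * x * (1.0 - x / params.Xmax)
    return _maybe_scalar(r, t)


def logistic_growth_integral(params: LogisticGrowthParams, t):
    """Closed-form cumulative biomass integral(0..t) X dtau (OD600*hr).

    Equals (Xmax/mu_m) * ln[(Xmax - X0 + X0 e^(mu_m t)) / Xmax]; zero at
    t = 0 and non-decreasing.
    """
    tt = _as_finite_time(t, allow_negative=False)
    X0, Xmax, mu = params.X0, params.Xmax, params.mu_m
    z = np.clip(mu * tt, -_EXP_CLAMP, _EXP_CLAMP)
    # log1p form keeps precision at small t where e^z ~ 1
    val = (Xmax / mu) * np.log1p(X0 * np.expm1(z) / Xmax)
    return _maybe_scalar(val, t)


def luedeking_piret_eval(params: LuedekingPiretParams, t):
    """Product level P(t) from the integrated Luedeking-Piret model.

    P(t) = P0 + alpha*(X(t) - X0) + beta * integral(0..t) X dtau; equals P0
    at t = 0.
    """
    tt = _as_finite_time(t, allow_negative=False)
    g = params.growth
    x = np.asarray(logistic_growth_eval(g, tt))
    integ = np.asarray(logistic_growth_integral(g, tt))
    p = params.P0 + params.alpha * (x - g.X0) + params.beta * integ
    return _maybe_scalar(p, t)


def luedeking_piret_rate(params: LuedekingPiretParams, t):
    """Production rate dP/dt = alpha*dX/dt + beta*X at time(s) ``t``."""
    r = params.alpha * np.asarray(logistic_growth_rate(params.growth, t)) + params.beta * np.asarray(
        logistic_growth_eval(params.growth, t)
    )
    return _maybe_scalar(r, t)


def growth_association_fraction(params: LuedekingPiretParams, t):
    """Fraction of instantaneous production that is growth-associated.

    Returns alpha*dX/dt / (alpha*dX/dt + beta*X) in [0, 1]. Near 1 the
    product is made while cells divide; near 0 production is
    non-growth-coupled (stationary-phase production), the regime reported
    for l-AI in *L. plantarum* WU14.
    """
    tt = _as_finite_time(t, allow_negative=False)
    if params.alpha < 0 or params.beta < 0:
        raise DomainError("growth_association_fraction requires alpha, beta >= 0")
    num = params.alpha * np.asarray(logistic_growth_rate(params.growth, tt))
    den = num + params.beta * np.asarray(logistic_growth_eval(params.growth, tt))
    if np.any(den == 0):
        raise DomainError("growth_association_fraction undefined: zero production rate")
    return _maybe_scalar(num / den, t)


# --- Published parameter sets: L. plantarum WU14 l-AI batch fermentation ---
# Reference fits to the 0-24 hr, 2-hr-interval time courses. X0 and P0 are
# not part of the published lists; X0 = 0.2 (order of the earliest OD600
# reading) and P0 = 0 are this package's conventions.

WU14_GROWTH_BOLTZMANN = BoltzmannParams(A1=-0.19407, A2=2.62428, x0=5.52242, dx=2.29839)
"""Biomass (OD600) Boltzmann fit; plateau A2 = 2.62428."""

WU14_LAI_BOLTZMANN = BoltzmannParams(A1=1.66015, A2=41.94723, x0=9.53752, dx=2.46001)
"""Enzyme activity (U/ml) Boltzmann fit; maximum activity A2 = 41.94723 U/ml."""

WU14_SUBSTRATE_POWER_LOGISTIC = PowerLogisticParams(A1=7.04942, A2=0.6189, x0=3.06749, p=1.14414)
"""Reducing sugar (mg/ml) power-logistic fit (the selected substrate model)."""

WU14_SUBSTRATE_BOLTZMANN_REJECTED = BoltzmannParams(A1=11297.04, A2=1.30758, x0=-31.55851, dx=4.15091)
"""Reducing-sugar Boltzmann fit with extreme A1/x0; reported only to be
rejected in favour of the power-logistic model, and used by no pipeline
default here."""

WU14_GROWTH_LOGISTIC = LogisticGrowthParams(X0=0.2, Xmax=37.77377, mu_m=0.28687)
"""Logistic growth fit (mu_m, Xmax published; X0 = 0.2 is a package choice)."""

WU14_LAI_LUEDEKING_PIRET = LuedekingPiretParams(
    alpha=5.92606, beta=1.23832, growth=WU14_GROWTH_LOGISTIC, P0=0.0
)
"""Luedeking-Piret fit for l-AI production (growth shared with the logistic fit)."""
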