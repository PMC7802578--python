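"""Nonlinear least-squares fitting and model selection for time courses.

Each model family is fitted by trust-region-reflective least squares
(:func:`scipy.optimize.least_squares`) minimising the residual sum of
squares between the closed-form model curve and the observations.
Initial values come from a data-driven heuristic (:func:`default_init`)
unless supplied; any subset of a family's parameters can be held fixed,
which is how the Luedeking-Piret product fit reuses the growth parameters
estimated from the biomass series.

Goodness of fit is the plain coefficient of determination
R^2 = 1 - SS_res/SS_tot ("fitting degree"); model selection ranks
candidate families by R^2 or, optionally, by AICc, which unlike R^2
penalises extra parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from . import models
from .errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    SelectionError,
)
from .models import (
    BoltzmannParams,
    LogisticGrowthParams,
    LuedekingPiretParams,
    ModelFamily,
    PowerLogisticParams,
)
from .timecourse import PAPER_GRID, Observable, TimeCourse

__all__ = [
    "FitResult",
    "ModelSelection",
    "r_squared",
    "default_init",
    "fit_model",
    "select_model",
    "recovery_study",
    "param_names",
    "params_to_dict",
    "params_from_dict",
    "render_equation",
]

_LN3 = float(np.log(3.0))
_POS = 1e-12  # open lower bound standing in for "strictly positive"

_NAMES: dict[ModelFamily, tuple[str, ...]] = {
    ModelFamily.BOLTZMANN: ("A1", "A2", "x0", "dx"),
    ModelFamily.POWER_LOGISTIC: ("A1", "A2", "x0", "p"),
    ModelFamily.LOGISTIC_GROWTH: ("X0", "Xmax", "mu_m"),
    ModelFamily.LUEDEKING_PIRET: ("alpha", "beta", "X0", "Xmax", "mu_m", "P0"),
}

# (lower, upper) box constraints per parameter; positivity where the model
# is undefined otherwise, alpha/beta left unbounded (their published values
# are positive but the model does not require it)
_BOUNDS: dict[ModelFamily, dict[str, tuple[float, float]]] = {
    ModelFamily.BOLTZMANN: {"dx": (_POS, np.inf)},
    ModelFamily.POWER_LOGISTIC: {"x0": (_POS, np.inf), "p": (_POS, np.inf)},
    ModelFamily.LOGISTIC_GROWTH: {
        "X0": (_POS, np.inf),
        "Xmax": (_POS, np.inf),
        "mu_m": (_POS, np.inf),
    },
    ModelFamily.LUEDEKING_PIRET: {
        "X0": (_POS, np.inf),
        "Xmax": (_POS, np.inf),
        "mu_m": (_POS, np.inf),
        "P0": (0.0, np.inf),
    },
}


def param_names(family: ModelFamily) -> tuple[str, ...]:
    """Ordered parameter names of a model family (growth flattened)."""
    return _NAMES[ModelFamily(family)]


def params_to_dict(params) -> dict[str, float]:
    """Flatten a parameter record to name -> value (nested growth included)."""
    if isinstance(params, LuedekingPiretParams):
        g = params.growth
        return {
            "alpha": params.alpha,
            "beta": params.beta,
            "X0": g.X0,
            "Xmax": g.Xmax,
            "mu_m": g.mu_m,
            "P0": params.P0,
        }
    return {k: getattr(params, k) for k in param_names(_family_of(params))}


def params_from_dict(family: ModelFamily, d: Mapping[str, float]):
    """Build the validated parameter record of ``family`` from a flat dict."""
    family = ModelFamily(family)
    if family is ModelFamily.BOLTZMANN:
        return BoltzmannParams(d["A1"], d["A2"], d["x0"], d["dx"])
    if family is ModelFamily.POWER_LOGISTIC:
        return PowerLogisticParams(d["A1"], d["A2"], d["x0"], d["p"])
    if family is ModelFamily.LOGISTIC_GROWTH:
        return LogisticGrowthParams(d["X0"], d["Xmax"], d["mu_m"])
    growth = LogisticGrowthParams(d["X0"], d["Xmax"], d["mu_m"])
    return LuedekingPiretParams(d["alpha"], d["beta"], growth, d["P0"])


def _family_of(params) -> ModelFamily:
    if isinstance(params, BoltzmannParams):
        return ModelFamily.BOLTZMANN
    if isinstance(params, PowerLogisticParams):
        return ModelFamily.POWER_LOGISTIC
    if isinstance(params, LogisticGrowthParams):
        return ModelFamily.LOGISTIC_GROWTH
    if isinstance(params, LuedekingPiretParams):
        return ModelFamily.LUEDEKING_PIRET
    raise DomainError(f"unrecognised parameter record {type(params).__name__}")


def _raw_eval(family: ModelFamily, d: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    """Unvalidated model evaluation for use inside the optimiser.

    The optimiser may propose transiently inconsistent parameters
    (e.g. X0 > Xmax); this evaluation never raises, it just computes.
    """
    clamp = 700.0
    if family is ModelFamily.BOLTZMANN:
        z = np.clip((t - d["x0"]) / d["dx"], -clamp, clamp)
        return (d["A1"] - d["A2"]) / (1.0 + np.exp(z)) + d["A2"]
    if family is ModelFamily.POWER_LOGISTIC:
        with np.errstate(over="ignore", invalid="ignore"):
            ratio = np.power(t / d["x0"], d["p"])
        ratio = np.where(np.isfinite(ratio), ratio, np.finfo(float).max)
        return (d["A1"] - d["A2"]) / (1.0 + ratio) + d["A2"]
    X0, Xmax, mu = d["X0"], d["Xmax"], d["mu_m"]
    e = np.exp(np.clip(mu * t, -clamp, clamp))
    with np.errstate(divide="ignore", invalid="ignore"):
        x = X0 * Xmax * e / (Xmax - X0 + X0 * e)
    if family is ModelFamily.LOGISTIC_GROWTH:
        return x
    with np.errstate(divide="ignore", invalid="ignore"):
        integ = (Xmax / mu) * np.log1p(X0 * np.expm1(np.clip(mu * t, -clamp, clamp)) / Xmax)
    return d["P0"] + d["alpha"] * (x - X0) + d["beta"] * integ


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus goodness-of-fit diagnostics for one family."""

    family: ModelFamily
    params: object
    r_squared: float
    ss_res: float
    ss_tot: float
    converged: bool
    n_obs: int
    init_params: object
    fixed: frozenset[str] = frozenset()

    @property
    def n_free(self) -> int:
        return len(param_names(self.family)) - len(self.fixed)

    @property
    def aicc(self) -> float:
        """Corrected Akaike information criterion under Gaussian errors."""
        n, k = self.n_obs, self.n_free
        if self.ss_res <= 0:
            return -np.inf
        if n - k - 1 <= 0:
            return np.inf
        return n * np.log(self.ss_res / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    def predict(self, t):
        from .simulate import model_mean

        return model_mean(self.family, self.params, t)

    @property
    def equation(self) -> str:
        return render_equation(self.family, self.params)

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "params": params_to_dict(self.params),
            "init_params": params_to_dict(self.init_params),
            "fixed": sorted(self.fixed),
            "r_squared": self.r_squared,
            "ss_res": self.ss_res,
            "ss_tot": self.ss_tot,
            "aicc": None if not np.isfinite(self.aicc) else self.aicc,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "equation": self.equation,
        }


@dataclass(frozen=True)
class ModelSelection:
    """Ranked candidate fits and the chosen family."""

    candidates: tuple[FitResult, ...]
    chosen: int
    criterion: str

    @property
    def best(self) -> FitResult:
        return self.candidates[self.chosen]

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "chosen": self.chosen,
            "chosen_family": self.best.family.value,
            "candidates": [c.to_dict() for c in self.candidates],
        }


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot ("fitting degree").

    Equals 1 exactly when predictions match observations; a constant
    observed series has zero total variance and raises
    :class:`DegenerateDataError`.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise DomainError("r_squared needs two equal-length sequences of >= 2 values")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("r_squared undefined: observed values are all identical")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _cross_time(times: np.ndarray, values: np.ndarray, level: float) -> float | None:
    """First time at which the series crosses ``level`` (linear interpolation)."""
    dv = values - level
    for i in range(len(dv) - 1):
        if dv[i] == 0:
            return float(times[i])
        if dv[i] * dv[i + 1] < 0:
            f = dv[i] / (dv[i] - dv[i + 1])
            return float(times[i] + f * (times[i + 1] - times[i]))
    if dv[-1] == 0:
        return float(times[-1])
    return None


def default_init(
    tc: TimeCourse,
    family: ModelFamily,
    growth: LogisticGrowthParams | None = None,
):
    """Data-driven starting parameters for ``family`` on ``tc``.

    Sigmoid families anchor the asymptotes at the first and last readings,
    place the transition midpoint where the series crosses their mean, and
    scale dx (or the exponent p) from the 25-75% transition span. Logistic
    growth starts from the first reading, 1.05x the maximum, and the early
    log-slope. The Luedeking-Piret start solves a non-negative linear
    least-squares problem for alpha and beta given ``growth``, which must
    be supplied (fit the biomass series first).
    """
    family = ModelFamily(family)
    t, v = tc.times, tc.values
    vrange = float(v.max() - v.min())
    if vrange <= 1e-12 * max(1.0, float(np.abs(v).max())):
        raise DegenerateDataError("default_init: series has no usable range")

    if family in (ModelFamily.BOLTZMANN, ModelFamily.POWER_LOGISTIC):
        A1, A2 = float(v[0]), float(v[-1])
        if A1 == A2:  # flat endpoints on a non-flat series: fall back to extremes
            A1, A2 = float(v.max()), float(v.min())
        mid = 0.5 * (A1 + A2)
        x0 = _cross_time(t, v, mid)
        if x0 is None:
            x0 = float(0.5 * (t[0] + t[-1]))
        t25 = _cross_time(t, v, A1 + 0.25 * (A2 - A1))
        t75 = _cross_time(t, v, A1 + 0.75 * (A2 - A1))
        span = abs(t75 - t25) if (t25 is not None and t75 is not None) else 0.0
        if span <= 0:
            span = 0.25 * (t[-1] - t[0])
        if family is ModelFamily.BOLTZMANN:
            return BoltzmannParams(A1=A1, A2=A2, x0=x0, dx=span / (2 * _LN3))
        x0 = max(x0, float(t[-1]) * 1e-3, _POS)
        if t25 and t75 and t25 > 0 and t75 > 0 and t75 != t25:
            p = abs(2 * _LN3 / np.log(t75 / t25))
        else:
            p = 1.0
        return PowerLogisticParams(A1=A1, A2=A2, x0=x0, p=p if p > 0 else 1.0)

    if family is ModelFamily.LOGISTIC_GROWTH:
        Xmax = 1.05 * float(v.max())
        X0 = float(np.clip(v[0], 1e-6 * Xmax, 0.9 * Xmax))
        early = slice(0, max(2, min(4, len(v))))
        tv, vv = t[early], v[early]
        pos = vv > 0
        if pos.sum() >= 2:
            slope = float(np.polyfit(tv[pos], np.log(vv[pos]), 1)[0])
        else:
            slope = 0.0
        mu = slope if slope > 0 else 0.1
        return LogisticGrowthParams(X0=X0, Xmax=Xmax, mu_m=mu)

    # Luedeking-Piret: linear in (alpha, beta) once growth is known
    if growth is None:
        raise DomainError(
            "default_init for the Luedeking-Piret family needs logistic growth "
            "parameters (fit the biomass series first and pass growth=...)"
        )
    P0 = max(float(v[0]), 0.0)
    x = np.asarray(models.logistic_growth_eval(growth, t))
    integ = np.asarray(models.logistic_growth_integral(growth, t))
    design = np.column_stack([x - growth.X0, integ])
    coef, _ = nnls(design, v - P0)
    return LuedekingPiretParams(alpha=float(coef[0]), beta=float(coef[1]), growth=growth, P0=P0)


def _default_fixed(family: ModelFamily) -> frozenset[str]:
    # the product fit inherits the growth curve rather than re-estimating it
    if family is ModelFamily.LUEDEKING_PIRET:
        return frozenset({"X0", "Xmax", "mu_m", "P0"})
    return frozenset()


def fit_model(
    tc: TimeCourse,
    family: ModelFamily,
    init=None,
    fixed: Iterable[str] | None = None,
    growth: LogisticGrowthParams | None = None,
) -> FitResult:
    """Least-squares fit of one model family to a time course.

    Parameters named in ``fixed`` are held at their ``init`` values; for
    the Luedeking-Piret family the default is to fix the growth parameters
    and P0, estimating only alpha and beta (pass ``fixed=()`` for joint
    estimation). Optimiser failure is reported through the ``converged``
    flag, not an exception; only structurally impossible fits (fewer
    observations than free parameters) raise.
    """
    family = ModelFamily(family)
    names = param_names(family)
    fixed_set = _default_fixed(family) if fixed is None else frozenset(fixed)
    unknown = fixed_set - set(names)
    if unknown:
        raise DomainError(f"fixed parameter(s) {sorted(unknown)} not in family {family.value}")
    free = [n for n in names if n not in fixed_set]
    if len(tc) < len(free):
        raise InsufficientDataError(
            f"{len(tc)} observations cannot identify {len(free)} free parameters "
            f"of the {family.value} model"
        )
    if init is None:
        init = default_init(tc, family, growth=growth)
    init_dict = params_to_dict(init)
    bounds_map = _BOUNDS[family]
    lo = np.array([bounds_map.get(n, (-np.inf, np.inf))[0] for n in free])
    hi = np.array([bounds_map.get(n, (-np.inf, np.inf))[1] for n in free])
    x0 = np.clip([init_dict[n] for n in free], lo, hi)

    t, obs = tc.times, tc.values

    def residual(x: np.ndarray) -> np.ndarray:
        d = dict(init_dict)
        d.update(zip(free, x))
        r = _raw_eval(family, d, t) - obs
        return np.nan_to_num(r, nan=1e10, posinf=1e10, neginf=-1e10)

    if free:
        sol = least_squares(
            residual,
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=1000,
        )
        final = dict(init_dict)
        final.update(zip(free, sol.x))
        converged = bool(sol.success)
        res = residual(sol.x)
    else:
        final = dict(init_dict)
        converged = True
        res = residual(np.empty(0))

    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    try:
        params = params_from_dict(family, final)
    except DomainError:
        params, converged = init, False
    return FitResult(
        family=family,
        params=params,
        r_squared=r2,
        ss_res=ss_res,
        ss_tot=ss_tot,
        converged=converged,
        n_obs=len(tc),
        init_params=init,
        fixed=fixed_set,
    )


_SELECTION_TIE_TOL = 1e-9


def select_model(
    tc: TimeCourse,
    families: Sequence[ModelFamily],
    criterion: str = "r_squared",
    growth: LogisticGrowthParams | None = None,
) -> ModelSelection:
    """Fit each candidate family and choose the best by the criterion.

    ``criterion`` is ``"r_squared"`` (maximised; the conventional
    "fitting degree" comparison) or ``"aicc"`` (minimised). Scores tied
    within 1e-9 go to the family with fewer free parameters, then to the
    earlier entry in ``families``.
    """
    if len(families) < 2:
        raise DomainError("select_model needs at least two candidate families")
    if criterion not in ("r_squared", "aicc"):
        raise DomainError(f"unknown selection criterion {criterion!r}")
    candidates = tuple(fit_model(tc, f, growth=growth) for f in families)
    scored = [
        (i, c.r_squared if criterion == "r_squared" else c.aicc)
        for i, c in enumerate(candidates)
        if c.converged and np.isfinite(c.r_squared)
    ]
    if not scored:
        raise SelectionError("no candidate model converged")
    sign = -1.0 if criterion == "r_squared" else 1.0  # normalise to minimisation
    best_score = min(s * sign for _, s in scored)
    tied = [i for i, s in scored if s * sign - best_score <= _SELECTION_TIE_TOL]
    chosen = min(tied, key=lambda i: (candidates[i].n_free, i))
    return ModelSelection(candidates=candidates, chosen=chosen, criterion=criterion)


def recovery_study(
    family: ModelFamily,
    true_params,
    noise_sd: float,
    n_reps: int,
    seed: int,
    observable: Observable = Observable.BIOMASS_OD600,
) -> pd.DataFrame:
    """Monte-Carlo parameter-recovery study on the 0-24 hr, 2-hr grid.

    Simulates ``n_reps`` noisy time courses from ``true_params``, refits
    each from the data-driven initialisation, and tabulates per-parameter
    bias and RMSE of the free parameters. Deterministic for a fixed seed.
    """
    from .simulate import SyntheticConfig, simulate_timecourse

    family = ModelFamily(family)
    if n_reps < 1:
        raise DomainError("recovery_study needs n_reps >= 1")
    if noise_sd < 0:
        raise DomainError("recovery_study needs noise_sd >= 0")
    true_dict = params_to_dict(true_params)
    fixed = _default_fixed(family)
    free = [n for n in param_names(family) if n not in fixed]
    growth = true_params.growth if isinstance(true_params, LuedekingPiretParams) else None
    children = np.random.SeedSequence(seed).spawn(n_reps)
    estimates = np.empty((n_reps, len(free)))
    n_converged = 0
    for r, child in enumerate(children):
        cfg = SyntheticConfig(
            family=family,
            params=true_params,
            observable=observable,
            noise_sd=noise_sd,
            seed=int(child.generate_state(1)[0]),
        )
        tc = simulate_timecourse(cfg)
        fit = fit_model(tc, family, growth=growth)
        n_converged += fit.converged
        d = params_to_dict(fit.params)
        estimates[r] = [d[n] for n in free]
    truth = np.array([true_dict[n] for n in free])
    err = estimates - truth
    return pd.DataFrame(
        {
            "true": truth,
            "bias": err.mean(axis=0),
            "rmse": np.sqrt((err**2).mean(axis=0)),
            "n_reps": n_reps,
            "n_converged": n_converged,
        },
        index=pd.Index(free, name="parameter"),
    )


def _fmt(x: float) -> str:
    return f"{x:.5f}".rstrip("0").rstrip(".") if abs(x) < 1e6 else f"{x:.5g}"


def render_equation(family: ModelFamily, params) -> str:
    """Render the fitted equation with numeric coefficients substituted."""
    family = ModelFamily(family)
    d = params_to_dict(params)
    if family is ModelFamily.BOLTZMANN:
        return (
            f"y = {_fmt(d['A2'])} + ({_fmt(d['A1'] - d['A2'])})"
            f"/(1 + e^((x - {_fmt(d['x0'])})/{_fmt(d['dx'])}))"
        )
    if family is ModelFamily.POWER_LOGISTIC:
        return (
            f"y = {_fmt(d['A2'])} + ({_fmt(d['A1'] - d['A2'])})"
            f"/(1 + (x/{_fmt(d['x0'])})^{_fmt(d['p'])})"
        )
    if family is ModelFamily.LOGISTIC_GROWTH:
        return (
            f"X(t) = ({_fmt(d['X0'])}*{_fmt(d['Xmax'])}*e^({_fmt(d['mu_m'])}*t))"
            f"/({_fmt(d['Xmax'] - d['X0'])} + {_fmt(d['X0'])}*e^({_fmt(d['mu_m'])}*t))"
        )
    return (
        f"P(t) = {_fmt(d['P0'])} + {_fmt(d['alpha'])}*(X(t) - {_fmt(d['X0'])})"
        f" + {_fmt(d['beta'])}*({_fmt(d['Xmax'])}/{_fmt(d['mu_m'])})"
        f"*ln(1 + {_fmt(d['X0'])}*(e^({_fmt(d['mu_m'])}*t) - 1)/{_fmt(d['Xmax'])})"
    )
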