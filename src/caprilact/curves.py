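"""Lactation-curve model registry and per-lactation least-squares fitting.

The registry ships a classical subset of lactation-curve models: the
five-parameter Ali–Schaeffer polynomial (the standard choice for milk yield
and components), the reciprocal-quadratic parabolic yield-density curve
(suited to somatic cell count), Wood's incomplete gamma, Wilmink's
exponential, and three further linear forms.  New models can be registered
at run time.

Fitting is nonlinear least squares under a Levenberg–Marquardt regime with a
small multi-start grid around moment-based initial values, a relative
convergence tolerance of 1e-8 and at most 2000 iterations.  For models that
are linear in their parameters the ordinary-least-squares solution is the
first grid start, so the iterative fit coincides with the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError, ValidationError

#: Scaling horizon T for the Ali–Schaeffer time axis x = t / T (days).
AS_SCALE = 340.0

#: Wilmink decay constant (1/days), the classical fixed value.
WILMINK_K = 0.05


def _check_t(t):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0):
        raise DomainError("days in milk must be strictly positive")
    return t


def ali_schaeffer(t, b, scale: float = AS_SCALE):
    """Ali–Schaeffer five-parameter curve.

    y(t) = b0 + b1*x + b2*x^2 + b3*ln(1/x) + b4*ln^2(1/x),  x = t/scale.

    Linear in b; b0 is the curve level, b1/b2 govern the late decline
    (persistency), b3/b4 the early rise.
    """
    x = _check_t(t) / scale
    l = np.log(1.0 / x)
    b = np.asarray(b, dtype=float)
    return b[0] + b[1] * x + b[2] * x**2 + b[3] * l + b[4] * l**2


def ali_schaeffer_design(t, scale: float = AS_SCALE) -> np.ndarray:
    """Design matrix with columns (1, x, x^2, ln(1/x), ln^2(1/x))."""
    x = _check_t(t) / scale
    l = np.log(1.0 / x)
    return np.column_stack([np.ones_like(x), x, x**2, l, l**2])


def parabolic_yield_density(t, b):
    """Reciprocal-quadratic curve y(t) = 1 / (b0 + b1*t + b2*t^2).

    Defined only where the denominator is strictly positive.
    """
    t = _check_t(t)
    b = np.asarray(b, dtype=float)
    den = b[0] + b[1] * t + b[2] * t**2
    if np.any(den <= 0):
        raise DomainError("parabolic yield-density denominator <= 0 on range")
    return 1.0 / den


def wood(t, b):
    """Wood incomplete-gamma curve y(t) = b0 * t^b1 * exp(-b2*t)."""
    t = _check_t(t)
    b = np.asarray(b, dtype=float)
    return b[0] * t ** b[1] * np.exp(-b[2] * t)


def wilmink(t, b, k: float = WILMINK_K):
    """Wilmink curve y(t) = b0 + b1*exp(-k*t) + b2*t with fixed k."""
    t = _check_t(t)
    b = np.asarray(b, dtype=float)
    return b[0] + b[1] * np.exp(-k * t) + b[2] * t


def quadratic(t, b):
    """Quadratic polynomial y(t) = b0 + b1*t + b2*t^2."""
    t = _check_t(t)
    b = np.asarray(b, dtype=float)
    return b[0] + b[1] * t + b[2] * t**2


def inverse_quadratic(t, b):
    """Nelder inverse polynomial y(t) = t / (b0 + b1*t + b2*t^2)."""
    t = _check_t(t)
    b = np.asarray(b, dtype=float)
    den = b[0] + b[1] * t + b[2] * t**2
    if np.any(den <= 0):
        raise DomainError("inverse-quadratic denominator <= 0 on range")
    return t / den


def mixed_log(t, b):
    """Mixed log model y(t) = b0 + b1*sqrt(t) + b2*ln(t)."""
    t = _check_t(t)
    b = np.asarray(b, dtype=float)
    return b[0] + b[1] * np.sqrt(t) + b[2] * np.log(t)


@dataclass(frozen=True)
class LactationModel:
    """A candidate lactation-curve model.

    ``fn(t, b)`` evaluates the curve; ``design`` (linear models only)
    returns the regression columns so the OLS solution can seed the fit;
    ``init`` maps observed (t, y) to a list of starting vectors.
    """

    model_id: str
    k: int
    fn: Callable
    linear_in_params: bool
    init: Callable
    design: Optional[Callable] = None


@dataclass
class FitResult:
    """Outcome of fitting one model to one lactation's (t, y) data."""

    model_id: str
    b: np.ndarray
    converged: bool
    iterations: int
    rss: float
    residuals: np.ndarray
    n: int
    t: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.b)


def _ols_starts(design):
    def init(t, y):
        A = design(t)
        b, *_ = np.linalg.lstsq(A, y, rcond=None)
        return [b]

    return init


def _wood_starts(t, y):
    # log-linearization: ln y = ln b0 + b1 ln t - b2 t, then a small
    # factorial grid around the moment-based point
    ypos = np.clip(y, 1e-9, None)
    A = np.column_stack([np.ones_like(t), np.log(t), -t])
    c, *_ = np.linalg.lstsq(A, np.log(ypos), rcond=None)
    b0 = np.array([np.exp(c[0]), c[1], c[2]])
    starts = [b0]
    for f1 in (0.5, 2.0):
        starts.append(b0 * np.array([f1, 1.0, 1.0]))
        starts.append(b0 * np.array([1.0, f1, f1]))
    starts.append(np.array([max(np.mean(ypos), 1e-6), 0.1, 0.001]))
    return starts


def _pyd_starts(t, y):
    # regress 1/y on (1, t, t^2) where y > 0
    ypos = np.clip(y, 1e-9, None)
    A = np.column_stack([np.ones_like(t), t, t**2])
    b0, *_ = np.linalg.lstsq(A, 1.0 / ypos, rcond=None)
    starts = [b0]
    m = 1.0 / max(np.mean(ypos), 1e-9)
    starts.append(np.array([m, 0.0, 0.0]))
    starts.append(b0 * np.array([1.5, 0.5, 0.5]))
    return starts


_REGISTRY: dict[str, LactationModel] = {}


def register_model(model: LactationModel, *, overwrite: bool = False) -> None:
    """Add a model to the registry; duplicate ids raise unless ``overwrite``."""
    if model.model_id in _REGISTRY and not overwrite:
        raise ValidationError(f"model id {model.model_id!r} already registered")
    _REGISTRY[model.model_id] = model


def registry() -> list[LactationModel]:
    """All registered models (built-ins plus user additions)."""
    return list(_REGISTRY.values())


def get_model(model_id: str) -> LactationModel:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise ValidationError(
            f"unknown model {model_id!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def _register_builtins():
    lin = [
        ("ali_schaeffer", 5, ali_schaeffer, ali_schaeffer_design),
        (
            "wilmink",
            3,
            wilmink,
            lambda t: np.column_stack(
                [np.ones_like(t), np.exp(-WILMINK_K * np.asarray(t, float)), t]
            ),
        ),
        (
            "quadratic",
            3,
            quadratic,
            lambda t: np.column_stack(
                [np.ones_like(np.asarray(t, float)), t, np.asarray(t, float) ** 2]
            ),
        ),
        (
            "mixed_log",
            3,
            mixed_log,
            lambda t: np.column_stack(
                [
                    np.ones_like(np.asarray(t, float)),
                    np.sqrt(np.asarray(t, float)),
                    np.log(np.asarray(t, float)),
                ]
            ),
        ),
    ]
    for mid, k, fn, design in lin:
        register_model(
            LactationModel(
                model_id=mid,
                k=k,
                fn=fn,
                linear_in_params=True,
                init=_ols_starts(design),
                design=design,
            )
        )
    register_model(
        LactationModel(
            model_id="parabolic_yield_density",
            k=3,
            fn=parabolic_yield_density,
            linear_in_params=False,
            init=_pyd_starts,
        )
    )
    register_model(
        LactationModel(
            model_id="inverse_quadratic",
            k=3,
            fn=inverse_quadratic,
            linear_in_params=False,
            init=_pyd_starts,
        )
    )
    register_model(
        LactationModel(
            model_id="wood", k=3, fn=wood, linear_in_params=False, init=_wood_starts
        )
    )


_register_builtins()


def fit_lactation(
    t,
    y,
    model: LactationModel,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FitResult:
    """Least-squares fit of one model to one lactation.

    Runs a Levenberg–Marquardt minimizer from every grid start and keeps
    the lowest-RSS solution.  Divergence of every start yields a
    ``converged=False`` result rather than an exception; too few points
    (n < k) raise :class:`InsufficientDataError`.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValidationError("t and y must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("days in milk must be strictly increasing")
    n = len(y)
    if n < model.k:
        raise InsufficientDataError(
            f"{model.model_id}: n={n} records < k={model.k} parameters"
        )

    def resid(b):
        with np.errstate(all="ignore"):
            try:
                r = y - model.fn(t, b)
            except DomainError:
                return np.full(n, 1e12)
        return np.where(np.isfinite(r), r, 1e12)

    best = None
    for b0 in model.init(t, y):
        try:
            sol = least_squares(
                resid,
                np.asarray(b0, dtype=float),
                method="lm",
                xtol=tol,
                ftol=tol,
                gtol=tol,
                max_nfev=max_iter,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if not np.isfinite(rss) or rss >= 1e20:
            continue
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return FitResult(
            model_id=model.model_id,
            b=np.full(model.k, np.nan),
            converged=False,
            iterations=max_iter,
            rss=np.inf,
            residuals=np.full(n, np.nan),
            n=n,
            t=t,
            y=y,
        )
    rss, sol = best
    return FitResult(
        model_id=model.model_id,
        b=sol.x.copy(),
        converged=bool(sol.success) and sol.nfev <= max_iter,
        iterations=int(sol.nfev),
        rss=rss,
        residuals=y - model.fn(t, sol.x),
        n=n,
        t=t,
        y=y,
    )
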