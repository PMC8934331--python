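"""Total-error metric, selection-strength sweeps and convergence-slope fits.

The accuracy of an order-``k`` approximation is quantified by the L2-in-time
total error

    E(eps) = sqrt( integral_0^Tmax  sum_c (ref_c(t) - approx_c(t))^2 dt ),

computed by composite trapezoid quadrature on a shared uniform grid.  Sweeping
the selection strength over a logarithmic grid and fitting log10 E against
log10 eps by ordinary least squares recovers the truncation-order exponent:
E scales as eps^{k+1} while the sweep stays inside the asymptotic regime of
the expansion (see docs/methods.md for the crossovers that bound that
regime).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

from . import lotka_volterra as lv
from . import public_goods as pg
from .core import Trajectory
from .exceptions import GridMismatchError, IntegrationError

__all__ = [
    "ErrorCurve",
    "SlopeFit",
    "total_error",
    "run_scaling_experiment",
    "fit_loglog_slope",
    "MODELS",
]

#: Time-scale compatibility for trajectory comparison: trajectories must be
#: parametrised by the same clock.
_T_CLOCK = {"inner_t": "t", "composite_t": "t", "outer_tau": "tau"}

#: Default quadrature resolution (points per unit time) and hard cap.
POINTS_PER_UNIT_TIME = 20
MAX_GRID_POINTS = 10**6


@dataclass(frozen=True)
class ErrorCurve:
    """Total error E per selection strength, plus experiment metadata."""

    eps_values: np.ndarray
    errors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps_values, dtype=float)
        err = np.asarray(self.errors, dtype=float)
        object.__setattr__(self, "eps_values", eps)
        object.__setattr__(self, "errors", err)
        if eps.size != err.size:
            raise ValueError("eps grid and errors differ in length")
        d = np.diff(eps)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("eps grid must be strictly monotone")
        if np.any(eps <= 0):
            raise ValueError("selection strengths must be positive")
        if np.any(err < 0):
            raise ValueError("errors must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epsilon": self.eps_values, "error": self.errors})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of log10(E) on log10(eps)."""

    slope: float
    intercept: float
    residual_rms: float
    n_points: int


def total_error(
    reference: Trajectory,
    approx: Trajectory,
    components: Sequence[str] | None = None,
) -> float:
    """L2-in-time distance between two trajectories on an identical grid."""
    if _T_CLOCK[reference.timescale] != _T_CLOCK[approx.timescale]:
        raise GridMismatchError(
            f"cannot compare a {reference.timescale!r} trajectory with a "
            f"{approx.timescale!r} one"
        )
    if len(reference) != len(approx) or not np.allclose(
        reference.times, approx.times, rtol=1e-12, atol=1e-12
    ):
        raise GridMismatchError("trajectories are sampled on different time grids")
    if components is None:
        components = [c for c in reference.columns if c in approx.columns]
        if not components:
            raise ValueError("trajectories share no state columns")
    sq = np.zeros_like(reference.times)
    for c in components:
        sq += (reference[c] - approx[c]) ** 2
    return float(np.sqrt(np.trapezoid(sq, reference.times)))


_DEFAULT_COMPONENTS = {"public_goods": ("u", "s"), "lotka_volterra": ("u",)}

MODELS = {
    "public_goods": pg,
    "lotka_volterra": lv,
}


def _simulate(model: str, params, level: str, t_grid) -> Trajectory:
    if model == "public_goods":
        return pg.simulate(params, level, t_grid)
    return lv.lv_assemble_approximation(level, params, t_grid)


def uniform_grid(t_max: float, points_per_unit_time: int = POINTS_PER_UNIT_TIME) -> np.ndarray:
    """Uniform quadrature grid over [0, t_max], capped at MAX_GRID_POINTS."""
    n = min(int(round(points_per_unit_time * t_max)) + 1, MAX_GRID_POINTS)
    return np.linspace(0.0, t_max, max(n, 2))


def run_scaling_experiment(
    model: str,
    level: str,
    eps_grid: Sequence[float],
    t_max: float,
    base_params=None,
    components: Sequence[str] | None = None,
    points_per_unit_time: int = POINTS_PER_UNIT_TIME,
) -> ErrorCurve:
    """Total error of ``level`` versus the full model across a selection sweep.

    For each selection strength the full model and the requested
    approximation are integrated from identical initial conditions on a
    shared uniform grid over ``[0, t_max]`` and compared with
    :func:`total_error`.  Integrator failures at individual sweep points are
    reported as warnings and the points dropped.

    Parameters
    ----------
    model
        ``"public_goods"`` (small parameter kappa) or ``"lotka_volterra"``
        (small parameter epsilon).
    level
        Approximation level understood by the model's simulator.
    base_params
        Model parameter object or dict; its small parameter is overridden by
        each sweep value in turn.
    components
        State columns entering the error; defaults to (u, s) for the public
        goods model and the wild-type fraction u alone for Lotka--Volterra.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    mod = MODELS[model]
    if base_params is None:
        base_params = {}
    if isinstance(base_params, dict):
        base_params = mod.params_from_dict(base_params)
    if components is None:
        components = _DEFAULT_COMPONENTS[model]

    eps_grid = np.asarray(eps_grid, dtype=float)
    t_grid = uniform_grid(t_max, points_per_unit_time)
    eps_kept, errors = [], []
    for eps in eps_grid:
        params = mod.with_epsilon(base_params, eps)
        try:
            ref = _simulate(model, params, "full", t_grid)
            approx = _simulate(model, params, level, t_grid)
        except IntegrationError as exc:  # pragma: no cover - defensive
            warnings.warn(
                f"sweep point eps={eps:g} dropped: {exc}", RuntimeWarning,
                stacklevel=2,
            )
            continue
        eps_kept.append(eps)
        errors.append(total_error(ref, approx, components))
    return ErrorCurve(
        eps_values=np.array(eps_kept),
        errors=np.array(errors),
        meta={
            "model": model,
            "level": level,
            "t_max": float(t_max),
            "components": tuple(components),
            "points_per_unit_time": points_per_unit_time,
        },
    )


def fit_loglog_slope(curve: ErrorCurve) -> SlopeFit:
    """Ordinary least squares of log10(E) on log10(eps).

    Non-positive errors carry no information on a log scale; they are
    excluded with a warning.  At least four usable points are required.
    """
    mask = curve.errors > 0
    if np.any(~mask):
        warnings.warn(
            f"{int((~mask).sum())} non-positive error value(s) excluded from "
            "the log-log fit", RuntimeWarning, stacklevel=2,
        )
    x = np.log10(curve.eps_values[mask])
    y = np.log10(curve.errors[mask])
    if x.size < 4:
        raise ValueError("need at least four positive error values to fit a slope")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return SlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(x.size),
    )
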