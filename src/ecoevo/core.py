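"""Generic weak-selection machinery for density- and frequency-dependent dynamics.

The starting point is a population of ``N`` genotypes with per-capita birth
rate ``F_i(x) = f_i(u) g(s)`` and death rate ``D_i(x) = d_i(u) h(s)``, where
``u`` is the vector of genotype frequencies and ``s`` the total population
size.  Under weak selection the frequency-dependent factors decompose as

    f_i(u) = f0(u) + eps * phi_i(u),    d_i(u) = d0(u) + eps * eta_i(u),

with a common baseline ``f0``/``d0`` and genotype-specific perturbations of
order ``eps << 1``.  In the ``(u, s)`` variables the dynamics then split into
a fast ecological part (size ``s`` relaxes, frequencies frozen) and a slow
evolutionary part on ``tau = eps * t`` (a density-modulated replicator
equation at the ecological equilibrium).  This module provides the change of
variables, the full coupled system, the zeroth-order inner and outer systems,
the ecological-equilibrium solver, a thin adaptive-ODE integration wrapper
and the matched-asymptotics composite assembly.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import (
    DegeneratePopulationError,
    GridMismatchError,
    IntegrationError,
    NoEquilibriumError,
    UnmatchedExpansionError,
    UnstableEquilibriumError,
)

__all__ = [
    "FREQ_TOL",
    "RateDecomposition",
    "ModelSpec",
    "FreqSizeState",
    "Trajectory",
    "EquilibriumResult",
    "frequencies_from_abundances",
    "abundances_from_frequencies",
    "full_rhs",
    "inner_zeroth_rhs",
    "ecological_equilibrium",
    "outer_zeroth_rhs",
    "integrate",
    "simulate_full",
    "composite_zeroth",
]

#: Tolerance on simplex membership of frequency vectors.
FREQ_TOL = 1e-9

#: Time-scale tags.  ``inner_t`` and ``composite_t`` are parametrised by the
#: fast time ``t``; ``outer_tau`` by the slow time ``tau = eps * t``.  Mixing
#: the two parametrisations in arithmetic is a :class:`GridMismatchError`.
TIMESCALES = ("inner_t", "outer_tau", "composite_t")

ScalarFn = Callable[[float], float]
FreqFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class RateDecomposition:
    """Weak-selection factorisation of the per-capita rates.

    Parameters
    ----------
    f0, d0
        Baseline frequency-dependent birth/death factors, functions of the
        frequency vector ``u`` (units 1/time).
    phi, eta
        Length-``N`` sequences of genotype-specific perturbations to the
        birth/death factors (dimensionless multipliers of ``eps``).
    g, h
        Density-dependent factors, functions of the total size ``s``
        (dimensionless).
    """

    f0: FreqFn
    d0: FreqFn
    phi: tuple[FreqFn, ...]
    eta: tuple[FreqFn, ...]
    g: ScalarFn
    h: ScalarFn

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", tuple(self.phi))
        object.__setattr__(self, "eta", tuple(self.eta))
        if len(self.phi) != len(self.eta):
            raise ValueError("phi and eta must have the same length")

    @property
    def n_types(self) -> int:
        return len(self.phi)

    def phi_values(self, u: np.ndarray) -> np.ndarray:
        return np.array([p(u) for p in self.phi], dtype=float)

    def eta_values(self, u: np.ndarray) -> np.ndarray:
        return np.array([e(u) for e in self.eta], dtype=float)

    def birth_rates(self, u: np.ndarray, epsilon: float) -> np.ndarray:
        """Recompose f_i = f0 + eps * phi_i."""
        return self.f0(u) + epsilon * self.phi_values(u)

    def death_rates(self, u: np.ndarray, epsilon: float) -> np.ndarray:
        """Recompose d_i = d0 + eps * eta_i."""
        return self.d0(u) + epsilon * self.eta_values(u)


@dataclass(frozen=True)
class ModelSpec:
    """A concrete model: genotype count, rate decomposition and selection strength."""

    n_types: int
    rates: RateDecomposition
    epsilon: float

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("a weak-selection model needs at least two genotypes")
        if self.epsilon < 0:
            raise ValueError("selection strength must be non-negative")
        if self.rates.n_types != self.n_types:
            raise ValueError(
                f"rate decomposition has {self.rates.n_types} genotypes, "
                f"model declares {self.n_types}"
            )


@dataclass(frozen=True)
class FreqSizeState:
    """Point in (frequency simplex) x (total size >= 0)."""

    u: np.ndarray
    s: float

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "s", float(self.s))
        if abs(u.sum() - 1.0) > FREQ_TOL:
            raise ValueError(f"frequencies sum to {u.sum()!r}, not 1")
        if np.any(u < -FREQ_TOL) or np.any(u > 1.0 + FREQ_TOL):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.s < 0:
            raise ValueError("total population size must be non-negative")

    @property
    def n_types(self) -> int:
        return self.u.size


@dataclass
class Trajectory:
    """Named state columns sampled on a strictly increasing time grid.

    ``timescale`` records whether ``times`` is the fast time ``t``
    (``"inner_t"``, ``"composite_t"``) or the slow time ``tau``
    (``"outer_tau"``), so that trajectories living on different clocks cannot
    be silently combined.
    """

    times: np.ndarray
    states: dict[str, np.ndarray]
    timescale: str = "inner_t"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need a 1-d time grid with at least two points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.timescale not in TIMESCALES:
            raise ValueError(f"unknown timescale tag {self.timescale!r}")
        self.states = {k: np.asarray(v, dtype=float) for k, v in self.states.items()}
        for name, col in self.states.items():
            if col.shape != self.times.shape:
                raise ValueError(f"column {name!r} does not match the time grid")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[name]

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.states)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, **self.states})
        df["timescale"] = self.timescale
        return df

    def to_csv(self, path) -> None:
        """Write ``time,<state columns>,timescale`` with 15 significant digits."""
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


@dataclass(frozen=True)
class EquilibriumResult:
    """Root of the ecological balance r(S) = g(S) f0(u) - h(S) d0(u)."""

    s_star: float
    stable: bool
    bracket: tuple[float, float]
    residual: float
    roots: tuple[tuple[float, bool], ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# change of variables


def frequencies_from_abundances(x: Sequence[float]) -> FreqSizeState:
    """Map abundances ``x_i`` to frequencies ``u_i = x_i / sum(x)`` and size ``s``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    s = x.sum()
    if s <= 0:
        raise DegeneratePopulationError(
            "cannot form frequencies for an extinct population (sum(x) == 0)"
        )
    return FreqSizeState(u=x / s, s=s)


def abundances_from_frequencies(state: FreqSizeState) -> np.ndarray:
    """Inverse change of variables, ``x_i = s * u_i``."""
    return state.s * state.u


# ---------------------------------------------------------------------------
# right-hand sides


def full_rhs(state: FreqSizeState, model: ModelSpec) -> tuple[np.ndarray, float]:
    """Exact (u, s) dynamics of the weak-selection model.

    du_i/dt = eps * u_i [ (phi_i - phibar) g(s) - (eta_i - etabar) h(s) ]
    ds/dt   = eps * s [ g(s) phibar - h(s) etabar ] + s [ g(s) f0 - h(s) d0 ]

    Extinction (s == 0) is absorbing: all derivatives vanish there.
    """
    u, s = state.u, state.s
    if s == 0.0:
        return np.zeros_like(u), 0.0
    rates = model.rates
    phi = rates.phi_values(u)
    eta = rates.eta_values(u)
    phibar = float(u @ phi)
    etabar = float(u @ eta)
    gs = rates.g(s)
    hs = rates.h(s)
    du = model.epsilon * u * ((phi - phibar) * gs - (eta - etabar) * hs)
    ds = model.epsilon * s * (gs * phibar - hs * etabar) + s * (
        gs * rates.f0(u) - hs * rates.d0(u)
    )
    return du, float(ds)


def inner_zeroth_rhs(state: FreqSizeState, model: ModelSpec) -> tuple[np.ndarray, float]:
    """Zeroth-order inner (ecological) system: frequencies frozen, size relaxes.

    du_i0/dt = 0 exactly;  ds0/dt = s0 [ g(s0) f0(u0) - h(s0) d0(u0) ].
    """
    u, s = state.u, state.s
    du = np.zeros_like(u)
    if s == 0.0:
        return du, 0.0
    rates = model.rates
    ds = s * (rates.g(s) * rates.f0(u) - rates.h(s) * rates.d0(u))
    return du, float(ds)


def outer_zeroth_rhs(
    U0: np.ndarray,
    model: ModelSpec,
    s_star: Union[float, EquilibriumResult],
) -> np.ndarray:
    """Zeroth-order outer (evolutionary) system on tau = eps * t.

    A replicator equation modulated by the density factors evaluated at the
    ecological equilibrium ``S0*``:

    dU_i0/dtau = U_i0 [ (phi_i - phibar) g(S0*) - (eta_i - etabar) h(S0*) ].
    """
    if isinstance(s_star, EquilibriumResult):
        if not s_star.stable:
            raise UnstableEquilibriumError(
                "outer dynamics require a stable ecological equilibrium"
            )
        s_star = s_star.s_star
    U0 = np.asarray(U0, dtype=float)
    rates = model.rates
    phi = rates.phi_values(U0)
    eta = rates.eta_values(U0)
    phibar = float(U0 @ phi)
    etabar = float(U0 @ eta)
    gs = rates.g(float(s_star))
    hs = rates.h(float(s_star))
    return U0 * ((phi - phibar) * gs - (eta - etabar) * hs)


# ---------------------------------------------------------------------------
# ecological equilibrium


def _fd_derivative(fn: ScalarFn, x: float) -> float:
    # central differences; g, h are opaque user callables
    step = 1e-6 * max(1.0, abs(x))
    return (fn(x + step) - fn(x - step)) / (2.0 * step)


def ecological_equilibrium(
    u0: np.ndarray,
    model: ModelSpec,
    bracket: tuple[float, float],
    s_init: float | None = None,
    n_scan: int = 200,
) -> EquilibriumResult:
    """Solve g(S) f0(u0) = h(S) d0(u0) for the equilibrium density ``S0* > 0``.

    The bracket is scanned at ``n_scan`` uniform points for sign changes of
    the residual ``r(S)``; each is refined by Brent's method.  Stability uses
    the condition ``g'(S0*) f0(u0) < h'(S0*) d0(u0)`` with central finite
    differences.  With several stable roots the one closest to the long-time
    limit of the zeroth-order inner dynamics started from ``(u0, s_init)`` is
    selected (the initial condition decides which basin the ecology lands in);
    ``s_init`` is then required.
    """
    u0 = np.asarray(u0, dtype=float)
    rates = model.rates
    f0v = rates.f0(u0)
    d0v = rates.d0(u0)

    def r(S: float) -> float:
        return rates.g(S) * f0v - rates.h(S) * d0v

    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0.0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    grid = np.linspace(lo, hi, n_scan)
    vals = np.array([r(S) for S in grid])

    roots: list[float] = []
    for i in range(n_scan - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            if not roots or abs(a - roots[-1]) > 1e-9 * max(1.0, abs(a)):
                roots.append(float(a))
            continue
        if fa * fb < 0:
            root = brentq(r, a, b, xtol=1e-12, rtol=4 * np.finfo(float).eps)
            roots.append(float(root))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        raise NoEquilibriumError(
            f"no sign change of g(S) f0 - h(S) d0 in bracket ({lo}, {hi})"
        )

    def stable_at(S: float) -> bool:
        return _fd_derivative(rates.g, S) * f0v < _fd_derivative(rates.h, S) * d0v

    annotated = tuple((S, stable_at(S)) for S in roots)
    stable_roots = [S for S, st in annotated if st]

    if len(stable_roots) == 1:
        chosen, chosen_stable = stable_roots[0], True
    elif len(stable_roots) == 0:
        chosen, chosen_stable = annotated[0]
    else:
        if s_init is None:
            raise ValueError(
                "multiple stable equilibria in bracket; pass s_init so the "
                "attained one can be selected from the inner dynamics"
            )
        spec_inner = lambda t, y: [y[0] * r(y[0])]  # noqa: E731 - local rhs
        sol = solve_ivp(
            spec_inner, (0.0, 1e4), [float(s_init)], method="LSODA",
            rtol=1e-10, atol=1e-12,
        )
        if not sol.success:
            raise IntegrationError(sol.message)
        s_end = float(sol.y[0, -1])
        chosen = min(stable_roots, key=lambda S: abs(S - s_end))
        chosen_stable = True

    residual = abs(r(chosen))
    scale = max(1.0, abs(rates.g(chosen) * f0v))
    if residual > 1e-10 * scale:
        raise NoEquilibriumError(
            f"root refinement left residual {residual:.3e} at S={chosen!r}"
        )
    return EquilibriumResult(
        s_star=chosen, stable=chosen_stable, bracket=(lo, hi),
        residual=residual, roots=annotated,
    )


# ---------------------------------------------------------------------------
# integration


def integrate(
    rhs: Callable[[float, np.ndarray], Sequence[float]],
    y0: Sequence[float],
    times: Sequence[float],
    names: Sequence[str] | None = None,
    timescale: str = "inner_t",
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Adaptive stiff/non-stiff integration sampled on a supplied grid.

    Tolerances default to rtol=1e-10, atol=1e-12, far below the leading
    perturbation error, so measured error-scaling slopes reflect the
    approximation order rather than the solver.
    """
    times = np.asarray(times, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    d0 = np.asarray(rhs(times[0], y0), dtype=float)
    if not np.all(np.isfinite(d0)):
        raise IntegrationError("right-hand side is not finite at the initial state")
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, t_eval=times,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError("ODE solver produced non-finite values")
    if names is None:
        names = [f"y{i}" for i in range(y0.size)]
    states = {name: sol.y[i] for i, name in enumerate(names)}
    return Trajectory(times=times, states=states, timescale=timescale)


def simulate_full(
    model: ModelSpec,
    state0: FreqSizeState,
    times: Sequence[float],
    **kwargs,
) -> Trajectory:
    """Integrate the full (u, s) system of a generic model.

    Only the first ``N - 1`` frequencies are integrated; the last is closed
    by ``u_N = 1 - sum(u_i)``, which removes round-off drift off the simplex.
    Negative round-off down to -1e-9 is clipped and the output renormalised.
    """
    n = model.n_types

    def closed_u(y: np.ndarray) -> np.ndarray:
        u = np.empty(n)
        u[:-1] = y[:-1]
        u[-1] = 1.0 - y[:-1].sum()
        return np.clip(u, -FREQ_TOL, None)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        u = closed_u(y)
        u = np.clip(u, 0.0, None)
        total = u.sum()
        if total > 0:
            u = u / total
        s = max(y[-1], 0.0)
        du, ds = full_rhs(FreqSizeState(u=u, s=s), model)
        return np.append(du[:-1], ds)

    y0 = np.append(state0.u[:-1], state0.s)
    names = [f"u{i + 1}" for i in range(n - 1)] + ["s"]
    traj = integrate(rhs, y0, times, names=names, **kwargs)

    cols = np.vstack([traj[f"u{i + 1}"] for i in range(n - 1)])
    last = 1.0 - cols.sum(axis=0)
    full = np.vstack([cols, last])
    if np.any(full < -FREQ_TOL):
        raise IntegrationError("frequencies drifted below the simplex tolerance")
    full = np.clip(full, 0.0, None)
    full /= full.sum(axis=0)
    states = {f"u{i + 1}": full[i] for i in range(n)}
    states["s"] = traj["s"]
    return Trajectory(times=traj.times, states=states, timescale=traj.timescale)


# ---------------------------------------------------------------------------
# matched asymptotics


def _overlap_mapping(
    overlap: Union[FreqSizeState, Mapping[str, float]],
    columns: Sequence[str],
) -> dict[str, float]:
    if isinstance(overlap, FreqSizeState):
        n = overlap.n_types
        if n == 2 and set(columns) == {"u", "s"}:
            return {"u": float(overlap.u[0]), "s": overlap.s}
        m = {f"u{i + 1}": float(overlap.u[i]) for i in range(n)}
        m["s"] = overlap.s
        return m
    return {k: float(v) for k, v in overlap.items()}


def composite_zeroth(
    inner: Trajectory,
    outer: Trajectory,
    overlap_state: Union[FreqSizeState, Mapping[str, float]],
    epsilon: float,
    match_tol: float = 1e-6,
) -> Trajectory:
    """Uniformly valid composite: inner(t) + outer(eps * t) - overlap.

    The overlap is the common limit ``lim_{t->inf} inner = lim_{tau->0} outer``;
    disagreement of either branch with it beyond ``match_tol`` raises
    :class:`UnmatchedExpansionError`.  ``outer`` must be sampled on the grid
    ``tau = eps * inner.times``.
    """
    if inner.timescale != "inner_t":
        raise GridMismatchError("inner trajectory must be on the fast time scale")
    if outer.timescale != "outer_tau":
        raise GridMismatchError("outer trajectory must be on the slow time scale")
    if epsilon <= 0:
        raise ValueError("composite assembly needs epsilon > 0")
    if not np.allclose(outer.times, epsilon * inner.times, rtol=1e-12, atol=1e-15):
        raise GridMismatchError("outer grid is not eps * inner grid")
    common = [c for c in inner.columns if c in outer.columns]
    if not common:
        raise ValueError("inner and outer trajectories share no state columns")
    overlap = _overlap_mapping(overlap_state, common)

    for col in common:
        a = overlap[col]
        if abs(inner[col][-1] - a) > match_tol:
            raise UnmatchedExpansionError(
                f"inner long-time limit of {col!r} ({inner[col][-1]!r}) does not "
                f"match the overlap value {a!r}"
            )
        if abs(outer[col][0] - a) > match_tol:
            raise UnmatchedExpansionError(
                f"outer initial value of {col!r} ({outer[col][0]!r}) does not "
                f"match the overlap value {a!r}"
            )
    states = {c: inner[c] + outer[c] - overlap[c] for c in common}
    return Trajectory(times=inner.times, states=states, timescale="composite_t")

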