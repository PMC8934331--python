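"""Prey plus two competing predators: perturbation analysis of invader advantage.

The full model is the three-species Lotka--Volterra system

    dx/dt  = alpha x - beta x (y1 + (1 + eps) y2)
    dy1/dt = delta x y1 - gamma y1
    dy2/dt = delta (1 + eps) x y2 - gamma y2,

where ``x`` is the prey, ``y1`` the wild-type predator and ``y2`` an invading
predator that is a factor ``1 + eps`` better at converting prey.  In the
variables prey ``x``, wild-type fraction ``u = y1/(y1 + y2)`` and total
predator population ``s = y1 + y2`` the system becomes

    dx/dt = alpha x - beta x s (1 + eps (1 - u))
    du/dt = -eps delta x u (1 - u)
    ds/dt = eps delta s x (1 - u) + delta s x - gamma s.

Unlike the logistic case the fast (ecological) dynamics converge to a limit
cycle, not a point, so no composite solution exists; inner and outer
approximations are compared with the full model separately.  To zeroth order
the outer dynamics put prey and predators on the coexistence steady state
``X0 = gamma/delta``, ``S0 = alpha/beta`` and reduce the wild-type fraction to
a replicator equation with constant selection coefficient ``-gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Callable, Sequence

import numpy as np

from . import core
from .core import RateDecomposition, Trajectory

__all__ = [
    "LVParams",
    "LVState",
    "initial_state",
    "lv_full_rhs",
    "lv_uvs_rhs",
    "predator_rate_decomposition",
    "lv_inner_rhs",
    "lv_outer_zeroth",
    "lv_outer_first",
    "replicator_decay",
    "lv_first_integral",
    "lv_assemble_approximation",
    "LEVELS",
]

LEVELS = ("full", "inner0", "inner1", "outer0", "outer1")


@dataclass(frozen=True)
class LVParams:
    """Rates and initial condition of the predator-competition model.

    alpha : prey growth rate (1/time)
    beta  : predation rate (1/(size * time))
    delta : conversion rate of prey into predators (1/(size * time))
    gamma : predator death rate (1/time)
    epsilon : invader advantage (dimensionless); the small parameter
    x0, y1_0, y2_0 : initial prey, wild-type and invader sizes (> 0)
    """

    alpha: float = 0.2
    beta: float = 1.0
    delta: float = 0.5
    gamma: float = 1.0
    epsilon: float = 0.05
    x0: float = 1.0
    y1_0: float = 1.0
    y2_0: float = 0.01

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.delta, self.gamma) <= 0:
            raise ValueError("all rates must be positive")
        if self.epsilon < 0:
            raise ValueError("invader advantage must be non-negative")
        if min(self.x0, self.y1_0, self.y2_0) <= 0:
            raise ValueError("initial sizes must be positive")


@dataclass(frozen=True)
class LVState:
    """Prey size, wild-type predator fraction and total predator size."""

    x: float
    u: float
    s: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.s < 0:
            raise ValueError("population sizes must be non-negative")
        if not -core.FREQ_TOL <= self.u <= 1.0 + core.FREQ_TOL:
            raise ValueError("wild-type fraction must lie in [0, 1]")


def initial_state(p: LVParams) -> LVState:
    fs = core.frequencies_from_abundances([p.y1_0, p.y2_0])
    return LVState(x=p.x0, u=float(fs.u[0]), s=fs.s)


# ---------------------------------------------------------------------------
# right-hand sides


def lv_full_rhs(
    x: float, y1: float, y2: float, p: LVParams
) -> tuple[float, float, float]:
    """The three-species system in the original abundances."""
    dx = p.alpha * x - p.beta * x * (y1 + (1.0 + p.epsilon) * y2)
    dy1 = p.delta * x * y1 - p.gamma * y1
    dy2 = p.delta * (1.0 + p.epsilon) * x * y2 - p.gamma * y2
    return dx, dy1, dy2


def lv_uvs_rhs(state: LVState, p: LVParams) -> tuple[float, float, float]:
    """The system after the change of variables to (x, u, s).

    Substituting y1 = s u, y2 = s (1 - u) gives
    y1 + (1 + eps) y2 = s (1 + eps (1 - u)), hence

        dx/dt = alpha x - beta x s (1 + eps (1 - u))
        du/dt = -eps delta x u (1 - u)
        ds/dt = eps delta s x (1 - u) + delta s x - gamma s.
    """
    x, u, s = state.x, state.u, state.s
    e = p.epsilon
    dx = p.alpha * x - p.beta * x * s * (1.0 + e * (1.0 - u))
    du = -e * p.delta * x * u * (1.0 - u)
    ds = e * p.delta * s * x * (1.0 - u) + p.delta * s * x - p.gamma * s
    return dx, du, ds


def predator_rate_decomposition(x: float, p: LVParams) -> RateDecomposition:
    """Predator subsystem as a weak-selection decomposition at frozen prey ``x``.

    The prey enters the predator rates as an external driver, so the model
    fits the generic (u, s)-framework only with ``x`` held fixed: ``f0 =
    delta x`` for both predators, ``phi = (0, delta x)`` (the invader's extra
    conversion), constant death ``d0 = gamma`` and no density dependence
    (``g = h = 1``).
    """
    return RateDecomposition(
        f0=lambda u: p.delta * x,
        d0=lambda u: p.gamma,
        phi=(lambda u: 0.0, lambda u: p.delta * x),
        eta=(lambda u: 0.0, lambda u: 0.0),
        g=lambda s: 1.0,
        h=lambda s: 1.0,
    )


def lv_inner_rhs(
    order: int, state: Sequence[float], p: LVParams
) -> tuple[float, ...]:
    """Inner (ecological, fast-time) expansion right-hand sides.

    order 0, state (x0, u0, s0): a classical one-prey/one-predator system in
    (x0, s0) with the wild-type fraction frozen:
        dx0/dt = alpha x0 - beta x0 s0
        du0/dt = 0
        ds0/dt = delta s0 x0 - gamma s0
    order 1, state (x0, u0, s0, x1, u1, s1) co-integrated:
        dx1/dt = alpha x1 - beta (x0 (s1 + s0 (1 - u0)) + x1 s0)
        du1/dt = -delta x0 u0 (1 - u0)
        ds1/dt = delta s0 x0 (1 - u0) + delta (x0 s1 + x1 s0) - gamma s1
    """
    if order == 0:
        x0, u0, s0 = state
        return (
            p.alpha * x0 - p.beta * x0 * s0,
            0.0,
            p.delta * s0 * x0 - p.gamma * s0,
        )
    if order == 1:
        x0, u0, s0, x1, u1, s1 = state
        dx0 = p.alpha * x0 - p.beta * x0 * s0
        ds0 = p.delta * s0 * x0 - p.gamma * s0
        dx1 = p.alpha * x1 - p.beta * (
            x0 * (s1 + s0 * (1.0 - u0)) + x1 * s0
        )
        du1 = -p.delta * x0 * u0 * (1.0 - u0)
        ds1 = (
            p.delta * s0 * x0 * (1.0 - u0)
            + p.delta * (x0 * s1 + x1 * s0)
            - p.gamma * s1
        )
        return dx0, 0.0, ds0, dx1, du1, ds1
    raise ValueError("inner expansion implemented to orders 0 and 1 only")


# ---------------------------------------------------------------------------
# outer systems


def lv_outer_zeroth(p: LVParams) -> tuple[float, float, Callable[[float], float]]:
    """Zeroth-order outer solution: steady densities plus replicator decay.

    X0 = gamma/delta and S0 = alpha/beta are the coexistence steady state of
    the fast dynamics; the wild-type fraction obeys
    dU0/dtau = -delta X0 U0 (1 - U0) = -gamma U0 (1 - U0).
    """
    X0 = p.gamma / p.delta
    S0 = p.alpha / p.beta

    def rhs(U0: float) -> float:
        return -p.delta * X0 * U0 * (1.0 - U0)

    return X0, S0, rhs


def lv_outer_first(
    U0: float, U1: float, p: LVParams
) -> tuple[float, float, float]:
    """First-order outer corrections (algebraic X1, S1; dynamic U1).

    X1 = -(gamma/delta) (1 - U0),  S1 = -(alpha/beta) (1 - U0),
    dU1/dtau = -delta X0 U1 (1 - 2 U0) - delta X1 U0 (1 - U0).
    """
    X0 = p.gamma / p.delta
    X1 = -(p.gamma / p.delta) * (1.0 - U0)
    S1 = -(p.alpha / p.beta) * (1.0 - U0)
    dU1 = -p.delta * X0 * U1 * (1.0 - 2.0 * U0) - p.delta * X1 * U0 * (1.0 - U0)
    return X1, S1, dU1


def replicator_decay(tau, a: float, gamma: float):
    """Closed-form solution U0(tau) = a / (a + (1 - a) e^{gamma tau}).

    Solves dU0/dtau = -gamma U0 (1 - U0) with U0(0) = a (logistic decay of
    the wild-type fraction under constant selection coefficient -gamma).
    """
    tau = np.asarray(tau, dtype=float)
    return a / (a + (1.0 - a) * np.exp(gamma * tau))


def lv_first_integral(x, s, p: LVParams):
    """Conserved quantity delta x - gamma ln x + beta s - alpha ln s of the
    zeroth-order (classical Lotka--Volterra) inner system."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    return p.delta * x - p.gamma * np.log(x) + p.beta * s - p.alpha * np.log(s)


# ---------------------------------------------------------------------------
# trajectories


def lv_assemble_approximation(
    level: str, p: LVParams, t_grid: Sequence[float]
) -> Trajectory:
    """Trajectory of the full model or an approximation, columns (x, u, s).

    Inner levels integrate the fast-time expansions and assemble
    ``x0 + eps x1`` etc.; outer levels integrate the slow dynamics on
    ``tau = eps t`` and map back to the t-grid, with X and S from the
    algebraic steady-state forms.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    st = initial_state(p)

    if level == "full":
        def rhs(tt, y):
            return lv_uvs_rhs(LVState(x=max(y[0], 0.0), u=float(np.clip(y[1], 0, 1)),
                                      s=max(y[2], 0.0)), p)
        return core.integrate(rhs, [st.x, st.u, st.s], t, names=["x", "u", "s"])

    if level == "inner0":
        rhs = lambda tt, y: lv_inner_rhs(0, y, p)  # noqa: E731
        return core.integrate(rhs, [st.x, st.u, st.s], t, names=["x", "u", "s"])

    if level == "inner1":
        rhs = lambda tt, y: lv_inner_rhs(1, y, p)  # noqa: E731
        traj = core.integrate(
            rhs, [st.x, st.u, st.s, 0.0, 0.0, 0.0], t,
            names=["x0", "u0", "s0", "x1", "u1", "s1"],
        )
        e = p.epsilon
        return Trajectory(
            times=t,
            states={"x": traj["x0"] + e * traj["x1"],
                    "u": traj["u0"] + e * traj["u1"],
                    "s": traj["s0"] + e * traj["s1"]},
        )

    if level in ("outer0", "outer1"):
        X0, S0, rhs0 = lv_outer_zeroth(p)
        a = st.u
        if p.epsilon == 0.0:
            U0 = np.full_like(t, a)
            U1 = np.zeros_like(t)
        else:
            tau = p.epsilon * t

            def rhs(tt, y):
                dU0 = rhs0(y[0])
                if level == "outer0":
                    return [dU0]
                _, _, dU1 = lv_outer_first(y[0], y[1], p)
                return [dU0, dU1]

            y0 = [a] if level == "outer0" else [a, 0.0]
            traj = core.integrate(rhs, y0, tau, timescale="outer_tau")
            U0 = traj["y0"]
            U1 = traj["y1"] if level == "outer1" else np.zeros_like(t)
        if level == "outer0":
            x = np.full_like(t, X0)
            s = np.full_like(t, S0)
            u = U0
        else:
            X1 = -(p.gamma / p.delta) * (1.0 - U0)
            S1 = -(p.alpha / p.beta) * (1.0 - U0)
            x = X0 + p.epsilon * X1
            s = S0 + p.epsilon * S1
            u = U0 + p.epsilon * U1
        return Trajectory(times=t, states={"x": x, "u": u, "s": s})

    raise ValueError(f"unknown approximation level {level!r}; choose from {LEVELS}")


def params_from_dict(d: dict) -> LVParams:
    return LVParams(**d)


def with_epsilon(p: LVParams, eps: float) -> LVParams:
    """Copy of the params with the small parameter (epsilon) replaced."""
    return replace(p, epsilon=float(eps))
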