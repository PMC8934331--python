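"""Public goods game under logistic growth: producers versus free-riders.

Producers (type 1) pay a cost ``kappa`` to generate a benefit ``beta`` that is
shared by everybody, free-riders (type 2) pay nothing:

    f1(u) = alpha (1 + beta u) - kappa,   f2(u) = alpha (1 + beta u),

with logistic density dependence ``g(s) = 1 - s/K`` on births, a constant
per-capita death rate ``mu`` and producer frequency ``u``.  The cost ``kappa``
is the small parameter: in the weak-selection decomposition ``f0 = alpha (1 +
beta u)``, ``phi = (-1, 0)``, ``eta = (0, 0)`` and ``eps = kappa``.  In the
``(u, s)`` variables the full dynamics read

    du/dt = -kappa u (1-u) (1 - s/K)
    ds/dt = -kappa s u (1 - s/K) + alpha (1 + beta u) s (1 - s/K) - mu s.

This module provides the full system, the inner (ecological) expansions at
orders 0 and 1, the outer (evolutionary) expansions at orders 0 and 1
including the algebraic equilibrium densities S0 and S1, the zeroth-order
matched-asymptotics composite, and the invariant-manifold cross-check for the
producer-frequency equation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Sequence

import numpy as np

from . import core
from .core import FreqSizeState, ModelSpec, RateDecomposition, Trajectory
from .exceptions import NoEquilibriumError

__all__ = [
    "PublicGoodsParams",
    "rate_decomposition",
    "model_spec",
    "pg_full_rhs",
    "pg_inner_rhs",
    "pg_outer_S0",
    "pg_outer_zeroth_rhs",
    "pg_outer_dS0_dtau",
    "pg_outer_S1",
    "pg_outer_first_rhs",
    "pg_composite",
    "pg_invariant_manifold_rhs",
    "simulate",
    "LEVELS",
]

LEVELS = ("full", "inner0", "inner1", "outer0", "outer1", "composite0")


@dataclass(frozen=True)
class PublicGoodsParams:
    """Parameters of the public goods model.

    alpha : baseline growth rate (1/time), > 0
    beta  : impact of the public good (dimensionless), >= 0
    kappa : cost of production (1/time); the small parameter, >= 0
    K     : carrying capacity (size units), > 0
    mu    : per-capita death rate (1/time); mu < alpha keeps the equilibrium
            density positive for every producer frequency
    a     : initial producer frequency in [0, 1]
    b     : initial total population size, > 0
    """

    alpha: float = 1.0
    beta: float = 1.0
    kappa: float = 0.1
    K: float = 1.0
    mu: float = 0.2
    a: float = 0.5
    b: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.K <= 0 or self.b <= 0:
            raise ValueError("alpha, K and b must be positive")
        if self.beta < 0 or self.kappa < 0:
            raise ValueError("beta and kappa must be non-negative")
        if not 0.0 <= self.mu < self.alpha:
            # mu < alpha (1 + beta u) for all u in [0, 1] iff mu < alpha
            raise ValueError("need 0 <= mu < alpha for a positive equilibrium density")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("initial producer frequency must lie in [0, 1]")


def rate_decomposition(p: PublicGoodsParams) -> RateDecomposition:
    """Weak-selection factorisation; index 0 is the producer."""
    return RateDecomposition(
        f0=lambda u: p.alpha * (1.0 + p.beta * u[0]),
        d0=lambda u: p.mu,
        phi=(lambda u: -1.0, lambda u: 0.0),
        eta=(lambda u: 0.0, lambda u: 0.0),
        g=lambda s: 1.0 - s / p.K,
        h=lambda s: 1.0,
    )


def model_spec(p: PublicGoodsParams) -> ModelSpec:
    """The model as an instance of the generic framework (eps = kappa)."""
    return ModelSpec(n_types=2, rates=rate_decomposition(p), epsilon=p.kappa)


def initial_state(p: PublicGoodsParams) -> FreqSizeState:
    return FreqSizeState(u=np.array([p.a, 1.0 - p.a]), s=p.b)


# ---------------------------------------------------------------------------
# full and inner systems


def pg_full_rhs(u: float, s: float, p: PublicGoodsParams) -> tuple[float, float]:
    """Exact (u, s) dynamics of the public goods model."""
    logistic = 1.0 - s / p.K
    du = -p.kappa * u * (1.0 - u) * logistic
    ds = (
        -p.kappa * s * u * logistic
        + p.alpha * (1.0 + p.beta * u) * s * logistic
        - p.mu * s
    )
    return du, ds


def pg_inner_rhs(
    order: int, state: Sequence[float], p: PublicGoodsParams
) -> tuple[float, ...]:
    """Inner (ecological, fast-time) expansion right-hand sides.

    order 0, state (u0, s0):
        du0/dt = 0,  ds0/dt = alpha (1 + beta u0) s0 (1 - s0/K) - mu s0
    order 1, state (u0, s0, u1, s1) co-integrated:
        du1/dt = -u0 (1 - u0) (1 - s0/K)
        ds1/dt = -s0 u0 (1 - s0/K) + alpha (1 + beta u0) s1 (1 - 2 s0/K)
                 + alpha beta u1 s0 (1 - s0/K) - mu s1
    """
    if order == 0:
        u0, s0 = state
        logistic = 1.0 - s0 / p.K
        ds0 = p.alpha * (1.0 + p.beta * u0) * s0 * logistic - p.mu * s0
        return 0.0, ds0
    if order == 1:
        u0, s0, u1, s1 = state
        logistic = 1.0 - s0 / p.K
        ds0 = p.alpha * (1.0 + p.beta * u0) * s0 * logistic - p.mu * s0
        du1 = -u0 * (1.0 - u0) * logistic
        ds1 = (
            -s0 * u0 * logistic
            + p.alpha * (1.0 + p.beta * u0) * s1 * (1.0 - 2.0 * s0 / p.K)
            + p.alpha * p.beta * u1 * s0 * logistic
            - p.mu * s1
        )
        return 0.0, ds0, du1, ds1
    raise ValueError("inner expansion implemented to orders 0 and 1 only")


# ---------------------------------------------------------------------------
# outer systems


def _check_positive_equilibrium(U0: float, p: PublicGoodsParams) -> None:
    if p.mu >= p.alpha * (1.0 + p.beta * U0):
        raise NoEquilibriumError(
            "death rate exceeds the maximal birth rate; the non-trivial "
            "equilibrium density would be non-positive"
        )


def pg_outer_S0(U0: float, p: PublicGoodsParams) -> float:
    """Non-trivial equilibrium density S0 = K (1 - mu / (alpha (1 + beta U0)))."""
    _check_positive_equilibrium(U0, p)
    return p.K * (1.0 - p.mu / (p.alpha * (1.0 + p.beta * U0)))


def pg_outer_zeroth_rhs(U0: float, p: PublicGoodsParams) -> float:
    """Replicator dynamics of the producer frequency on tau = kappa * t.

    dU0/dtau = -(mu / (alpha (1 + beta U0))) U0 (1 - U0); selection against
    producers is modulated by the residual logistic head-room mu/(alpha(1+beta U0)).
    """
    _check_positive_equilibrium(U0, p)
    return -(p.mu / (p.alpha * (1.0 + p.beta * U0))) * U0 * (1.0 - U0)


def pg_outer_dS0_dtau(U0: float, p: PublicGoodsParams) -> float:
    """Drift of the equilibrium density along the slow frequency dynamics."""
    _check_positive_equilibrium(U0, p)
    return (
        -p.K * p.beta * p.mu**2
        / (p.alpha**2 * (1.0 + p.beta * U0) ** 3)
        * U0 * (1.0 - U0)
    )


def pg_outer_S1(U0: float, U1: float, p: PublicGoodsParams) -> float:
    """First-order density correction, from the order-kappa solvability condition.

    S1 = [ dS0/dtau + S0 (1 - S0/K) (U0 - alpha beta U1) ]
         / [ alpha (1 + beta U0) (1 - 2 S0/K) - mu ]

    With S0 substituted the denominator equals mu - alpha (1 + beta U0) < 0,
    so it cannot vanish while the equilibrium density is positive.
    """
    S0 = pg_outer_S0(U0, p)
    denom = p.alpha * (1.0 + p.beta * U0) * (1.0 - 2.0 * S0 / p.K) - p.mu
    # identity: denom == mu - alpha (1 + beta U0) < 0 under the precondition
    assert denom < 0.0, "first-order denominator lost its sign"
    num = pg_outer_dS0_dtau(U0, p) + S0 * (1.0 - S0 / p.K) * (
        U0 - p.alpha * p.beta * U1
    )
    return num / denom


def pg_outer_first_rhs(U0: float, U1: float, p: PublicGoodsParams) -> float:
    """First-order correction to the outer frequency dynamics.

    dU1/dtau = U0 (1 - U0) S1/K + (2 U0 - 1) U1 (1 - S0/K),

    with (1 - S0/K) = mu / (alpha (1 + beta U0)).  This is the form obtained
    by expanding the slow-time system in powers of kappa (re-derived
    symbolically in the test suite).
    """
    _check_positive_equilibrium(U0, p)
    S1 = pg_outer_S1(U0, U1, p)
    head_room = p.mu / (p.alpha * (1.0 + p.beta * U0))  # = 1 - S0/K
    return U0 * (1.0 - U0) * S1 / p.K + (2.0 * U0 - 1.0) * U1 * head_room


# ---------------------------------------------------------------------------
# invariant-manifold cross-check


def pg_invariant_manifold_rhs(u: float, p: PublicGoodsParams) -> float:
    """Producer-frequency ODE on the slow invariant manifold (fast time).

    du/dt = -(mu kappa / (alpha (1 + beta u) - u kappa)) u (1 - u).

    A first-order Taylor expansion of the prefactor in kappa followed by the
    rescaling tau = kappa t recovers the zeroth-order outer replicator
    dynamics, so the two routes agree to O(kappa).
    """
    denom = p.alpha * (1.0 + p.beta * u) - u * p.kappa
    if denom <= 0:
        raise ValueError("invariant-manifold prefactor denominator is non-positive")
    return -(p.mu * p.kappa / denom) * u * (1.0 - u)


# ---------------------------------------------------------------------------
# trajectories


def _t_grid(t_grid: Sequence[float]) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return t


def _integrate_inner(p: PublicGoodsParams, order: int, t: np.ndarray) -> Trajectory:
    if order == 0:
        rhs = lambda tt, y: pg_inner_rhs(0, y, p)  # noqa: E731
        return core.integrate(rhs, [p.a, p.b], t, names=["u0", "s0"])
    rhs = lambda tt, y: pg_inner_rhs(1, y, p)  # noqa: E731
    return core.integrate(rhs, [p.a, p.b, 0.0, 0.0], t, names=["u0", "s0", "u1", "s1"])


def _integrate_outer0(p: PublicGoodsParams, tau: np.ndarray) -> Trajectory:
    rhs = lambda tt, y: [pg_outer_zeroth_rhs(y[0], p)]  # noqa: E731
    traj = core.integrate(rhs, [p.a], tau, names=["u"], timescale="outer_tau")
    S0 = np.array([pg_outer_S0(U, p) for U in traj["u"]])
    return Trajectory(times=tau, states={"u": traj["u"], "s": S0},
                      timescale="outer_tau")


def _integrate_outer1(p: PublicGoodsParams, tau: np.ndarray) -> Trajectory:
    def rhs(tt, y):
        U0, U1 = y
        return [pg_outer_zeroth_rhs(U0, p), pg_outer_first_rhs(U0, U1, p)]

    traj = core.integrate(rhs, [p.a, 0.0], tau, names=["U0", "U1"],
                          timescale="outer_tau")
    U0, U1 = traj["U0"], traj["U1"]
    S0 = np.array([pg_outer_S0(v, p) for v in U0])
    S1 = np.array([pg_outer_S1(v0, v1, p) for v0, v1 in zip(U0, U1)])
    return Trajectory(
        times=tau,
        states={"u": U0 + p.kappa * U1, "s": S0 + p.kappa * S1,
                "U0": U0, "U1": U1, "S0": S0, "S1": S1},
        timescale="outer_tau",
    )


def pg_composite(p: PublicGoodsParams, t_grid: Sequence[float], order: int = 0) -> Trajectory:
    """Zeroth-order composite solution, uniformly valid on both time scales.

    u_c(t) = u0(t) + U0(kappa t) - a                    (u0(t) = a for all t)
    s_c(t) = s0(t) + S0(kappa t) - K(1 - mu/(alpha(1 + beta a)))
    """
    if order != 0:
        raise ValueError("only the zeroth-order composite is defined")
    if p.kappa <= 0:
        raise ValueError("composite assembly needs kappa > 0")
    t = _t_grid(t_grid)
    inner = _integrate_inner(p, 0, t)
    inner = Trajectory(times=t, states={"u": inner["u0"], "s": inner["s0"]})
    outer = _integrate_outer0(p, p.kappa * t)
    overlap = {"u": p.a, "s": pg_outer_S0(p.a, p)}
    return core.composite_zeroth(inner, outer, overlap, p.kappa)


def simulate(p: PublicGoodsParams, level: str, t_grid: Sequence[float]) -> Trajectory:
    """Trajectory of the full model or one of its approximations on a t-grid.

    Levels: ``full``, ``inner0``, ``inner1`` (u0 + kappa u1, s0 + kappa s1),
    ``outer0``/``outer1`` (slow dynamics mapped back through tau = kappa t)
    and ``composite0``.  All are reported as columns ``u`` (producer
    frequency) and ``s`` (total size) against fast time ``t``.
    """
    t = _t_grid(t_grid)
    if level == "full":
        rhs = lambda tt, y: pg_full_rhs(y[0], y[1], p)  # noqa: E731
        return core.integrate(rhs, [p.a, p.b], t, names=["u", "s"])
    if level == "inner0":
        traj = _integrate_inner(p, 0, t)
        return Trajectory(times=t, states={"u": traj["u0"], "s": traj["s0"]})
    if level == "inner1":
        traj = _integrate_inner(p, 1, t)
        return Trajectory(
            times=t,
            states={"u": traj["u0"] + p.kappa * traj["u1"],
                    "s": traj["s0"] + p.kappa * traj["s1"]},
        )
    if level in ("outer0", "outer1"):
        if p.kappa <= 0:
            raise ValueError("outer levels need kappa > 0 to map tau = kappa t")
        tau = p.kappa * t
        outer = _integrate_outer0(p, tau) if level == "outer0" else _integrate_outer1(p, tau)
        return Trajectory(times=t, states={"u": outer["u"], "s": outer["s"]})
    if level == "composite0":
        return pg_composite(p, t)
    raise ValueError(f"unknown approximation level {level!r}; choose from {LEVELS}")


def params_from_dict(d: dict) -> PublicGoodsParams:
    """Build params from JSON-style keys (u0/s0 aliases for a/b accepted)."""
    d = dict(d)
    if "u0" in d:
        d["a"] = d.pop("u0")
    if "s0" in d:
        d["b"] = d.pop("s0")
    return PublicGoodsParams(**d)


def with_epsilon(p: PublicGoodsParams, eps: float) -> PublicGoodsParams:
    """Copy of the params with the small parameter (kappa) replaced."""
    return replace(p, kappa=float(eps))
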