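"""Unit and property tests for the generic weak-selection framework."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoevo import core
from ecoevo import lotka_volterra as lv
from ecoevo import public_goods as pg
from ecoevo.core import FreqSizeState, ModelSpec, RateDecomposition
from ecoevo.exceptions import (
    DegeneratePopulationError,
    GridMismatchError,
    IntegrationError,
    NoEquilibriumError,
    UnmatchedExpansionError,
    UnstableEquilibriumError,
)


# ---------------------------------------------------------------------------
# change of variables


@pytest.mark.parametrize(
    "x, u_expected, s_expected",
    [
        ([1.0, 1.0], [0.5, 0.5], 2.0),
        ([1.0, 0.01], [1 / 1.01, 0.01 / 1.01], 1.01),  # LV predators at t=0
        ([0.005, 0.005], [0.5, 0.5], 0.01),  # (u, s) = (0.5, 0.01)
        ([1.0, 3.0], [0.25, 0.75], 4.0),
    ],
)
def test_frequencies_from_abundances(x, u_expected, s_expected):
    state = core.frequencies_from_abundances(x)
    np.testing.assert_allclose(state.u, u_expected, rtol=1e-14)
    assert state.s == pytest.approx(s_expected, rel=1e-14)


@pytest.mark.parametrize(
    "u, s, x_expected",
    [([0.5, 0.5], 2.0, [1.0, 1.0]), ([1.0, 0.0], 3.0, [3.0, 0.0]),
     ([0.25, 0.75], 4.0, [1.0, 3.0])],
)
def test_abundances_from_frequencies(u, s, x_expected):
    state = FreqSizeState(u=np.array(u), s=s)
    np.testing.assert_allclose(
        core.abundances_from_frequencies(state), x_expected, atol=1e-14
    )


def test_extinct_population_has_no_frequencies():
    with pytest.raises(DegeneratePopulationError):
        core.frequencies_from_abundances([0.0, 0.0, 0.0])


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=2, max_size=6)
)
def test_change_of_variables_round_trip(x):
    state = core.frequencies_from_abundances(x)
    back = core.abundances_from_frequencies(state)
    np.testing.assert_allclose(back, x, rtol=1e-12)
    assert state.u.sum() == pytest.approx(1.0, abs=1e-12)


def test_state_validation_rejects_off_simplex():
    with pytest.raises(ValueError):
        FreqSizeState(u=np.array([0.6, 0.6]), s=1.0)
    with pytest.raises(ValueError):
        FreqSizeState(u=np.array([1.5, -0.5]), s=1.0)
    with pytest.raises(ValueError):
        FreqSizeState(u=np.array([0.5, 0.5]), s=-1.0)


# ---------------------------------------------------------------------------
# right-hand sides


def _random_pg_states(rng, n):
    for _ in range(n):
        u1 = rng.uniform(0.0, 1.0)
        s = rng.uniform(1e-3, 2.0)
        yield u1, s


def test_full_rhs_neutral_limit_freezes_frequencies(pg_params, rng):
    """With eps = 0 the frequency equations vanish identically and the size
    equation coincides with the zeroth-order inner system."""
    import dataclasses

    p = dataclasses.replace(pg_params, kappa=0.0)
    model = pg.model_spec(p)
    for u1, s in _random_pg_states(rng, 20):
        state = FreqSizeState(u=np.array([u1, 1 - u1]), s=s)
        du, ds = core.full_rhs(state, model)
        np.testing.assert_array_equal(du, 0.0)
        du0, ds0 = core.inner_zeroth_rhs(state, model)
        assert ds == ds0


def test_full_rhs_monomorphic_vertex_is_fixed_for_frequencies(pg_params):
    model = pg.model_spec(pg_params)
    state = FreqSizeState(u=np.array([1.0, 0.0]), s=0.3)
    du, _ = core.full_rhs(state, model)
    np.testing.assert_allclose(du, 0.0, atol=1e-15)


def test_full_rhs_simplex_tangency(pg_params, rng):
    """Frequency derivatives sum to zero: the flow stays on the simplex."""
    model = pg.model_spec(pg_params)
    for u1, s in _random_pg_states(rng, 50):
        state = FreqSizeState(u=np.array([u1, 1 - u1]), s=s)
        du, _ = core.full_rhs(state, model)
        assert abs(du.sum()) < 1e-12


def test_generic_full_rhs_matches_hand_coded_public_goods(pg_params, rng):
    model = pg.model_spec(pg_params)
    for u1, s in _random_pg_states(rng, 100):
        state = FreqSizeState(u=np.array([u1, 1 - u1]), s=s)
        du, ds = core.full_rhs(state, model)
        du_pg, ds_pg = pg.pg_full_rhs(u1, s, pg_params)
        assert du[0] == pytest.approx(du_pg, rel=1e-12, abs=1e-15)
        assert ds == pytest.approx(ds_pg, rel=1e-12, abs=1e-15)


def test_generic_full_rhs_matches_hand_coded_predators(lv_params, rng):
    """At frozen prey x, the predator subsystem is a weak-selection model and
    the generic machinery must reproduce the hand-coded (u, s) equations."""
    for _ in range(100):
        x = rng.uniform(0.1, 4.0)
        u = rng.uniform(0.0, 1.0)
        s = rng.uniform(1e-2, 2.0)
        model = ModelSpec(
            n_types=2,
            rates=lv.predator_rate_decomposition(x, lv_params),
            epsilon=lv_params.epsilon,
        )
        du, ds = core.full_rhs(FreqSizeState(u=np.array([u, 1 - u]), s=s), model)
        _, du_lv, ds_lv = lv.lv_uvs_rhs(lv.LVState(x=x, u=u, s=s), lv_params)
        assert du[0] == pytest.approx(du_lv, rel=1e-12, abs=1e-15)
        assert ds == pytest.approx(ds_lv, rel=1e-12, abs=1e-15)


def test_rate_decomposition_recomposes_model_rates(pg_params, rng):
    """f_i = f0 + eps*phi_i must reproduce the undecomposed rates exactly."""
    rates = pg.rate_decomposition(pg_params)
    p = pg_params
    for u1, _ in _random_pg_states(rng, 20):
        u = np.array([u1, 1 - u1])
        f = rates.birth_rates(u, p.kappa)
        assert f[0] == p.alpha * (1 + p.beta * u1) - p.kappa
        assert f[1] == p.alpha * (1 + p.beta * u1)
        np.testing.assert_array_equal(rates.death_rates(u, p.kappa), p.mu)


def test_inner_zeroth_rhs_frequencies_exactly_frozen(pg_params):
    model = pg.model_spec(pg_params)
    state = FreqSizeState(u=np.array([0.3, 0.7]), s=1.4)
    du, _ = core.inner_zeroth_rhs(state, model)
    assert du.tolist() == [0.0, 0.0]


def test_inner_zeroth_rhs_values(pg_params):
    model = pg.model_spec(pg_params)
    # ds0/dt = 1.5 * 0.5 * 0.5 - 0.2 * 0.5 = 0.275 at (u0, s0) = (0.5, 0.5)
    _, ds = core.inner_zeroth_rhs(
        FreqSizeState(u=np.array([0.5, 0.5]), s=0.5), model
    )
    assert ds == pytest.approx(0.275, rel=1e-14)
    # extinction is absorbing
    _, ds = core.inner_zeroth_rhs(
        FreqSizeState(u=np.array([0.5, 0.5]), s=0.0), model
    )
    assert ds == 0.0


# ---------------------------------------------------------------------------
# ecological equilibrium


def test_equilibrium_matches_logistic_closed_form(pg_params):
    model = pg.model_spec(pg_params)
    res = core.ecological_equilibrium(
        np.array([0.5, 0.5]), model, bracket=(1e-3, 2.0)
    )
    assert res.s_star == pytest.approx(13 / 15, abs=1e-10)
    assert res.stable
    assert res.residual < 1e-10


def test_equilibrium_carrying_capacity_without_deaths():
    import dataclasses

    p = dataclasses.replace(pg.PublicGoodsParams(), mu=0.0)
    model = pg.model_spec(p)
    res = core.ecological_equilibrium(
        np.array([0.5, 0.5]), model, bracket=(1e-3, 2.0)
    )
    assert res.s_star == pytest.approx(p.K, abs=1e-10)
    assert res.stable


def test_density_independent_rates_have_no_equilibrium(lv_params):
    """With g = h = 1 and f0 != d0 the balance r(S) has no root: the LV
    predator density equation admits no fixed point at frozen frequency."""
    model = ModelSpec(
        n_types=2,
        rates=lv.predator_rate_decomposition(1.0, lv_params),  # delta*x != gamma
        epsilon=lv_params.epsilon,
    )
    with pytest.raises(NoEquilibriumError):
        core.ecological_equilibrium(np.array([0.5, 0.5]), model, bracket=(0.1, 5.0))


def _bistable_model():
    # r(S) = -(S-1)(S-2)(S-3): stable roots at 1 and 3, unstable at 2
    rates = RateDecomposition(
        f0=lambda u: 1.0,
        d0=lambda u: 1.0,
        phi=(lambda u: 0.0, lambda u: 0.0),
        eta=(lambda u: 0.0, lambda u: 0.0),
        g=lambda s: 1.0 - (s - 1.0) * (s - 2.0) * (s - 3.0),
        h=lambda s: 1.0,
    )
    return ModelSpec(n_types=2, rates=rates, epsilon=0.01)


def test_equilibrium_selection_follows_inner_dynamics():
    """With two stable roots the one in the basin of the initial density wins."""
    model = _bistable_model()
    u0 = np.array([0.5, 0.5])
    low = core.ecological_equilibrium(u0, model, bracket=(0.2, 4.0), s_init=0.5)
    high = core.ecological_equilibrium(u0, model, bracket=(0.2, 4.0), s_init=4.0)
    assert low.s_star == pytest.approx(1.0, abs=1e-9)
    assert high.s_star == pytest.approx(3.0, abs=1e-9)
    assert {round(r, 6) for r, _ in low.roots} == {1.0, 2.0, 3.0}
    assert [st for _, st in sorted(low.roots)] == [True, False, True]
    with pytest.raises(ValueError, match="multiple stable"):
        core.ecological_equilibrium(u0, model, bracket=(0.2, 4.0))


# ---------------------------------------------------------------------------
# outer dynamics


def test_outer_zeroth_rhs_fixed_points(pg_params):
    model = pg.model_spec(pg_params)
    s_star = pg.pg_outer_S0(1.0, pg_params)
    du = core.outer_zeroth_rhs(np.array([1.0, 0.0]), model, s_star)
    np.testing.assert_allclose(du, 0.0, atol=1e-15)


def test_outer_zeroth_rhs_no_selection_differential(rng):
    """phi = eta implies the bracket vanishes for every frequency (g=h=1)."""
    rates = RateDecomposition(
        f0=lambda u: 1.0,
        d0=lambda u: 0.5,
        phi=(lambda u: 0.7, lambda u: 0.2),
        eta=(lambda u: 0.7, lambda u: 0.2),
        g=lambda s: 1.0,
        h=lambda s: 1.0,
    )
    model = ModelSpec(n_types=2, rates=rates, epsilon=0.01)
    for _ in range(10):
        a = rng.uniform(0, 1)
        du = core.outer_zeroth_rhs(np.array([a, 1 - a]), model, 1.0)
        np.testing.assert_allclose(du, 0.0, atol=1e-15)


def test_outer_zeroth_rhs_public_goods_value(pg_params):
    model = pg.model_spec(pg_params)
    s_star = pg.pg_outer_S0(0.5, pg_params)
    du = core.outer_zeroth_rhs(np.array([0.5, 0.5]), model, s_star)
    assert du[0] == pytest.approx(-1 / 30, rel=1e-12)
    assert abs(du.sum()) < 1e-15


def test_outer_zeroth_rhs_rejects_unstable_equilibrium(pg_params):
    model = pg.model_spec(pg_params)
    bad = core.EquilibriumResult(
        s_star=0.5, stable=False, bracket=(0.1, 1.0), residual=0.0
    )
    with pytest.raises(UnstableEquilibriumError):
        core.outer_zeroth_rhs(np.array([0.5, 0.5]), model, bad)


# ---------------------------------------------------------------------------
# integration


def test_integrate_constant_flow():
    t = np.linspace(0, 5, 11)
    traj = core.integrate(lambda tt, y: [0.0, 0.0], [1.0, 2.0], t)
    np.testing.assert_array_equal(traj["y0"], 1.0)
    np.testing.assert_array_equal(traj["y1"], 2.0)


def test_integrate_logistic_closed_form():
    t = np.array([0.0, 1.0, 2.0, 5.0])
    traj = core.integrate(lambda tt, y: [y[0] * (1 - y[0])], [0.5], t)
    np.testing.assert_allclose(traj["y0"], 1.0 / (1.0 + np.exp(-t)), atol=1e-8)


def test_integrate_conserves_lv_first_integral(lv_params):
    """The zeroth-order inner system is classical Lotka-Volterra in (x0, s0)
    and must conserve delta*x - gamma*ln x + beta*s - alpha*ln s."""
    p = lv_params
    t = np.linspace(0, 200, 4001)
    rhs = lambda tt, y: [  # noqa: E731
        p.alpha * y[0] - p.beta * y[0] * y[1],
        p.delta * y[1] * y[0] - p.gamma * y[1],
    ]
    traj = core.integrate(rhs, [1.0, 1.01], t, names=["x", "s"])
    C = lv.lv_first_integral(traj["x"], traj["s"], p)
    assert np.max(np.abs(C - C[0])) < 1e-6


def test_integrate_signals_nonfinite_rhs():
    with pytest.raises(IntegrationError):
        core.integrate(lambda tt, y: [np.nan], [1.0], np.linspace(0, 1, 5))


def test_simulate_full_stays_on_simplex_and_matches_hand_coded(pg_params):
    model = pg.model_spec(pg_params)
    t = np.linspace(0, 50, 501)
    traj = core.simulate_full(model, pg.initial_state(pg_params), t)
    total = traj["u1"] + traj["u2"]
    assert np.max(np.abs(total - 1.0)) < 1e-8
    ref = pg.simulate(pg_params, "full", t)
    np.testing.assert_allclose(traj["u1"], ref["u"], atol=1e-8)
    np.testing.assert_allclose(traj["s"], ref["s"], atol=1e-8)


# ---------------------------------------------------------------------------
# composite assembly


def test_composite_matches_initial_condition(pg_params):
    t = np.linspace(0, 2000, 4001)
    comp = pg.pg_composite(pg_params, t)
    assert comp["u"][0] == pytest.approx(pg_params.a, abs=1e-12)
    assert comp["s"][0] == pytest.approx(pg_params.b, abs=1e-10)
    assert comp.timescale == "composite_t"


def test_composite_approaches_outer_branch_after_transient():
    """Once the fast transient has relaxed (t >> 1, kappa*t << 1) the
    composite coincides with the outer branch to within O(kappa)."""
    import dataclasses

    p = dataclasses.replace(pg.PublicGoodsParams(), kappa=0.01)
    t = np.linspace(0, 2000, 4001)
    comp = pg.pg_composite(p, t)
    outer = pg.simulate(p, "outer0", t)
    i = np.searchsorted(t, 50.0)
    assert abs(comp["u"][i] - outer["u"][i]) < p.kappa
    assert abs(comp["s"][i] - outer["s"][i]) < p.kappa


def test_composite_rejects_unmatched_expansions(pg_params):
    t = np.linspace(0, 2000, 401)
    inner = pg.simulate(pg_params, "inner0", t)
    outer = pg._integrate_outer0(pg_params, pg_params.kappa * t)
    wrong_overlap = {"u": pg_params.a + 0.1, "s": pg.pg_outer_S0(pg_params.a, pg_params)}
    with pytest.raises(UnmatchedExpansionError):
        core.composite_zeroth(inner, outer, wrong_overlap, pg_params.kappa)


def test_composite_rejects_mismatched_grids(pg_params):
    t = np.linspace(0, 2000, 401)
    inner = pg.simulate(pg_params, "inner0", t)
    outer = pg._integrate_outer0(pg_params, 0.5 * pg_params.kappa * t)
    overlap = {"u": pg_params.a, "s": pg.pg_outer_S0(pg_params.a, pg_params)}
    with pytest.raises(GridMismatchError):
        core.composite_zeroth(inner, outer, overlap, pg_params.kappa)


# ---------------------------------------------------------------------------
# trajectory container


def test_trajectory_validation_and_csv_round_trip(tmp_path):
    t = np.linspace(0, 1, 5)
    traj = core.Trajectory(times=t, states={"u": t**2, "s": 1 - t})
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["time", "u", "s", "timescale"]
    np.testing.assert_allclose(df["u"], t**2, rtol=1e-14)
    assert (df["timescale"] == "inner_t").all()

    with pytest.raises(ValueError):
        core.Trajectory(times=t[::-1], states={"u": t})
    with pytest.raises(ValueError):
        core.Trajectory(times=t, states={"u": t[:-1]})
    with pytest.raises(ValueError):
        core.Trajectory(times=t, states={"u": t}, timescale="weird")
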