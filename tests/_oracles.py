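"""Independent symbolic re-derivations of the perturbation systems.

Each helper substitutes the power-series ansatz into the *exact* model
equations with sympy, collects powers of the small parameter and returns
plain python callables for the expansion right-hand sides.  These are
derived from the full systems only — never from the implemented expansion
code — so they serve as independent oracles for the order-0/1 inner and
outer systems of both built-in models.
"""

from __future__ import annotations

import sympy as sp


def _coeff(expr, k, n):
    return sp.expand(expr).coeff(k, n)


def pg_inner_oracle(alpha, beta, K, mu):
    """Inner expansion of the public goods model.

    Returns callables du1(u0, s0), ds0(u0, s0), ds1(u0, s0, u1, s1) obtained
    by substituting u = u0 + k u1, s = s0 + k s1 into the exact (u, s) system
    and matching powers of the cost k.
    """
    k, u0, s0, u1, s1 = sp.symbols("k u0 s0 u1 s1")
    a, b, Ks, m = [sp.nsimplify(v) for v in (alpha, beta, K, mu)]
    u = u0 + k * u1
    s = s0 + k * s1
    F_u = -k * u * (1 - u) * (1 - s / Ks)
    F_s = -k * s * u * (1 - s / Ks) + a * (1 + b * u) * s * (1 - s / Ks) - m * s
    # du/dt = du0/dt + k du1/dt  and  ds/dt = ds0/dt + k ds1/dt
    du0 = _coeff(F_u, k, 0)
    du1 = _coeff(F_u, k, 1)
    ds0 = _coeff(F_s, k, 0)
    ds1 = _coeff(F_s, k, 1)
    assert sp.simplify(du0) == 0
    return (
        sp.lambdify((u0, s0), du1, "math"),
        sp.lambdify((u0, s0), ds0, "math"),
        sp.lambdify((u0, s0, u1, s1), ds1, "math"),
    )


def pg_outer_oracle(alpha, beta, K, mu):
    """Outer (slow-time) expansion of the public goods model.

    Works on tau = k t: substitutes u = U0 + k U1, s = S0 + k S1 into
    k du/dtau = F_u and k ds/dtau = F_s, solves the order-k^0 equation of the
    size for S0, the order-k^1 equation for S1 and extracts dU0/dtau (order
    k^1 of the frequency equation) and dU1/dtau (order k^2).  Returns
    callables S0(U0), dS0dtau(U0), S1(U0, U1), dU0(U0), dU1(U0, U1).
    """
    k = sp.symbols("k")
    U0, U1 = sp.symbols("U0 U1")
    S0f, S1f = sp.symbols("S0 S1")
    a, b, Ks, m = [sp.nsimplify(v) for v in (alpha, beta, K, mu)]

    u = U0 + k * U1
    s = S0f + k * S1f
    F_u = -k * u * (1 - u) * (1 - s / Ks)
    F_s = -k * s * u * (1 - s / Ks) + a * (1 + b * u) * s * (1 - s / Ks) - m * s

    # order k^0 of the size equation: algebraic condition for S0 (ignore S0=0)
    eq0 = _coeff(F_s, k, 0)
    S0_sol = [r for r in sp.solve(sp.Eq(eq0, 0), S0f) if r != 0]
    assert len(S0_sol) == 1
    S0_expr = sp.simplify(S0_sol[0])

    # dU0/dtau from order k^1 of the frequency equation, with S0 substituted
    dU0_expr = sp.simplify(_coeff(F_u, k, 1).subs(S0f, S0_expr))

    # chain rule: dS0/dtau = dS0/dU0 * dU0/dtau
    dS0_expr = sp.simplify(sp.diff(S0_expr, U0) * dU0_expr)

    # order k^1 of the size equation equals dS0/dtau; solve for S1
    eq1 = sp.Eq(dS0_expr, _coeff(F_s, k, 1).subs(S0f, S0_expr))
    S1_sol = sp.solve(eq1, S1f)
    assert len(S1_sol) == 1
    S1_expr = sp.simplify(S1_sol[0])

    # order k^2 of the frequency equation is dU1/dtau
    dU1_expr = sp.simplify(
        _coeff(F_u, k, 2).subs({S0f: S0_expr, S1f: S1_expr})
    )

    return (
        sp.lambdify(U0, S0_expr, "math"),
        sp.lambdify(U0, dS0_expr, "math"),
        sp.lambdify((U0, U1), S1_expr, "math"),
        sp.lambdify(U0, dU0_expr, "math"),
        sp.lambdify((U0, U1), dU1_expr, "math"),
    )


def lv_change_of_variables_oracle():
    """Symbolic (x, u, s) system derived from the abundance equations.

    Starts from the three-species system in (x, y1, y2), substitutes
    y1 = s u, y2 = s (1 - u) and applies the chain/quotient rule to
    u = y1/(y1+y2), s = y1+y2.  Returns sympy expressions (dx, du, ds) in
    symbols (x, u, s, alpha, beta, delta, gamma, eps).
    """
    x, y1, y2, al, be, de, ga, e = sp.symbols("x y1 y2 alpha beta delta gamma eps")
    u, s = sp.symbols("u s")
    dx = al * x - be * x * (y1 + (1 + e) * y2)
    dy1 = de * x * y1 - ga * y1
    dy2 = de * (1 + e) * x * y2 - ga * y2
    ds = dy1 + dy2
    du = (dy1 * (y1 + y2) - y1 * ds) / (y1 + y2) ** 2
    sub = {y1: s * u, y2: s * (1 - u)}
    return (
        sp.simplify(dx.subs(sub)),
        sp.simplify(du.subs(sub)),
        sp.simplify(ds.subs(sub)),
    )


def lv_inner_oracle(alpha, beta, delta, gamma):
    """Inner expansion of the predator-competition model.

    Substitutes x = x0 + e x1, u = u0 + e u1, s = s0 + e s1 into the exact
    (x, u, s) system (itself derived symbolically from the abundances) and
    matches powers of the invader advantage e.  Returns callables for the
    order-0 triple and the order-1 triple.
    """
    e = sp.symbols("eps")
    x0, u0, s0, x1, u1, s1 = sp.symbols("x0 u0 s0 x1 u1 s1")
    al, be, de, ga = [sp.nsimplify(v) for v in (alpha, beta, delta, gamma)]

    dx_e, du_e, ds_e = lv_change_of_variables_oracle()
    x, u, s = sp.symbols("x u s")
    pars = dict(zip(sp.symbols("alpha beta delta gamma"), (al, be, de, ga)))
    sub = {x: x0 + e * x1, u: u0 + e * u1, s: s0 + e * s1, **pars}
    dx = dx_e.subs(sub)
    du = du_e.subs(sub)
    ds = ds_e.subs(sub)

    order0 = tuple(sp.simplify(_coeff(f, e, 0)) for f in (dx, du, ds))
    order1 = tuple(sp.simplify(_coeff(f, e, 1)) for f in (dx, du, ds))
    assert order0[1] == 0  # frequencies frozen at zeroth order
    args0 = (x0, u0, s0)
    args1 = (x0, u0, s0, x1, u1, s1)
    return (
        [sp.lambdify(args0, f, "math") for f in order0],
        [sp.lambdify(args1, f, "math") for f in order1],
    )


def lv_outer_oracle(alpha, beta, delta, gamma):
    """Outer expansion of the predator-competition model.

    On tau = e t: e dx/dtau = F_x etc.  Order e^0 gives the algebraic steady
    state (X0, S0); order e^1 of the x- and s-equations is algebraic in
    (X1, S1) because X0, S0 are constants; order e^1 / e^2 of the u-equation
    give dU0/dtau and dU1/dtau.  Returns (X0, S0) floats and callables
    X1(U0), S1(U0), dU0(U0), dU1(U0, U1).
    """
    e = sp.symbols("eps")
    U0, U1, X0f, X1f, S0f, S1f = sp.symbols("U0 U1 X0 X1 S0 S1")
    al, be, de, ga = [sp.nsimplify(v) for v in (alpha, beta, delta, gamma)]

    dx_e, du_e, ds_e = lv_change_of_variables_oracle()
    x, u, s = sp.symbols("x u s")
    pars = dict(zip(sp.symbols("alpha beta delta gamma"), (al, be, de, ga)))
    sub = {x: X0f + e * X1f, u: U0 + e * U1, s: S0f + e * S1f, **pars}
    F_x = dx_e.subs(sub)
    F_u = du_e.subs(sub)
    F_s = ds_e.subs(sub)

    # order e^0: steady state (excluding extinction)
    st = sp.solve([_coeff(F_x, e, 0), _coeff(F_s, e, 0)], [X0f, S0f], dict=True)
    st = [r for r in st if r.get(X0f, 0) != 0 and r.get(S0f, 0) != 0]
    assert len(st) == 1
    X0_expr, S0_expr = st[0][X0f], st[0][S0f]

    # order e^1 of x- and s-equations: LHS is dX0/dtau = dS0/dtau = 0
    lin = sp.solve(
        [
            _coeff(F_x, e, 1).subs({X0f: X0_expr, S0f: S0_expr}),
            _coeff(F_s, e, 1).subs({X0f: X0_expr, S0f: S0_expr}),
        ],
        [X1f, S1f],
        dict=True,
    )
    assert len(lin) == 1
    X1_expr = sp.simplify(lin[0][X1f])
    S1_expr = sp.simplify(lin[0][S1f])

    dU0_expr = sp.simplify(_coeff(F_u, e, 1).subs({X0f: X0_expr, S0f: S0_expr}))
    dU1_expr = sp.simplify(
        _coeff(F_u, e, 2).subs(
            {X0f: X0_expr, S0f: S0_expr, X1f: X1_expr, S1f: S1_expr}
        )
    )

    return (
        float(X0_expr),
        float(S0_expr),
        sp.lambdify(U0, X1_expr, "math"),
        sp.lambdify(U0, S1_expr, "math"),
        sp.lambdify(U0, dU0_expr, "math"),
        sp.lambdify((U0, U1), dU1_expr, "math"),
    )
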