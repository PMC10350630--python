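"""ODE assembly, Jacobians, steady states and stability classification."""

import numpy as np
import pytest

from mvamep.network import REFERENCE_CONCENTRATIONS
from mvamep.odes import (
    assemble_odes,
    classify_stability,
    find_steady_state,
    jacobian,
)

from conftest import toy_pool, toy_reaction
from mvamep.network import PathwayModel


def test_single_pool_closed_form(linear_toy):
    """One-pool toy: constant inflow c against a saturating consumer."""
    model, p = linear_toy
    ss = find_steady_state(model)
    # exact fixed point of c = V M / (K + M):  M* = c K / (V - c)
    expected = p["c"] * p["K"] / (p["V"] - p["c"])
    assert ss.converged and ss.stable
    assert ss.concentrations["M"] == pytest.approx(expected, rel=1e-6)
    assert ss.residual_norm < 1e-8


def test_chain_toy_matches_hand_written_odes(chain_toy):
    """Derivatives equal the hand-expanded mass balances of the 3-pool chain."""
    system = assemble_odes(chain_toy)
    state = {"A": 0.3, "B": 0.15, "C": 0.25}
    y = system.state_vector(state)
    dydt = system.rhs(y)

    def mm(V, x, K):
        return V * x / (K + x)

    f_in = mm(1.0, 2.0, 1.0)
    f_ab = mm(2.0, 0.3, 0.4)
    f_bc = mm(1.5, 0.15, 0.3)
    f_out = mm(1.2, 0.25, 0.2)
    expected = {"A": f_in - f_ab, "B": f_ab - f_bc, "C": f_bc - f_out}
    for pool, val in expected.items():
        i = system.pool_order.index(pool)
        assert dydt[i] == pytest.approx(val, rel=1e-12)


@pytest.mark.parametrize("fixture", ["linear_toy", "chain_toy"])
def test_jacobian_matches_central_differences(fixture, request):
    model = request.getfixturevalue(fixture)
    model = model[0] if isinstance(model, tuple) else model
    system = assemble_odes(model)
    y = system.basal_vector() * 1.3
    J = system.jacobian(y)
    h_rel = 1e-6
    for j in range(system.n):
        h = h_rel * y[j]
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        fd = (system.rhs(yp) - system.rhs(ym)) / (2 * h)
        assert np.allclose(J[:, j], fd, rtol=1e-6, atol=1e-10)


def test_wild_type_jacobian_shape_and_fd_agreement(wt_model):
    state = {k: v for k, v in REFERENCE_CONCENTRATIONS.items()}
    J = jacobian(wt_model, state)
    assert J.shape == (14, 14)
    system = assemble_odes(wt_model)
    y = system.state_vector(state)
    for j in range(14):
        h = 1e-6 * y[j]
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        fd = (system.rhs(yp) - system.rhs(ym)) / (2 * h)
        scale = np.max(np.abs(J[:, j]))
        assert np.allclose(J[:, j], fd, rtol=2e-6, atol=1e-8 * max(scale, 1.0))


@pytest.mark.parametrize(
    "eigs, expected",
    [([-1.0, complex(-0.5, 2.0), complex(-0.5, -2.0)], "stable"),
     ([-1.0, 0.01], "unstable")],
)
def test_classify_stability(eigs, expected):
    assert classify_stability(eigs) == expected


def test_classify_stability_rejects_empty():
    with pytest.raises(ValueError):
        classify_stability([])


def test_wild_type_reaches_reference_steady_state(wt_model):
    ss = find_steady_state(wt_model)
    assert ss.converged and ss.stable
    for pool, ref in REFERENCE_CONCENTRATIONS.items():
        assert ss.concentrations[pool] == pytest.approx(ref, rel=1e-6)
    assert max(e.real for e in ss.eigenvalues) < 0
    assert len(ss.eigenvalues) == 14


def test_mass_balance_holds_at_any_converged_state(variant_models):
    """At steady state every pool's production equals its consumption."""
    for model in variant_models.values():
        ss = find_steady_state(model)
        assert ss.converged
        system = assemble_odes(model)
        y = system.state_vector(ss.concentrations)
        rates = system.rates(y)
        for pool in model.dynamic_pools:
            prod = sum(rates[r.id] for r in model.producers(pool))
            cons = sum(rates[r.id] for r in model.consumers(pool))
            assert abs(prod - cons) < 1e-8


def test_divergent_pool_reported_as_accumulating():
    """A pool whose only consumer has V = 0 cannot reach a steady state."""
    pools = {
        "S": toy_pool("S", 1.0, role="fixed"),
        "M": toy_pool("M", 0.01),
    }
    reactions = {
        "prod": toy_reaction("prod", ["S"], ["M"], V=1.0, K={"S": 0.5}),
        "cons": toy_reaction("cons", ["M"], [], V=0.0, K={"M": 0.5}),
    }
    model = PathwayModel(variant="toy", pools=pools, reactions=reactions)
    ss = find_steady_state(model)
    assert not ss.converged
    assert ss.accumulating == ["M"]


def test_negative_initial_state_rejected(linear_toy):
    model, _ = linear_toy
    with pytest.raises(ValueError):
        find_steady_state(model, init={"M": -1.0})


def test_stability_agrees_with_perturbed_integration(linear_toy):
    """Eigenvalue classification matches the return behavior after a 1% kick."""
    from scipy.integrate import solve_ivp

    model, _ = linear_toy
    ss = find_steady_state(model)
    system = assemble_odes(model)
    y0 = system.state_vector(ss.concentrations) * 1.01
    sol = solve_ivp(lambda t, y: system.rhs(y), (0, 500.0), y0, rtol=1e-9)
    final = sol.y[:, -1]
    ref = system.state_vector(ss.concentrations)
    returned = np.allclose(final, ref, rtol=1e-3)
    assert returned == ss.stable
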