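import numpy as np
import pytest
from hypothesis import given, strategies as st

from homeoca.meanfield import (
    classify_fixed_point, leading_order_interior, mf_fixed_points,
    mf_integrate, mf_jacobian, mf_rhs, vector_field,
)
from homeoca.params import Params, validate_params


def fd_jacobian(state, params, h=1e-6):
    p, q = state
    J = np.empty((2, 2))
    for col, (dp, dq) in enumerate(((h, 0.0), (0.0, h))):
        f_plus = mf_rhs((p + dp, q + dq), params)
        f_minus = mf_rhs((p - dp, q - dq), params)
        J[0, col] = (f_plus[0] - f_minus[0]) / (2 * h)
        J[1, col] = (f_plus[1] - f_minus[1]) / (2 * h)
    return J


# --- right-hand side ------------------------------------------------------

@pytest.mark.parametrize("params", [
    Params(r=0.0, d=0.2, a=0.1),
    Params(r=3.0, d=0.1, a=0.3),
    Params(r=1.0, d=0.9, a=0.05),
])
def test_absorbing_states_are_fixed_points(params):
    assert mf_rhs((0.0, 0.0), params) == (0.0, 0.0)
    assert mf_rhs((0.0, 1.0), params) == (0.0, 0.0)


def test_rhs_hand_evaluation():
    dp, dq = mf_rhs((0.5, 0.25), Params(r=0.0, d=0.0, a=0.0))
    assert dp == pytest.approx(0.5 * 1.0 * 0.25)
    assert dq == pytest.approx(0.0)


@given(p=st.floats(0, 1), q=st.floats(0, 1),
       d=st.floats(0.01, 0.99), a=st.floats(0, 0.5), r=st.floats(0, 2))
def test_proliferative_wall_is_invariant(p, q, d, a, r):
    """rho_p = 0 is an absorbing wall: the proliferative density cannot
    regrow once lost (every gain term carries rho_p)."""
    if q > 1:
        return
    dp, _ = mf_rhs((0.0, q), Params(r=r, d=d, a=a))
    assert dp == 0.0


# --- Jacobian -------------------------------------------------------------

def test_jacobian_at_origin_closed_form():
    d = 0.3
    J = mf_jacobian((0.0, 0.0), Params(r=1.0, d=d, a=0.2))
    assert np.allclose(J, [[1 - d, 0.0], [0.0, -d]])
    assert classify_fixed_point(J) == "saddle"


def test_jacobian_at_all_quiescent_is_saddle():
    params = Params(r=1.5, d=0.3, a=0.2)
    J = mf_jacobian((0.0, 1.0), params)
    assert J[0, 0] == pytest.approx(-(params.a + params.d))
    assert J[0, 1] == pytest.approx(0.0)
    assert J[1, 1] == pytest.approx(params.d)
    assert np.linalg.det(J) == pytest.approx(-params.d * (params.a + params.d))
    assert classify_fixed_point(J) == "saddle"


@given(
    p=st.floats(0, 1), q=st.floats(0, 1),
    r=st.floats(0, 3), d=st.floats(0, 1), a=st.floats(0, 1),
)
def test_analytic_jacobian_matches_finite_differences(p, q, r, d, a):
    if p + q > 1:
        return
    params = Params(r=r, d=d, a=a)
    J = mf_jacobian((p, q), params)
    assert np.allclose(J, fd_jacobian((p, q), params), rtol=1e-5, atol=1e-6)


@pytest.mark.parametrize("J, label", [
    ([[1.0, 0.0], [0.0, -1.0]], "saddle"),
    ([[-0.1, -1.0], [1.0, -0.1]], "stable spiral"),
    ([[-3.0, 0.0], [0.0, -1.0]], "stable node"),
    ([[0.1, -1.0], [1.0, 0.1]], "unstable spiral"),
    ([[2.0, 0.0], [0.0, 1.0]], "unstable node"),
    ([[0.0, 0.0], [0.0, 0.0]], "degenerate"),
])
def test_classification_table(J, label):
    assert classify_fixed_point(np.array(J)) == label


# --- fixed points ---------------------------------------------------------

@given(d=st.floats(0.05, 0.95), a=st.floats(0.05, 0.5), r=st.floats(0, 2))
def test_absorbing_fixed_points_are_saddles(d, a, r):
    params = Params(r=r, d=d, a=a)
    if not validate_params(params).ok:
        return
    for state in ((0.0, 0.0), (0.0, 1.0)):
        assert classify_fixed_point(mf_jacobian(state, params)) == "saddle"


SPIRAL_PARAMS = Params(r=3.0, d=0.1, a=0.25)   # low-proliferation equilibrium
NODE_PARAMS = Params(r=1.0, d=0.2, a=0.05)     # high-proliferation equilibrium


def _interior(reports):
    pts = [fp for fp in reports if fp.rho_p > 1e-6]
    assert pts, "no interior fixed point found"
    return pts


def test_fixed_points_contain_absorbing_pair_and_interior_root():
    reports = mf_fixed_points(SPIRAL_PARAMS)
    locs = {(round(fp.rho_p, 8), round(fp.rho_q, 8)) for fp in reports}
    assert (0.0, 0.0) in locs and (0.0, 1.0) in locs
    for fp in _interior(reports):
        assert fp.residual < 1e-10
        assert fp.rho_p + fp.rho_q <= 1 + 1e-9


def test_interior_point_spiral_in_low_proliferation_regime():
    fp = _interior(mf_fixed_points(SPIRAL_PARAMS))[0]
    assert fp.label == "stable spiral"
    assert fp.trace < 0
    assert fp.discriminant < 0


def test_interior_point_node_in_high_proliferation_regime():
    fp = _interior(mf_fixed_points(NODE_PARAMS))[0]
    assert fp.label == "stable node"
    assert fp.trace < 0
    assert fp.rho_p > 0.3


def test_leading_order_expressions_are_rough_guides():
    lp, lq = leading_order_interior(NODE_PARAMS)
    fp = _interior(mf_fixed_points(NODE_PARAMS))[0]
    assert lp == pytest.approx((1 - 0.2) * (0.2 - 0.05) / 0.2)
    # leading order is only an approximation; it should land in the
    # right region of the simplex
    assert abs(lp - fp.rho_p) < 0.35
    with pytest.raises(ValueError):
        leading_order_interior(Params(r=0.0, d=0.3, a=0.1))


# --- integration ----------------------------------------------------------

def test_integration_stays_at_interior_fixed_point():
    fp = _interior(mf_fixed_points(NODE_PARAMS))[0]
    path = mf_integrate(NODE_PARAMS, init=fp.location, t_max=200.0)
    assert np.hypot(*(np.array(path.terminal()) - fp.location)) < 1e-7


def test_integration_converges_to_stable_node_from_seed():
    fp = _interior(mf_fixed_points(NODE_PARAMS))[0]
    path = mf_integrate(NODE_PARAMS, init=(1e-4, 0.0), t_max=2000.0)
    assert np.hypot(*(np.array(path.terminal()) - fp.location)) < 1e-6


def test_spiral_regime_shows_decaying_oscillations():
    path = mf_integrate(SPIRAL_PARAMS, init=(1e-4, 0.0), t_max=3000.0)
    dp = np.diff(path.rho_p)
    sign_changes = int((np.sign(dp[:-1]) * np.sign(dp[1:]) < 0).sum())
    assert sign_changes >= 3
    fp = _interior(mf_fixed_points(SPIRAL_PARAMS))[0]
    assert np.hypot(*(np.array(path.terminal()) - fp.location)) < 1e-4


@pytest.mark.parametrize("params", [SPIRAL_PARAMS, NODE_PARAMS,
                                    Params(r=0.0, d=0.4, a=0.2)])
def test_simplex_forward_invariance(params):
    for init in [(1e-4, 0.0), (0.5, 0.4), (0.05, 0.9)]:
        path = mf_integrate(params, init=init, t_max=500.0)
        assert (path.rho_p >= -1e-9).all()
        assert (path.rho_q >= -1e-9).all()
        assert (path.rho_p + path.rho_q <= 1 + 1e-9).all()


def test_integrate_rejects_states_outside_simplex():
    with pytest.raises(ValueError):
        mf_integrate(NODE_PARAMS, init=(0.7, 0.5))


# --- vector field ---------------------------------------------------------

def test_vector_field_geometry():
    states, derivs = vector_field(Params(r=1.0, d=0.3, a=0.2), resolution=11)
    assert (states.sum(axis=1) <= 1 + 1e-12).all()
    wall = states[:, 0] == 0.0
    assert np.allclose(derivs[wall, 0], 0.0)
    origin = (states == 0).all(axis=1)
    assert np.allclose(derivs[origin], 0.0)
    boundary = np.isclose(states.sum(axis=1), 1.0)
    assert (derivs[boundary].sum(axis=1) <= 1e-12).all()
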