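"""Mean-field analysis of the automaton.

Closing the site-resolved master equation under the mean-field
assumption (neighbour occupancies replaced by global densities, infinite
lattice) turns the dynamics into a planar ODE for the proliferative and
quiescent densities ``(rho_p, rho_q)`` on the simplex
``{rho_p, rho_q >= 0, rho_p + rho_q <= 1}``::

    d rho_p / dt = rho_p (1 + r rho_q)(1 - rho_p - rho_q)
                   - (a (rho_p + rho_q) + d) rho_p
    d rho_q / dt = a (rho_p + rho_q) rho_p
                   - (d + r rho_p)(1 - rho_p - rho_q) rho_q

Gain of proliferative density comes from division into vacancy (boosted
by quiescent reactivation through ``r``); loss from death (``d``) and
contact-inhibition arrest (``a``).  ``(0, 0)`` (all vacant) and
``(0, 1)`` (all quiescent) are always fixed points — the absorbing
configurations of the stochastic model — and ``rho_p = 0`` is an
invariant wall.  A third, interior fixed point (when present) is the
homeostatic equilibrium; its Jacobian classification (stable spiral at
low proliferative density, stable node at high) governs the robustness
of homeostasis.

Interior fixed points are found numerically by multi-start root-finding
on a simplex grid; closed-form leading-order expressions are exposed as
diagnostics only (:func:`leading_order_interior`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import Params

__all__ = [
    "mf_rhs", "mf_jacobian", "classify_fixed_point", "mf_fixed_points",
    "mf_integrate", "vector_field", "leading_order_interior",
    "FixedPointReport", "MeanFieldPath",
]


def mf_rhs(state, params: Params) -> tuple[float, float]:
    """Right-hand side ``(d rho_p/dt, d rho_q/dt)`` of the mean-field ODE."""
    p, q = state
    v = 1.0 - p - q
    dp = p * (params.g + params.r * q) * v - (params.a * (p + q) + params.d) * p
    dq = params.a * (p + q) * p - (params.d + params.r * p) * v * q
    return dp, dq


def mf_jacobian(state, params: Params) -> np.ndarray:
    """Analytic Jacobian of :func:`mf_rhs` at ``state``.

    Derived by differentiating the RHS (and verified against central
    finite differences in the test suite), rather than transcribed from
    any printed matrix.
    """
    p, q = state
    r, d, a, g = params.r, params.d, params.a, params.g
    v = 1.0 - p - q
    j11 = (g + r * q) * (v - p) - 2.0 * a * p - a * q - d
    j12 = p * (r * v - (g + r * q)) - a * p
    j21 = a * (2.0 * p + q) - r * v * q + (d + r * p) * q
    j22 = a * p - (d + r * p) * (v - q)
    return np.array([[j11, j12], [j21, j22]])


def classify_fixed_point(jacobian: np.ndarray, tol: float = 1e-9) -> str:
    """Standard planar linear classification from trace and determinant.

    Returns one of ``saddle``, ``stable spiral``, ``stable node``,
    ``unstable spiral``, ``unstable node`` or ``degenerate`` (determinant
    or trace within ``tol`` of zero where the label would be ambiguous).
    """
    J = np.asarray(jacobian, dtype=float)
    if not np.isfinite(J).all():
        raise ValueError("Jacobian must be finite")
    det = float(np.linalg.det(J))
    tr = float(np.trace(J))
    disc = tr * tr - 4.0 * det
    if abs(det) < tol:
        return "degenerate"
    if det < 0.0:
        return "saddle"
    if abs(tr) < tol:
        return "degenerate"
    kind = "spiral" if disc < 0.0 else "node"
    return f"{'stable' if tr < 0.0 else 'unstable'} {kind}"


@dataclass
class FixedPointReport:
    """A fixed point with its local linearisation."""

    rho_p: float
    rho_q: float
    jacobian: np.ndarray
    trace: float
    det: float
    discriminant: float
    label: str
    residual: float

    @property
    def location(self) -> tuple[float, float]:
        return (self.rho_p, self.rho_q)


def _report(point, params) -> FixedPointReport:
    J = mf_jacobian(point, params)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    res = float(np.hypot(*mf_rhs(point, params)))
    return FixedPointReport(
        rho_p=float(point[0]), rho_q=float(point[1]), jacobian=J,
        trace=tr, det=det, discriminant=tr * tr - 4.0 * det,
        label=classify_fixed_point(J), residual=res,
    )


def mf_fixed_points(
    params: Params,
    grid_n: int = 21,
    tol: float = 1e-12,
    merge_tol: float = 1e-8,
    residual_tol: float = 1e-10,
) -> list[FixedPointReport]:
    """All fixed points of the mean-field flow in the simplex.

    ``(0, 0)`` and ``(0, 1)`` are always included.  Further roots come
    from Powell-hybrid root-finding started on a ``grid_n x grid_n``
    simplex lattice; converged roots (residual below ``residual_tol``)
    within ``merge_tol`` of each other are merged.  If no interior root
    (``rho_p > merge_tol``) converges from any start, a warning is
    emitted — for some parameters no interior equilibrium exists.
    """
    found: list[np.ndarray] = [np.array([0.0, 0.0]), np.array([0.0, 1.0])]

    def fun(v):
        return np.array(mf_rhs(v, params))

    def jac(v):
        return mf_jacobian(v, params)

    for i in range(grid_n):
        for j in range(grid_n - i):
            x0 = np.array([i, j]) / (grid_n - 1)
            sol = root(fun, x0, jac=jac, method="hybr", tol=tol)
            if not sol.success:
                continue
            x = sol.x
            x[np.abs(x) < merge_tol] = 0.0
            if x[0] < 0 or x[1] < 0 or x.sum() > 1.0 + merge_tol:
                continue
            if np.hypot(*fun(x)) > residual_tol:
                continue
            if all(np.hypot(*(x - y)) > merge_tol for y in found):
                found.append(x)

    if not any(x[0] > merge_tol for x in found):
        warnings.warn(
            "no interior fixed point converged from any start; "
            "only the absorbing fixed points are reported",
            stacklevel=2,
        )
    return [_report(x, params) for x in found]


def leading_order_interior(params: Params) -> tuple[float, float]:
    """Leading-order closed form for the interior fixed point (diagnostic).

    ``rho_p3 ~ (1-d)(rd-a)/(rd)``, ``rho_q3 ~ a(1-d)/(rd)``; correction
    terms are omitted, so use :func:`mf_fixed_points` for computation.
    Requires ``r*d > 0``.
    """
    rd = params.r * params.d
    if rd <= 0:
        raise ValueError("leading-order expressions require r*d > 0")
    return ((1 - params.d) * (rd - params.a) / rd, params.a * (1 - params.d) / rd)


@dataclass
class MeanFieldPath:
    """A time-stamped trajectory of the mean-field ODE."""

    t: np.ndarray
    rho_p: np.ndarray
    rho_q: np.ndarray

    def terminal(self) -> tuple[float, float]:
        return float(self.rho_p[-1]), float(self.rho_q[-1])


def mf_integrate(
    params: Params,
    init=(1e-4, 0.0),
    t_max: float = 2000.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_points: int = 2001,
) -> MeanFieldPath:
    """Integrate the mean-field ODE with an adaptive RK scheme.

    The default initial condition ``(1e-4, 0)`` mimics the single-seed
    initial condition of the lattice simulations.  The simplex is forward
    invariant, so no clipping is applied; the path stays inside it up to
    solver tolerance.
    """
    p0, q0 = float(init[0]), float(init[1])
    if p0 < 0 or q0 < 0 or p0 + q0 > 1.0:
        raise ValueError(f"initial state {init} outside the simplex")
    sol = solve_ivp(
        lambda t, y: mf_rhs(y, params),
        (0.0, t_max),
        [p0, q0],
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, t_max, n_points),
        jac=lambda t, y: mf_jacobian(y, params),
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return MeanFieldPath(t=sol.t, rho_p=sol.y[0], rho_q=sol.y[1])


def vector_field(params: Params, resolution: int = 21):
    """Evaluate the mean-field flow on a triangular simplex grid.

    Returns ``(states, derivs)`` as ``(n, 2)`` arrays over all grid
    points ``(i, j)/(resolution-1)`` with ``rho_p + rho_q <= 1``, for
    portrait rendering.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    pts = []
    for i in range(resolution):
        for j in range(resolution - i):
            pts.append((i / (resolution - 1), j / (resolution - 1)))
    states = np.array(pts)
    derivs = np.array([mf_rhs(s, params) for s in states])
    return states, derivs
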