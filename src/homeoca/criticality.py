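"""Phase classification, critical-point location and scaling fits.

Infinite-size phase separation follows the short-time/modest-lattice
protocol: ensembles of single-seed sessions are classified from the
late-time behaviour of the session-averaged counts —

* extinctive (E): the mean proliferative number decays toward zero
  (late-time log-slope below ``-eps`` per step, or full extinction);
* degenerative (D): the quiescent cluster expands exponentially, i.e.
  ``log(N_q/N_p)`` grows linearly *and* the mean quiescent number itself
  grows;
* proliferative (P): otherwise (growing proliferative number, bounded
  ratio).

Critical death probabilities are located by bisection on ``d`` with a
fixed ensemble seed, so the estimate is deterministic given the seed.
At criticality the mean proliferative number grows as a power law
``t^theta``; exponents are measured by least squares on log-log scales.

Finite-size analysis works on the active probability ``P_act(t)``:
quasi-stable phases (slow extinction SE, oscillatory degeneration OD)
show a long plateau followed by an exponential decay with a
characteristic lifetime ``t_f``; ``t_f`` diverges as ``|d - d_c|^-mu``
on approach to the proliferative phase, which lets ``d_c`` be
extrapolated from lifetime fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from .engine import EnsembleSummary, run_ensemble
from .observables import CorrelationEstimate
from .params import Params, validate_params

__all__ = [
    "PowerLawFit", "CorrelationLengthFit", "TfFit", "LifetimeFit",
    "InfinitePhase", "FinitePhase", "CriticalPoint", "CriticalGrowthFit",
    "fit_power_exponent", "classify_infinite", "locate_critical_d",
    "critical_power_law",
    "fit_correlation_length", "fit_tf", "extrapolate_dc_from_tf",
    "classify_finite", "build_phase_diagram",
]


# ---------------------------------------------------------------------------
# fits

@dataclass
class PowerLawFit:
    exponent: float
    amplitude: float
    window: tuple[float, float]
    r2: float


def fit_power_exponent(x, y, window=None) -> PowerLawFit:
    """Least-squares slope of ``log y`` against ``log x`` within ``window``.

    All ``y`` in the window must be positive and at least 5 points are
    required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is None:
        window = (x.min(), x.max())
    mask = (x >= window[0]) & (x <= window[1]) & (x > 0)
    if mask.sum() < 5:
        raise ValueError("need at least 5 points in the fit window")
    if (y[mask] <= 0).any():
        raise ValueError("non-positive values in the fit window")
    lx, ly = np.log(x[mask]), np.log(y[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(
        exponent=float(slope), amplitude=float(np.exp(intercept)),
        window=(float(window[0]), float(window[1])), r2=r2,
    )


@dataclass
class CorrelationLengthFit:
    alpha: float
    xi: float | None          # None = unbounded (no resolvable exponential cut-off)
    residual: float
    alpha_fixed: bool


def fit_correlation_length(
    corr: CorrelationEstimate,
    alpha: float | None = None,
    window=None,
    xi_cap: float | None = None,
) -> CorrelationLengthFit:
    """Fit ``C(l) ~ l^-alpha exp(-l/xi)`` on positive correlations.

    With ``alpha`` given, only the correlation length is free (the
    protocol for near-critical scans: measure ``alpha`` at the critical
    point, then fix it); otherwise both are fitted.  The fit is linear
    least squares of ``log C`` against ``-alpha log l - l/xi``.  A fitted
    ``xi`` above ``xi_cap`` (default ``20 * l_max``, i.e. beyond any
    resolvable decay) is reported as unbounded (``xi = None``).
    Requires at least 6 usable distances with ``C(l) > 0``.
    """
    l = np.asarray(corr.l, dtype=float)
    C = np.asarray(corr.C, dtype=float)
    if window is None:
        window = (1.0, l.max())
    mask = (l >= max(window[0], 1.0)) & (l <= window[1]) & (C > 0)
    if mask.sum() < 6:
        raise ValueError("need >= 6 usable distances with C(l) > 0")
    ll, lc = l[mask], np.log(C[mask])
    if xi_cap is None:
        xi_cap = 20.0 * float(l.max())

    if alpha is not None:
        def model(x, logA, s):
            return logA - alpha * np.log(x) - s * x
        p0 = (lc[0], 0.1)
        bounds = ([-np.inf, 0.0], [np.inf, np.inf])
    else:
        def model(x, logA, alpha_free, s):
            return logA - alpha_free * np.log(x) - s * x
        p0 = (lc[0], 0.5, 0.1)
        bounds = ([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf])

    popt, _ = curve_fit(model, ll, lc, p0=p0, bounds=bounds, maxfev=20000)
    s = popt[-1]
    alpha_out = float(alpha) if alpha is not None else float(popt[1])
    resid = float(np.linalg.norm(lc - model(ll, *popt)))
    xi = None if s < 1.0 / xi_cap else float(1.0 / s)
    return CorrelationLengthFit(
        alpha=alpha_out, xi=xi, residual=resid, alpha_fixed=alpha is not None
    )


@dataclass
class TfFit:
    """Exponential-tail fit of a decaying active probability."""

    t_f: float | None
    censored: bool
    plateau: float
    plateau_end: float        # time of the first crossing below the threshold
    amplitude: float | None = None


def fit_tf(t, p_act, sessions: int | None = None,
           threshold_frac: float = 0.8) -> TfFit:
    """Characteristic lifetime of a decaying active probability.

    The plateau level is read after the initial transient (at 10 % of the
    record); the exponential ``P_act ~ A exp(-t/t_f)`` is fitted on the
    tail from the first crossing below ``threshold_frac * plateau`` to the
    last time with ``P_act > 1/sessions`` (the single-session resolution
    floor).  If the curve never leaves its plateau the fit is censored
    and ``t_f`` is only bounded below by the record length.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p_act, dtype=float)
    i0 = int(0.1 * len(t))
    plateau = float(p[i0])
    floor = 1.0 / sessions if sessions else 0.0
    if plateau <= floor:
        # decayed before the plateau reference point: fit the whole decay
        plateau = float(p[0])
        i0 = 0
    below = np.nonzero(p[i0:] < threshold_frac * plateau)[0]
    if below.size == 0:
        return TfFit(t_f=None, censored=True, plateau=plateau,
                     plateau_end=float(t[-1]))
    j = i0 + below[0]
    tail = slice(j, None)
    mask = p[tail] > floor
    tt, pp = t[tail][mask], p[tail][mask]
    if tt.size < 2:
        return TfFit(t_f=float(t[-1] - t[j]) or 1.0, censored=False,
                     plateau=plateau, plateau_end=float(t[j]))
    slope, intercept = np.polyfit(tt, np.log(pp), 1)
    if slope >= 0:
        return TfFit(t_f=None, censored=True, plateau=plateau,
                     plateau_end=float(t[j]))
    return TfFit(t_f=float(-1.0 / slope), censored=False, plateau=plateau,
                 plateau_end=float(t[j]), amplitude=float(np.exp(intercept)))


@dataclass
class LifetimeFit:
    d_c: float
    mu: float
    residual: float
    flagged: bool = False


def extrapolate_dc_from_tf(d, t_f, side: str = "above") -> LifetimeFit:
    """Extrapolate the critical point from the lifetime divergence.

    Fits ``log t_f = c - mu log|d - d_c|`` by least squares with
    ``(d_c, mu)`` free, ``side`` indicating whether the data approach the
    divergence from above (``d > d_c``) or below.  Lifetimes that do not
    increase monotonically toward the critical point, or do not vary at
    all, yield a flagged (poor) fit.
    """
    d = np.asarray(d, dtype=float)
    tf = np.asarray(t_f, dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 (d, t_f) points")
    order = np.argsort(d)
    d, tf = d[order], tf[order]
    span = d.max() - d.min()
    ltf = np.log(tf)
    if np.ptp(ltf) < 0.05:
        return LifetimeFit(d_c=float("nan"), mu=0.0, residual=0.0, flagged=True)
    increasing_toward = np.all(np.diff(tf) < 0) if side == "above" \
        else np.all(np.diff(tf) > 0)

    def ssr(dc):
        x = np.log(np.abs(d - dc))
        mu, c = np.polyfit(x, ltf, 1)
        return float(((ltf - (mu * x + c)) ** 2).sum())

    eps = 1e-6 * max(span, 1e-6)
    if side == "above":
        lo, hi = d.min() - 2.0 * span, d.min() - eps
    elif side == "below":
        lo, hi = d.max() + eps, d.max() + 2.0 * span
    else:
        raise ValueError(f"unknown side {side!r}")
    res = minimize_scalar(ssr, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    dc = float(res.x)
    x = np.log(np.abs(d - dc))
    mu, _c = np.polyfit(x, ltf, 1)
    return LifetimeFit(d_c=dc, mu=float(-mu), residual=float(res.fun),
                       flagged=not increasing_toward)


# ---------------------------------------------------------------------------
# classification

def _late_window(n: int, frac: float) -> slice:
    return slice(n - max(int(frac * n), 5), n)


def _log_slope(t, y):
    """Per-step slope of log(y) over points with y > 0; None if < 5 points."""
    mask = y > 0
    if mask.sum() < 5:
        return None
    slope, _ = np.polyfit(t[mask], np.log(y[mask]), 1)
    return float(slope)


@dataclass
class InfinitePhase:
    label: str                # "E", "P", "D" or "indeterminate"
    slope_np: float | None
    slope_ratio: float | None
    slope_nq: float | None
    end_ratio: float | None = None
    indeterminate: bool = False


def classify_infinite(
    ensemble: EnsembleSummary, eps: float = 0.005, window_frac: float = 0.5
) -> InfinitePhase:
    """Classify an ensemble as extinctive / proliferative / degenerative.

    Operates on the late-time window (last ``window_frac`` of the step
    grid).  E: the mean proliferative number decays (log-slope below
    ``-eps`` per step) or has effectively vanished.  D: the mean
    quiescent-to-proliferative ratio grows (log-slope above ``eps``) —
    the expanding quiescent cluster.  P: neither.  When both tests fire
    (deep degeneration also loses proliferative cells under a finite
    horizon), quiescent dominance at the end of the window (ratio > 1)
    decides for D; otherwise the point is flagged indeterminate (scan
    ``d`` more finely).
    """
    w = _late_window(len(ensemble.t), window_frac)
    t = ensemble.t[w].astype(float)
    mnp = ensemble.mean_np[w]
    mnq = ensemble.mean_nq[w]
    slope_np = _log_slope(t, mnp)
    slope_nq = _log_slope(t, mnq)
    ratio_mask = (mnp > 0) & (mnq > 0)
    slope_ratio = (
        _log_slope(t[ratio_mask], mnq[ratio_mask] / mnp[ratio_mask])
        if ratio_mask.sum() >= 5 else None
    )
    end_ratio = (
        float(mnq[ratio_mask][-1] / mnp[ratio_mask][-1])
        if ratio_mask.any() else None
    )
    is_e = slope_np is None or slope_np < -eps
    is_d = slope_ratio is not None and slope_ratio > eps
    if is_e and is_d:
        if end_ratio is not None and end_ratio > 1.0:
            return InfinitePhase("D", slope_np, slope_ratio, slope_nq, end_ratio)
        return InfinitePhase("indeterminate", slope_np, slope_ratio, slope_nq,
                             end_ratio, indeterminate=True)
    if is_e:
        return InfinitePhase("E", slope_np, slope_ratio, slope_nq, end_ratio)
    if is_d:
        return InfinitePhase("D", slope_np, slope_ratio, slope_nq, end_ratio)
    return InfinitePhase("P", slope_np, slope_ratio, slope_nq, end_ratio)


@dataclass
class CriticalPoint:
    d_c: float
    half_width: float
    boundary: str
    log: list[tuple[float, str]] = field(default_factory=list)


def locate_critical_d(
    r: float,
    a: float,
    bracket: tuple[float, float],
    boundary: str = "ep",
    L: int = 64,
    max_steps: int = 300,
    sessions: int = 1000,
    base_seed: int = 0,
    resolution: float = 0.005,
    g: float = 1.0,
    eps: float = 0.005,
) -> CriticalPoint:
    """Bisect the background death probability to a phase boundary.

    ``boundary="ep"`` targets the extinctive/proliferative transition
    (predicate: classified E); ``boundary="pd"`` the proliferative/
    degenerative one (predicate: classified D).  The two bracket
    endpoints must classify differently under the predicate.  Every
    evaluation reuses the same ensemble base seed, so the bisection is
    deterministic given the seed; the result is the bracket midpoint with
    its half-width once the bracket is at most ``resolution`` wide.
    """
    if boundary not in ("ep", "pd"):
        raise ValueError(f"unknown boundary {boundary!r}")
    predicate_label = "E" if boundary == "ep" else "D"
    log: list[tuple[float, str]] = []

    def hits(d):
        ens = run_ensemble(Params(r=r, d=d, a=a, g=g), L, max_steps,
                           sessions, base_seed)
        cls = classify_infinite(ens, eps=eps)
        log.append((float(d), cls.label))
        return cls.label == predicate_label

    lo, hi = float(bracket[0]), float(bracket[1])
    p_lo, p_hi = hits(lo), hits(hi)
    if p_lo == p_hi:
        raise ValueError(
            f"bracket endpoints classify identically "
            f"(predicate {predicate_label!r}: {p_lo}); widen the bracket"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if hits(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return CriticalPoint(
        d_c=0.5 * (lo + hi), half_width=0.5 * (hi - lo),
        boundary=boundary, log=log,
    )


@dataclass
class CriticalGrowthFit:
    """Power-law fit of a growth observable at the refined critical point."""

    d_c: float
    exponent: float
    r2: float
    curvature: float
    window: tuple[float, float]
    evaluations: list[tuple[float, float, float]] = field(default_factory=list)
    # (d, curvature, slope) for every ensemble evaluated during refinement


def _growth_series(ens: EnsembleSummary, observable: str):
    if observable == "np":
        mask = ens.mean_np > 0
        return ens.t[mask].astype(float), ens.mean_np[mask]
    if observable == "ratio":
        mask = (ens.mean_np > 0) & (ens.mean_nq > 0)
        return ens.t[mask].astype(float), ens.mean_nq[mask] / ens.mean_np[mask]
    raise ValueError(f"unknown observable {observable!r}")


def critical_power_law(
    r: float,
    a: float,
    bracket: tuple[float, float],
    observable: str = "np",
    L: int = 64,
    max_steps: int = 300,
    sessions: int = 1000,
    base_seed: int = 0,
    resolution: float = 0.002,
    t_min: float = 10.0,
    g: float = 1.0,
) -> CriticalGrowthFit:
    """Exponent of the critical power-law growth of an ensemble observable.

    At the critical point the observable (mean proliferative number, or
    the quiescent-to-proliferative ratio) grows as a pure power of time;
    off-critical curves bend on log-log scales (up when supercritical,
    down when subcritical).  The critical death probability is therefore
    refined inside ``bracket`` by bisecting on the sign of the quadratic
    (curvature) coefficient of ``log(observable)`` against ``log t`` over
    ``t >= t_min`` — the standard effective-exponent criterion.  Because
    the effective slope varies steeply with ``d`` across the transition
    while each ensemble's curvature estimate is noisy, the exponent is
    not read off a single ensemble: the (curvature, slope) pairs of the
    evaluations nearest the transition are combined by linear regression
    and the slope interpolated to zero curvature, pooling the statistics
    of every ensemble already computed.  The bracket should span the
    transition (e.g. the final bisection bracket of
    :func:`locate_critical_d`, widened by its resolution).
    """

    evals: list[tuple[float, float, float, float]] = []  # d, curv, slope, r2
    # one independent seed per evaluation (all derived from base_seed):
    # with a shared seed the ensembles' curvature errors are coherent and
    # the zero-curvature interpolation cannot average them out
    eval_seeds = iter(int(s) % (2 ** 31) for s in
                      np.random.SeedSequence(base_seed).generate_state(
                          64, dtype=np.uint32))

    def curvature_at(d):
        ens = run_ensemble(Params(r=r, d=d, a=a, g=g), L, max_steps,
                           sessions, int(next(eval_seeds)))
        t, y = _growth_series(ens, observable)
        sel = t >= t_min
        if sel.sum() < 10:
            raise ValueError(f"observable vanished at d={d}: not enough points")
        lx, ly = np.log(t[sel]), np.log(y[sel])
        c2 = np.polyfit(lx, ly, 2)[0]
        slope, intercept = np.polyfit(lx, ly, 1)
        pred = slope * lx + intercept
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(((ly - pred) ** 2).sum()) / ss_tot
        evals.append((float(d), float(c2), float(slope), r2))
        return float(c2), float(slope), r2

    lo, hi = float(min(bracket)), float(max(bracket))
    c_lo, s_lo, r2_lo = curvature_at(lo)
    c_hi, s_hi, r2_hi = curvature_at(hi)
    # deep in the supercritical regime the growing cluster saturates the
    # finite lattice within the horizon and the curve bends down again;
    # walk the low edge toward the transition until it bends up
    walks = 0
    while c_lo < 0 and c_hi < 0 and walks < 4:
        lo = 0.5 * (lo + hi)
        c_lo, s_lo, r2_lo = curvature_at(lo)
        walks += 1
    # supercritical (low d) curves bend up, subcritical down
    if c_lo * c_hi > 0:
        # no sign change anywhere: report the flattest evaluation
        d_c, c, s, r2 = min(evals, key=lambda e: abs(e[1]))
        return CriticalGrowthFit(d_c, s, r2, c, (t_min, max_steps),
                                 [(d, cc, ss) for d, cc, ss, _ in evals])
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        c_m, _, _ = curvature_at(mid)
        if (c_m > 0) == (c_lo > 0):
            lo = mid
        else:
            hi = mid

    # interpolate the effective slope to zero curvature over the
    # evaluations nearest the transition
    near = sorted(evals, key=lambda e: abs(e[1]))[:4]
    d_best, c_best, s_best, r2_best = near[0]
    cs = np.array([c for _, c, _, _ in near])
    if len(near) >= 3 and np.ptp(cs) > 0:
        ss = np.array([s for _, _, s, _ in near])
        ds = np.array([d for d, _, _, _ in near])
        exponent = float(np.polyval(np.polyfit(cs, ss, 1), 0.0))
        d_c = float(np.polyval(np.polyfit(cs, ds, 1), 0.0))
    else:
        exponent, d_c = s_best, d_best
    return CriticalGrowthFit(d_c, exponent, r2_best, c_best,
                             (t_min, max_steps),
                             [(d, cc, ss) for d, cc, ss, _ in evals])


@dataclass
class FinitePhase:
    label: str                # "E", "SE", "P", "OD", "D" or "indeterminate"
    t_f: float | None
    plateau_detected: bool
    diverging_ratio: bool
    indeterminate: bool = False


def classify_finite(
    ensemble: EnsembleSummary,
    t_short: float = 100.0,
    p_min: float = 0.5,
    eps: float = 0.005,
    plateau_min_frac: float = 0.1,
    plateau_min_level: float = 0.25,
) -> FinitePhase:
    """Five-phase finite-size classification from the active probability.

    P: ``P_act`` at the end of the record stays above ``p_min`` with no
    decaying tail.  Collapsing ensembles split by lifetime: quick decay
    (``t_f < t_short``, or no plateau at all) is E or D; a plateau
    (lasting at least ``plateau_min_frac`` of the record at a level of at
    least ``plateau_min_level``) followed by slow decay is the
    quasi-stable band — SE on the extinction side, OD on the degeneration
    side.  SE/OD are never issued for a fast monotone-from-start decay.

    The degeneration side is recognised either by the diverging
    quiescent-to-proliferative ratio of the late-time means, or by the
    collapse proceeding through a quiescent-dominated structure (the peak
    mean quiescent number exceeding the peak mean proliferative number)
    — the finite-size absorbing state "filled with quiescent cells"
    rather than "vacant".
    """
    t = ensemble.t.astype(float)
    pa = ensemble.p_act
    fit = fit_tf(t, pa, sessions=ensemble.sessions)
    inf = classify_infinite(ensemble, eps=eps)
    diverging = (
        inf.label == "D"
        or (inf.slope_ratio is not None and inf.slope_ratio > eps)
        or float(ensemble.mean_nq.max()) > float(ensemble.mean_np.max())
    )
    if fit.censored:
        if pa[-1] > p_min:
            return FinitePhase("P", None, False, diverging)
        return FinitePhase("indeterminate", None, False, diverging,
                           indeterminate=True)
    plateau_detected = (
        fit.plateau_end >= plateau_min_frac * t[-1]
        and fit.plateau >= plateau_min_level
    )
    if pa[-1] > p_min:
        return FinitePhase("P", fit.t_f, plateau_detected, diverging)
    if fit.t_f is not None and fit.t_f >= t_short and plateau_detected:
        return FinitePhase("OD" if diverging else "SE", fit.t_f,
                           plateau_detected, diverging)
    return FinitePhase("D" if diverging else "E", fit.t_f,
                       plateau_detected, diverging)


def build_phase_diagram(
    r: float,
    a_grid,
    d_grid,
    mode: str = "infinite",
    L: int = 64,
    max_steps: int = 300,
    sessions: int = 1000,
    base_seed: int = 0,
    g: float = 1.0,
    finite_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Classify every point of an ``(a, d)`` grid at fixed ``r``.

    Returns a DataFrame with one row per grid point carrying the phase
    label and classification diagnostics; infeasible parameter
    combinations (row-sum constraints violated) are labelled
    ``"infeasible"`` and not simulated.
    """
    if mode not in ("infinite", "finite"):
        raise ValueError(f"unknown mode {mode!r}")
    finite_kwargs = finite_kwargs or {}
    rows = []
    for a in a_grid:
        for d in d_grid:
            params = Params(r=r, d=float(d), a=float(a), g=g)
            row = {"r": r, "a": float(a), "d": float(d), "L": L,
                   "sessions": sessions, "steps": max_steps}
            if not validate_params(params).ok:
                row.update(label="infeasible", t_f=np.nan)
                rows.append(row)
                continue
            ens = run_ensemble(params, L, max_steps, sessions, base_seed)
            if mode == "infinite":
                cls = classify_infinite(ens)
                row.update(label=cls.label, slope_np=cls.slope_np,
                           slope_ratio=cls.slope_ratio, t_f=np.nan)
            else:
                cls = classify_finite(ens, **finite_kwargs)
                row.update(label=cls.label,
                           t_f=np.nan if cls.t_f is None else cls.t_f,
                           plateau=cls.plateau_detected,
                           diverging_ratio=cls.diverging_ratio)
            rows.append(row)
    return pd.DataFrame(rows)


def growth_annotation(turnover_mean: float, xi: float | None,
                      n_p_series=None) -> str:
    """Heuristic, advisory-only sub-pattern label for proliferative phases.

    Compact growth features high turnover and short correlation length;
    a dominant spectral peak in the proliferative count marks oscillatory
    growth; everything else is called scattered.  There are no rigid
    criteria for these sub-patterns, so the label is qualitative.
    """
    if n_p_series is not None:
        x = np.asarray(n_p_series, dtype=float)
        x = x - x.mean()
        if x.size >= 32 and x.std() > 0:
            power = np.abs(np.fft.rfft(x))[1:]
            if power.size > 3 and power.max() > 5.0 * np.median(power):
                return "oscillatory"
    if turnover_mean > 0.1 and (xi is not None and xi < 5.0):
        return "compact"
    if turnover_mean > 0.1:
        return "compact"
    return "scattered"
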