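"""Measurements on trajectories and snapshot sets.

Turnover rate: newly born cells (vacant -> proliferative events) per
living cell per step, averaged over the survival time — the model analogue
of tissue cell-turnover measurements.  Reactivations of quiescent cells
are deliberately not counted as births: a reactivated cell is the same
cell, whereas turnover quantifies replacement.

Lifespan: either the *active* lifespan (first step with no proliferative
cells, the event underlying the active probability) or the *full* one
(lattice entirely vacant or entirely quiescent).

Spatial correlation: the equal-time two-point function of the site state
eta in {-1, 0, 1},

    C(l) = <eta(x) eta(x+l)> - <eta(x)> <eta(x+l)>,

averaged over all sites, both lattice axis directions, and all supplied
(equilibrated) snapshots, with periodic wrap.  Distances are measured
along the lattice axes; the time-lagged version C(l, T>0) is reserved in
the interface but not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import RunTrajectory

__all__ = ["TurnoverEstimate", "Lifespan", "CorrelationEstimate",
           "turnover_rate", "lifespan", "spatial_correlation",
           "stationarity_check"]


def stationarity_check(series, alpha: float = 0.05) -> tuple[bool, float]:
    """Test a sampling window for the absence of a monotone trend.

    Equilibrium snapshots should come from a stationary stretch of the
    trajectory; this runs a Spearman rank correlation of the series
    (e.g. ``N_p`` over the sampling window) against time and reports
    ``(stationary, p_value)`` — stationary when no monotone trend is
    detected at significance ``alpha``.  Constant series are stationary
    by definition.
    """
    from scipy.stats import spearmanr

    y = np.asarray(series, dtype=float)
    if y.size < 8:
        raise ValueError("stationarity check needs at least 8 points")
    if np.ptp(y) == 0:
        return True, 1.0
    rho, p = spearmanr(np.arange(y.size), y)
    return bool(p >= alpha), float(p)


@dataclass
class TurnoverEstimate:
    mean: float
    sd: float
    n_steps: int


@dataclass
class Lifespan:
    """A lifespan measurement; ``censored`` means the event did not occur
    within the simulated horizon, so ``time`` is only a lower bound."""

    time: int
    censored: bool


@dataclass
class CorrelationEstimate:
    l: np.ndarray
    C: np.ndarray
    n_samples: np.ndarray


def turnover_rate(trajectory: RunTrajectory, burn_in: int = 0) -> TurnoverEstimate:
    """Mean and step-to-step s.d. of births per living cell per step.

    Per-step ratios ``births(t) / (N_p(t) + N_q(t))`` are taken over
    steps ``t`` in ``[max(burn_in, 1), absorption)`` (or the end of the
    record if the system never lost its proliferative cells); steps with
    no living cells are excluded.  Raises ``ValueError`` when no step
    qualifies.
    """
    stop = trajectory.absorption_time
    if stop is None:
        stop = len(trajectory.t)
    lo = max(int(burn_in), 1)
    living = trajectory.n_p[lo:stop] + trajectory.n_q[lo:stop]
    births = trajectory.births[lo:stop]
    mask = living > 0
    if not mask.any():
        raise ValueError("turnover undefined: no step with living cells")
    ratios = births[mask] / living[mask]
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return TurnoverEstimate(mean=float(ratios.mean()), sd=sd, n_steps=int(mask.sum()))


def lifespan(trajectory: RunTrajectory, mode: str = "full") -> Lifespan:
    """System lifespan in steps.

    ``mode="active"`` returns the absorption time of the proliferative
    population (the event underlying P_act); ``mode="full"`` the time at
    which the whole lattice is vacant or entirely quiescent.  When the
    event never occurred the result is censored at the last recorded step.
    """
    if mode == "active":
        event = trajectory.absorption_time
    elif mode == "full":
        event = trajectory.full_absorption_time
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if event is None:
        return Lifespan(time=int(trajectory.t[-1]), censored=True)
    return Lifespan(time=int(event), censored=False)


def spatial_correlation(snapshots, l_max: int, lag: int = 0) -> CorrelationEstimate:
    """Equal-time spatial correlation of the site state over snapshots.

    ``snapshots`` is an iterable of ``(L, L)`` lattices (equilibrated
    configurations, possibly pooled over time and sessions).  For each
    axial distance ``l <= l_max`` the estimator pools all sites, both
    +row and +col displacements and all snapshots, then subtracts the
    squared global mean.  ``l_max`` must be below ``L/2`` to avoid
    double-counting through the periodic wrap.  ``lag != 0`` (the time
    interval of the general correlator) is reserved and not implemented.
    """
    if lag != 0:
        raise NotImplementedError("time-lagged correlation is not implemented")
    arr = np.asarray(list(snapshots), dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("snapshots must be a set of 2-D lattices")
    L = arr.shape[1]
    if l_max >= L / 2:
        raise ValueError(f"l_max = {l_max} must be < L/2 = {L / 2}")
    m = arr.mean()
    ls = np.arange(l_max + 1)
    C = np.empty(l_max + 1)
    n_samples = np.empty(l_max + 1, dtype=np.int64)
    for l in ls:
        along_rows = (arr * np.roll(arr, int(l), axis=1)).mean()
        along_cols = (arr * np.roll(arr, int(l), axis=2)).mean()
        C[l] = 0.5 * (along_rows + along_cols) - m * m
        n_samples[l] = arr.shape[0] * L * L * (1 if l == 0 else 2)
    return CorrelationEstimate(l=ls, C=C, n_samples=n_samples)
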