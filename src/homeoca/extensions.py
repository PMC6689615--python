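"""Model variants: oscillatory death rate and threshold-death.

Oscillatory death: the background death probability is driven by an
external sinusoidal rhythm, ``d(t) = d0 (1 + A sin(2 pi t / P))``,
modelling exogenous temporal modulation (the reference rhythm has period
500 steps, about 120 days at the 8.66 h/step calibration, around a
baseline d0 = 0.08).  The modulated value replaces ``d`` in *every*
transition it enters (proliferative death and the quiescent death
channel); amplitude, period and baseline are all configurable.  At
amplitude 0 the variant is bit-identical to the base model under the
same seed.

Threshold death: the stochastic proliferative death draw is replaced by
a deterministic age rule — a cell dies, when updated, once its *active
lifespan* (number of steps spent in the proliferative state; frozen
while quiescent, reset on vacancy) exceeds ``ceil(1/d)``.  At the
single-cell level this matches the mean geometric lifetime ``1/d`` of
the base model, but it turns every configuration without proliferative
cells into an absorbing state and destabilises compact homeostasis over
long times (systematic ageing).  Whether the quiescent death channel is
also thresholded is configurable (default: it keeps its stochastic
form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import RunTrajectory, run_session
from .params import Params, validate_params

__all__ = ["DeathSchedule", "death_at", "run_session_oscillatory",
           "run_session_threshold"]


@dataclass(frozen=True)
class DeathSchedule:
    """Sinusoidal modulation of the background death probability."""

    d0: float
    amplitude: float = 0.0
    period: float = 500.0

    def __post_init__(self):
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")

    @property
    def d_max(self) -> float:
        return self.d0 * (1.0 + self.amplitude)


def death_at(t, schedule: DeathSchedule):
    """Death probability at step ``t`` (vectorised over ``t``)."""
    t = np.asarray(t, dtype=float)
    out = schedule.d0 * (1.0 + schedule.amplitude
                         * np.sin(2.0 * np.pi * t / schedule.period))
    return float(out) if out.ndim == 0 else out


def run_session_oscillatory(
    params: Params,
    schedule: DeathSchedule,
    L: int,
    max_steps: int,
    seed: int,
    init: str | np.ndarray = "single",
    snapshot_times=None,
) -> RunTrajectory:
    """One session with the time-dependent death probability.

    Identical to the base session except that step ``t`` uses ``d(t)``
    from the schedule in both death channels.  Feasibility is checked at
    the schedule's maximum; ``params.d`` is ignored in favour of the
    schedule.  The applied ``d(t)`` trace is recorded on the trajectory.
    """
    peak = Params(params.r, schedule.d_max, params.a, params.g)
    rep = validate_params(peak)
    if not rep.ok:
        raise ValueError(
            "death schedule infeasible at its maximum d(t) = "
            f"{schedule.d_max:.4g}: " + "; ".join(rep.messages())
        )
    d_sched = death_at(np.arange(1, max_steps + 1), schedule)
    base = Params(params.r, schedule.d0, params.a, params.g)
    traj = run_session(
        base, L, max_steps, seed, init=init, snapshot_times=snapshot_times,
        _d_sched=d_sched, _variant="oscillatory",
    )
    return traj


def run_session_threshold(
    params: Params,
    L: int,
    max_steps: int,
    seed: int,
    init: str | np.ndarray = "single",
    snapshot_times=None,
    quiescent_thresholded: bool = False,
) -> RunTrajectory:
    """One session under the threshold implementation of cell death.

    Requires ``d > 0`` (the threshold ``ceil(1/d)`` would otherwise be
    infinite).  A proliferative cell dies deterministically, when
    updated, once its active-lifespan counter strictly exceeds
    ``ceil(1/d)``; with ``quiescent_thresholded`` the quiescent channel's
    ``d`` factor is replaced by the same age indicator, otherwise it
    stays ``d * n_v/4``.  The final age field is recorded on the
    trajectory.
    """
    if params.d <= 0:
        raise ValueError("threshold death requires d > 0")
    threshold = math.ceil(1.0 / params.d)
    return run_session(
        params, L, max_steps, seed, init=init, snapshot_times=snapshot_times,
        _variant="threshold", _age_threshold=threshold,
        _thr_quiescent=quiescent_thresholded,
    )
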