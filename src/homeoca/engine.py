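"""Session and ensemble drivers for the automaton.

A *session* is one realisation: a lattice evolved from an initial
condition for up to ``max_steps`` asynchronous steps.  An *ensemble* is a
set of independent sessions with reproducibly derived seeds, summarised
by the session-averaged counts and the active probability
``P_act(t)`` — the fraction of sessions still containing at least one
proliferative cell at step ``t``.  Sessions absorbed early contribute
their frozen (zero-proliferative) counts at later times, so ensemble
means include extinct sessions as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("homeoca")

from . import _kernels
from .lattice import make_lattice, step, state_counts
from .params import Params

__all__ = ["RunTrajectory", "EnsembleSummary", "run_session", "run_ensemble",
           "derive_seeds"]


@dataclass
class RunTrajectory:
    """Per-step record of one session.

    Arrays are indexed by step ``t = 0 .. max_steps`` (``t = 0`` is the
    initial condition; ``births[0] = 0``).  ``absorption_time`` is the
    first step with no proliferative cells (``None`` if never);
    ``full_absorption_time`` the first step at which the lattice is
    entirely vacant or entirely quiescent.
    """

    t: np.ndarray
    n_p: np.ndarray
    n_q: np.ndarray
    n_v: np.ndarray
    births: np.ndarray
    absorption_time: int | None
    full_absorption_time: int | None
    L: int
    params: Params
    seed: int
    variant: str = "base"
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)
    final_grid: np.ndarray | None = None
    age_field: np.ndarray | None = None
    d_trace: np.ndarray | None = None

    @property
    def max_steps(self) -> int:
        return len(self.t) - 1


@dataclass
class EnsembleSummary:
    """Session-averaged counts and active probability on a step grid."""

    t: np.ndarray
    mean_np: np.ndarray
    mean_nq: np.ndarray
    p_act: np.ndarray
    sessions: int
    L: int
    params: Params
    base_seed: int
    seeds: np.ndarray


def derive_seeds(base_seed: int, sessions: int) -> np.ndarray:
    """Independent per-session seeds derived from one base seed.

    Uses ``numpy.random.SeedSequence`` as the documented counter: session
    ``k`` gets the ``k``-th word of ``SeedSequence(base_seed)``'s output
    stream, a uint32 suitable for the compiled kernel's MT19937.
    """
    ss = np.random.SeedSequence(int(base_seed))
    return ss.generate_state(sessions, dtype=np.uint32)


def _kernel_session(grid, params, d_sched, seed, snap_times, variant_code,
                    age_threshold, thr_quiescent, ages=None):
    if ages is None:
        ages = np.zeros(grid.shape, dtype=np.int64)
    return _kernels.run_kernel(
        grid, ages, float(params.r), float(params.a), float(params.g),
        d_sched, variant_code, int(age_threshold), int(thr_quiescent),
        int(seed), snap_times,
    ), ages


def run_session(
    params: Params,
    L: int,
    max_steps: int,
    seed: int,
    init: str | np.ndarray = "single",
    snapshot_times=None,
    engine: str = "compiled",
    _d_sched: np.ndarray | None = None,
    _variant: str = "base",
    _age_threshold: int = 0,
    _thr_quiescent: bool = False,
) -> RunTrajectory:
    """Run one session and record counts and births at every step.

    The default initial condition seeds one proliferative cell at the
    lattice centre.  ``engine="compiled"`` (default) uses the jitted
    kernel; ``engine="python"`` iterates the reference
    :func:`homeoca.lattice.step` (slower; its RNG stream differs from the
    kernel's, so the two engines agree in distribution, not bit-for-bit).

    Underscore-prefixed arguments are the variant plumbing used by
    :mod:`homeoca.extensions`.
    """
    params.validated()
    if L < 3:
        raise ValueError("L must be at least 3")
    grid = make_lattice(L, init)
    if _d_sched is None:
        d_sched = np.full(max_steps, float(params.d))
    else:
        d_sched = np.asarray(_d_sched, dtype=np.float64)
        if len(d_sched) != max_steps:
            raise ValueError("death schedule length must equal max_steps")
    snap_times = np.asarray(
        sorted(snapshot_times) if snapshot_times is not None else [], dtype=np.int64
    )
    variant_code = (_kernels.VARIANT_THRESHOLD if _variant == "threshold"
                    else _kernels.VARIANT_BASE)

    if engine == "compiled":
        (n_p, n_q, births, absorb, full_absorb, snaps), ages = _kernel_session(
            grid, params, d_sched, seed, snap_times, variant_code,
            _age_threshold, _thr_quiescent,
        )
        snapshots = [(int(tt), snaps[k].copy()) for k, tt in enumerate(snap_times)]
        if logger.isEnabledFor(logging.INFO):
            for tt in range(0, max_steps + 1, 100):
                logger.info("t=%d N_p=%d N_q=%d", tt, n_p[tt], n_q[tt])
    elif engine == "python":
        if _variant != "base":
            raise ValueError("the python engine only implements the base model")
        rng = np.random.default_rng(seed)
        n_p = np.zeros(max_steps + 1, dtype=np.int64)
        n_q = np.zeros(max_steps + 1, dtype=np.int64)
        births = np.zeros(max_steps + 1, dtype=np.int64)
        cp, cq, _ = state_counts(grid)
        n_p[0], n_q[0] = cp, cq
        absorb = -1 if cp > 0 else 0
        full_absorb = 0 if (cp == 0 and (cq == 0 or cq == L * L)) else -1
        snapshots = []
        snap_set = set(int(x) for x in snap_times)
        if 0 in snap_set:
            snapshots.append((0, grid.copy()))
        step_params = params
        for t in range(1, max_steps + 1):
            if full_absorb >= 0:
                n_p[t:] = cp
                n_q[t:] = cq
                break
            if d_sched[t - 1] != params.d:
                step_params = Params(params.r, float(d_sched[t - 1]), params.a, params.g)
            _, tally = step(grid, step_params, rng)
            cp, cq, _ = state_counts(grid)
            n_p[t], n_q[t] = cp, cq
            births[t] = tally.get((0, 1), 0)
            if t % 100 == 0:
                logger.info("t=%d N_p=%d N_q=%d", t, cp, cq)
                logger.debug("t=%d tally=%r", t, tally)
            if absorb < 0 and cp == 0:
                absorb = t
            if full_absorb < 0 and cp == 0 and (cq == 0 or cq == L * L):
                full_absorb = t
            if t in snap_set:
                snapshots.append((t, grid.copy()))
        ages = None
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return RunTrajectory(
        t=np.arange(max_steps + 1),
        n_p=n_p,
        n_q=n_q,
        n_v=L * L - n_p - n_q,
        births=births,
        absorption_time=None if absorb < 0 else int(absorb),
        full_absorption_time=None if full_absorb < 0 else int(full_absorb),
        L=L,
        params=params,
        seed=int(seed),
        variant=_variant,
        snapshots=snapshots,
        final_grid=grid,
        age_field=ages if _variant == "threshold" else None,
        d_trace=d_sched if _d_sched is not None else None,
    )


def run_ensemble(
    params: Params,
    L: int,
    max_steps: int,
    sessions: int,
    base_seed: int,
    init: str | np.ndarray = "single",
) -> EnsembleSummary:
    """Run ``sessions`` independent sessions and summarise them.

    Seeds derive reproducibly from ``base_seed`` (see
    :func:`derive_seeds`).  ``P_act(t)`` is the fraction of sessions with
    at least one proliferative cell at step ``t``; absorbed sessions
    contribute zeros to the count means thereafter.
    """
    if sessions < 1:
        raise ValueError("sessions must be >= 1")
    params.validated()
    seeds = derive_seeds(base_seed, sessions)
    d_sched = np.full(max_steps, float(params.d))
    empty_snaps = np.empty(0, dtype=np.int64)
    sum_np = np.zeros(max_steps + 1)
    sum_nq = np.zeros(max_steps + 1)
    act = np.zeros(max_steps + 1)
    for s in seeds:
        grid = make_lattice(L, init)
        (n_p, n_q, _, _, _, _), _ = _kernel_session(
            grid, params, d_sched, int(s), empty_snaps,
            _kernels.VARIANT_BASE, 0, False,
        )
        sum_np += n_p
        sum_nq += n_q
        act += n_p > 0
    return EnsembleSummary(
        t=np.arange(max_steps + 1),
        mean_np=sum_np / sessions,
        mean_nq=sum_nq / sessions,
        p_act=act / sessions,
        sessions=sessions,
        L=L,
        params=params,
        base_seed=int(base_seed),
        seeds=seeds,
    )
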