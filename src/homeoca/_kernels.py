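"""Compiled Monte-Carlo kernel.

One jitted routine runs a full session for the base model, the
oscillatory-death variant (via a per-step death-probability schedule) and
the threshold-death variant (via per-site active-lifespan counters).

Sampling semantics match :func:`homeoca.lattice.step`: per step, one
uniform random permutation of all sites, sequential in-place updates, one
uniform draw per site compared against cumulative exit probabilities in
the order (1, 0, -1, self).  The RNG is numba's per-thread MT19937 seeded
once per session, so sessions are bit-reproducible given their seed.

Once the lattice is fully absorbed (no proliferative cells and either no
quiescent or no vacant sites) the configuration can never change again;
the kernel then fills the remaining records with the frozen values and
stops sweeping.
"""

import numpy as np
from numba import njit

VARIANT_BASE = 0
VARIANT_THRESHOLD = 1


@njit(cache=False)
def run_kernel(grid, ages, r, a, g, d_sched, variant, age_threshold,
               thr_quiescent, seed, snap_times):
    """Simulate ``len(d_sched)`` steps on ``grid`` (modified in place).

    Parameters
    ----------
    grid : int8 (L, L) array, states in {-1, 0, 1}.
    ages : int64 (L, L) array of active-lifespan counters (threshold
        variant; ignored but still passed for the base variant).
    d_sched : float64 (max_steps,) death probability for each step.
    variant : VARIANT_BASE or VARIANT_THRESHOLD.
    age_threshold : death threshold on the active-lifespan counter
        (threshold variant; a proliferative cell dies, deterministically,
        when updated with counter > age_threshold).
    thr_quiescent : if nonzero, the quiescent death channel is also
        thresholded (indicator replaces the d factor).
    snap_times : sorted int64 array of step indices at which to record
        the lattice (0 = initial condition).

    Returns
    -------
    (n_p, n_q, births, absorption_time, full_absorption_time, snaps)
    with count arrays of length max_steps + 1 (index = step; births[0]=0),
    absorption times as -1 when the event did not occur, and snaps of
    shape (len(snap_times), L, L).
    """
    np.random.seed(seed)
    L = grid.shape[0]
    n_sites = L * L
    n_steps = d_sched.shape[0]
    n_p_arr = np.zeros(n_steps + 1, np.int64)
    n_q_arr = np.zeros(n_steps + 1, np.int64)
    births_arr = np.zeros(n_steps + 1, np.int64)
    snaps = np.zeros((snap_times.shape[0], L, L), np.int8)

    n_p = 0
    n_q = 0
    for i in range(L):
        for j in range(L):
            if grid[i, j] == 1:
                n_p += 1
            elif grid[i, j] == -1:
                n_q += 1
    n_p_arr[0] = n_p
    n_q_arr[0] = n_q
    absorption = -1 if n_p > 0 else 0
    full_absorption = 0 if (n_p == 0 and (n_q == 0 or n_q == n_sites)) else -1

    snap_ptr = 0
    while snap_ptr < snap_times.shape[0] and snap_times[snap_ptr] <= 0:
        snaps[snap_ptr] = grid
        snap_ptr += 1

    for t in range(1, n_steps + 1):
        if full_absorption >= 0:
            # frozen: propagate constants and stop sweeping
            for tt in range(t, n_steps + 1):
                n_p_arr[tt] = n_p
                n_q_arr[tt] = n_q
            while snap_ptr < snap_times.shape[0]:
                snaps[snap_ptr] = grid
                snap_ptr += 1
            break
        d = d_sched[t - 1]
        births = 0
        order = np.random.permutation(n_sites)
        for k in range(n_sites):
            idx = order[k]
            i = idx // L
            j = idx - i * L
            s = grid[i, j]
            iu = i - 1 if i > 0 else L - 1
            ib = i + 1 if i < L - 1 else 0
            jl = j - 1 if j > 0 else L - 1
            jr = j + 1 if j < L - 1 else 0
            npn = 0
            nqn = 0
            v = grid[iu, j]
            if v == 1:
                npn += 1
            elif v == -1:
                nqn += 1
            v = grid[ib, j]
            if v == 1:
                npn += 1
            elif v == -1:
                nqn += 1
            v = grid[i, jl]
            if v == 1:
                npn += 1
            elif v == -1:
                nqn += 1
            v = grid[i, jr]
            if v == 1:
                npn += 1
            elif v == -1:
                nqn += 1
            u = np.random.random()
            if s == 0:
                if u < g * npn * 0.25:
                    grid[i, j] = 1
                    ages[i, j] = 0
                    births += 1
                    n_p += 1
            elif s == 1:
                if variant == VARIANT_THRESHOLD:
                    p_die = 1.0 if ages[i, j] > age_threshold else 0.0
                else:
                    p_die = d
                if u < p_die:
                    grid[i, j] = 0
                    ages[i, j] = 0
                    n_p -= 1
                elif u < p_die + a * (npn + nqn) * 0.25:
                    grid[i, j] = -1
                    n_p -= 1
                    n_q += 1
            else:  # quiescent
                nvn = 4 - npn - nqn
                p_up = r * (nvn * 0.25) * (npn * 0.25)
                if variant == VARIANT_THRESHOLD and thr_quiescent != 0:
                    p_die = (1.0 if ages[i, j] > age_threshold else 0.0) * (nvn * 0.25)
                else:
                    p_die = d * (nvn * 0.25)
                if u < p_up:
                    grid[i, j] = 1
                    n_q -= 1
                    n_p += 1
                elif u < p_up + p_die:
                    grid[i, j] = 0
                    ages[i, j] = 0
                    n_q -= 1
        if variant == VARIANT_THRESHOLD:
            # a cell accrues one unit of active lifespan per step it ends
            # in the proliferative state (newborns included)
            for i in range(L):
                for j in range(L):
                    if grid[i, j] == 1:
                        ages[i, j] += 1
        n_p_arr[t] = n_p
        n_q_arr[t] = n_q
        births_arr[t] = births
        if absorption < 0 and n_p == 0:
            absorption = t
        if full_absorption < 0 and n_p == 0 and (n_q == 0 or n_q == n_sites):
            full_absorption = t
        while snap_ptr < snap_times.shape[0] and snap_times[snap_ptr] == t:
            snaps[snap_ptr] = grid
            snap_ptr += 1

    return n_p_arr, n_q_arr, births_arr, absorption, full_absorption, snaps
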