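"""Lattice construction, neighbourhoods and the reference update step.

States live on a periodic ``L x L`` grid of int8 values in ``{-1, 0, 1}``
(quiescent, vacant, proliferative).  The neighbourhood is Von Neumann
(4 neighbours, periodic wrap); indexing is 0-based ``(row, col)``.

This module carries the *reference* implementation of one asynchronous
update step, written for clarity and used by the exact-enumeration tests.
Production runs go through the compiled kernel in
:mod:`homeoca._kernels` (same sampling semantics, much faster).
"""

from __future__ import annotations

import numpy as np

from .params import Params, validate_params, PROLIFERATIVE, VACANT, QUIESCENT

TRANSITION_ORDER = (1, 0, -1)  # cumulative sampling order; self absorbs the rest


def make_lattice(L: int, init: str | np.ndarray = "single") -> np.ndarray:
    """Build an initial lattice.

    ``init`` may be ``"single"`` (one proliferative cell at the centre
    ``(L//2, L//2)``, the default developmental initial condition),
    ``"empty"``, or an explicit array of values in ``{-1, 0, 1}``.
    """
    if isinstance(init, np.ndarray):
        grid = np.asarray(init, dtype=np.int8).copy()
        if grid.shape != (L, L):
            raise ValueError(f"init grid shape {grid.shape} != ({L}, {L})")
        if not np.isin(grid, (-1, 0, 1)).all():
            raise ValueError("lattice values must be in {-1, 0, 1}")
        return grid
    grid = np.zeros((L, L), dtype=np.int8)
    if init == "single":
        grid[L // 2, L // 2] = PROLIFERATIVE
    elif init != "empty":
        raise ValueError(f"unknown init spec {init!r}")
    return grid


def neighbor_counts(grid: np.ndarray, x: tuple[int, int]) -> tuple[int, int, int]:
    """Counts ``(n_p, n_q, n_v)`` of the 4 Von Neumann neighbours of ``x``.

    Coordinates wrap periodically; ``x`` itself must lie in ``[0, L)^2``.
    """
    L = grid.shape[0]
    i, j = x
    if not (0 <= i < L and 0 <= j < L):
        raise IndexError(f"site {x} outside [0, {L})^2")
    n_p = n_q = 0
    for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
        v = grid[ni % L, nj % L]
        if v == PROLIFERATIVE:
            n_p += 1
        elif v == QUIESCENT:
            n_q += 1
    return n_p, n_q, 4 - n_p - n_q


def transition_vector(
    state: int, counts: tuple[int, int, int], params: Params
) -> dict[int, float]:
    """Per-update transition probabilities for a site.

    Returns a map ``{target_state: probability}`` over all three states;
    the self-transition absorbs the remainder so the entries sum to 1.
    Raises ``ValueError`` if the exit probabilities exceed 1 (infeasible
    parameter/configuration combination).
    """
    n_p, n_q, n_v = counts
    if n_p + n_q + n_v != 4 or min(counts) < 0:
        raise ValueError(f"neighbour counts {counts} must be >= 0 and sum to 4")
    if state == VACANT:
        p_up = params.g * n_p / 4.0
        vec = {PROLIFERATIVE: p_up, QUIESCENT: 0.0}
    elif state == PROLIFERATIVE:
        vec = {VACANT: params.d, QUIESCENT: params.a * (n_p + n_q) / 4.0}
    elif state == QUIESCENT:
        vec = {
            PROLIFERATIVE: params.r * (n_v / 4.0) * (n_p / 4.0),
            VACANT: params.d * (n_v / 4.0),
        }
    else:
        raise ValueError(f"unknown state {state!r}")
    total = sum(vec.values())
    if total > 1.0 + 1e-12:
        raise ValueError(
            f"exit probability {total:.4g} > 1 for state {state}, counts {counts}"
        )
    vec[state] = 1.0 - total
    return vec


def step(
    grid: np.ndarray, params: Params, rng: np.random.Generator
) -> tuple[np.ndarray, dict[tuple[int, int], int]]:
    """One asynchronous time step (reference implementation).

    Every site is updated exactly once, in a fresh uniform random
    permutation fixed at step start; each update samples its transition
    vector against the *current*, partially updated configuration using a
    single uniform draw compared against cumulative probabilities in the
    fixed order ``(1, 0, -1, self)``.  A cell born earlier in the sweep is
    therefore seen (and may itself be updated) by sites later in the order.

    The grid is modified in place and also returned, together with an
    event tally ``{(from_state, to_state): count}`` over non-self
    transitions (births are the ``(0, 1)`` entry).
    """
    L = grid.shape[0]
    tally: dict[tuple[int, int], int] = {}
    order = rng.permutation(L * L)
    for idx in order:
        i, j = divmod(int(idx), L)
        s = int(grid[i, j])
        counts = neighbor_counts(grid, (i, j))
        vec = transition_vector(s, counts, params)
        u = rng.random()
        acc = 0.0
        new = s
        for target in TRANSITION_ORDER:
            if target == s:
                continue
            acc += vec[target]
            if u < acc:
                new = target
                break
        if new != s:
            grid[i, j] = new
            tally[(s, new)] = tally.get((s, new), 0) + 1
    return grid, tally


def state_counts(grid: np.ndarray) -> tuple[int, int, int]:
    """Return ``(N_p, N_q, N_v)`` for a lattice."""
    n_p = int((grid == PROLIFERATIVE).sum())
    n_q = int((grid == QUIESCENT).sum())
    return n_p, n_q, grid.size - n_p - n_q
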