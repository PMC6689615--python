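"""Exact one-step enumeration oracle for tiny lattices.

Computes the exact probability distribution of the lattice configuration
after one asynchronous step by averaging over all update orders
(recursively: each remaining site is equally likely to be updated next)
and branching over every transition outcome.  Independent of the
simulation engines — it uses only the declarative transition vector.
Feasible for 3x3 lattices with few occupied sites thanks to memoisation
on (configuration, remaining-site set).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from homeoca.lattice import transition_vector
from homeoca.params import Params


def one_step_distribution(grid: np.ndarray, params: Params) -> dict[tuple, float]:
    """Exact distribution over final configurations after one step."""
    L = grid.shape[0]
    init = tuple(int(v) for v in grid.ravel())
    memo: dict[tuple, dict[tuple, float]] = {}

    def neigh(cfg, s):
        i, j = divmod(s, L)
        n_p = n_q = 0
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            v = cfg[(ni % L) * L + (nj % L)]
            if v == 1:
                n_p += 1
            elif v == -1:
                n_q += 1
        return (n_p, n_q, 4 - n_p - n_q)

    def rec(cfg: tuple, remaining: frozenset) -> dict[tuple, float]:
        if not remaining:
            return {cfg: 1.0}
        key = (cfg, remaining)
        if key in memo:
            return memo[key]
        out: dict[tuple, float] = defaultdict(float)
        w = 1.0 / len(remaining)
        for s in remaining:
            vec = transition_vector(cfg[s], neigh(cfg, s), params)
            rem2 = remaining - {s}
            for target, pr in vec.items():
                if pr == 0.0:
                    continue
                cfg2 = cfg if target == cfg[s] else cfg[:s] + (target,) + cfg[s + 1:]
                for cf, pf in rec(cfg2, rem2).items():
                    out[cf] += w * pr * pf
        memo[key] = dict(out)
        return memo[key]

    return rec(init, frozenset(range(L * L)))


def count_distribution(grid: np.ndarray, params: Params) -> dict[tuple[int, int], float]:
    """Exact distribution of (N_p, N_q) after one step."""
    out: dict[tuple[int, int], float] = defaultdict(float)
    for cfg, p in one_step_distribution(grid, params).items():
        n_p = sum(1 for v in cfg if v == 1)
        n_q = sum(1 for v in cfg if v == -1)
        out[(n_p, n_q)] += p
    return dict(out)
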