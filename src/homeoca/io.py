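"""Plain-text writers and readers for simulation output.

Snapshot files are space-separated grids of ``{-1, 0, 1}`` with a header
line ``# L=<L> t=<t> seed=<seed>``; trajectories and ensemble summaries
are CSV; run metadata is JSON carrying the full parameter set, seeds,
variant and software version, plus the configuration hash, so every
output file set is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .engine import EnsembleSummary, RunTrajectory

__all__ = ["write_snapshot", "read_snapshot", "write_trajectory_csv",
           "read_trajectory_csv", "write_ensemble_csv", "write_metadata"]


def write_snapshot(path, grid: np.ndarray, t: int, seed: int) -> None:
    L = grid.shape[0]
    header = f"L={L} t={t} seed={seed}"
    np.savetxt(path, grid, fmt="%d", header=header)


def read_snapshot(path) -> tuple[np.ndarray, dict]:
    """Read a snapshot file back into a lattice plus its header metadata."""
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = int(val)
    grid = np.loadtxt(path, dtype=np.int8, ndmin=2)
    if not np.isin(grid, (-1, 0, 1)).all():
        raise ValueError(f"{path}: snapshot contains values outside {{-1,0,1}}")
    return grid, meta


def write_trajectory_csv(path, traj: RunTrajectory) -> None:
    pd.DataFrame({
        "t": traj.t, "n_p": traj.n_p, "n_q": traj.n_q,
        "n_v": traj.n_v, "births": traj.births,
    }).to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ensemble_csv(path, ens: EnsembleSummary) -> None:
    pd.DataFrame({
        "t": ens.t, "mean_np": ens.mean_np, "mean_nq": ens.mean_nq,
        "p_act": ens.p_act, "sessions": ens.sessions,
    }).to_csv(path, index=False)


def write_metadata(path, *, params, L, max_steps, base_seed, variant="base",
                   sessions=None, config_hash=None, extra=None) -> None:
    meta = {
        "software": "homeoca",
        "version": __version__,
        "params": {"r": params.r, "d": params.d, "a": params.a, "g": params.g},
        "L": L,
        "max_steps": max_steps,
        "base_seed": base_seed,
        "variant": variant,
    }
    if sessions is not None:
        meta["sessions"] = sessions
    if config_hash is not None:
        meta["config_hash"] = config_hash
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
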