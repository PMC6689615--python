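import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from homeoca.engine import derive_seeds, run_session
from homeoca.extensions import (
    DeathSchedule, death_at, run_session_oscillatory, run_session_threshold,
)
from homeoca.lattice import make_lattice
from homeoca.observables import lifespan
from homeoca.params import Params


pytestmark = pytest.mark.usefixtures("warm_kernel")


# --- death schedule -------------------------------------------------------

def test_zero_amplitude_is_constant():
    sched = DeathSchedule(d0=0.08, amplitude=0.0)
    t = np.arange(0, 1000)
    assert np.allclose(death_at(t, sched), 0.08)


def test_sinusoid_peak_value():
    sched = DeathSchedule(d0=0.08, amplitude=0.5, period=500.0)
    assert death_at(125, sched) == pytest.approx(0.12)
    assert death_at(375, sched) == pytest.approx(0.04)


def test_periodicity():
    sched = DeathSchedule(d0=0.05, amplitude=0.3, period=500.0)
    t = np.arange(0, 500)
    assert np.allclose(death_at(t, sched), death_at(t + 500, sched))


def test_schedule_validation():
    with pytest.raises(ValueError):
        DeathSchedule(d0=0.1, amplitude=1.2)
    with pytest.raises(ValueError):
        DeathSchedule(d0=0.1, amplitude=0.5, period=0.0)


def test_infeasible_peak_rejected_at_run():
    # a + d_max = 0.6 + 0.45 > 1 violates the arrest row at its peak
    params = Params(r=0.0, d=0.3, a=0.6)
    sched = DeathSchedule(d0=0.3, amplitude=0.5)
    with pytest.raises(ValueError, match="infeasible"):
        run_session_oscillatory(params, sched, 8, 50, seed=0)


# --- oscillatory variant --------------------------------------------------

def test_zero_amplitude_reduces_to_base_model_bitwise():
    params = Params(r=0.5, d=0.08, a=0.3)
    sched = DeathSchedule(d0=0.08, amplitude=0.0)
    base = run_session(params, 12, 150, seed=77)
    osc = run_session_oscillatory(params, sched, 12, 150, seed=77)
    assert np.array_equal(base.n_p, osc.n_p)
    assert np.array_equal(base.n_q, osc.n_q)
    assert np.array_equal(base.births, osc.births)
    assert np.array_equal(base.final_grid, osc.final_grid)


def test_recorded_death_trace_matches_closed_form():
    sched = DeathSchedule(d0=0.08, amplitude=0.4, period=500.0)
    traj = run_session_oscillatory(Params(r=0.5, d=0.08, a=0.3), sched,
                                   10, 120, seed=3)
    assert np.allclose(traj.d_trace, death_at(np.arange(1, 121), sched))


def test_oscillation_does_not_stabilise_homeostasis():
    """Paired-seed comparison in a healthy-homeostasis regime (spiral
    equilibrium at low proliferative density): modulating d around a
    fixed baseline must not lengthen the active lifespan distribution
    (one-sided at 0.05).  The modulation period is shortened so several
    cycles fit the simulated horizon."""
    params = Params(r=2.0, d=0.08, a=0.15)
    sched = DeathSchedule(d0=0.08, amplitude=0.5, period=100.0)
    seeds = derive_seeds(2024, 200)
    base_life, osc_life = [], []
    for s in seeds:
        base_life.append(lifespan(run_session(params, 20, 800, seed=int(s)),
                                  "active").time)
        osc_life.append(lifespan(
            run_session_oscillatory(params, sched, 20, 800, seed=int(s)),
            "active").time)
    stat = mannwhitneyu(osc_life, base_life, alternative="greater")
    assert stat.pvalue > 0.05
    assert np.median(osc_life) <= np.median(base_life)


# --- threshold variant ----------------------------------------------------

def test_threshold_requires_positive_death_rate():
    with pytest.raises(ValueError):
        run_session_threshold(Params(r=0.0, d=0.0, a=0.0), 8, 10, seed=0)


def _isolated_cells_grid(L=40, spacing=4):
    grid = np.zeros((L, L), dtype=np.int8)
    grid[::spacing, ::spacing] = 1
    return grid


def test_threshold_single_cell_lifetime_matches_geometric_mean():
    """Isolated, non-interacting cells (g = 0 so no births, a = 0): the
    deterministic threshold lifetime ceil(1/d)+O(1) matches the base
    model's geometric mean lifetime 1/d within 10 %."""
    d = 0.02
    params = Params(r=0.0, d=d, a=0.0, g=0.0)
    grid = _isolated_cells_grid()
    n0 = grid.sum()

    thr = run_session_threshold(params, 40, 80, seed=1, init=grid)
    mean_life_thr = thr.n_p.sum() / n0

    base = run_session(params, 40, 400, seed=1, init=grid)
    assert base.n_p[-1] == 0
    mean_life_base = base.n_p.sum() / n0

    assert mean_life_thr / (1.0 / d) == pytest.approx(1.0, abs=0.1)
    assert mean_life_base / (1.0 / d) == pytest.approx(1.0, abs=0.1)
    # the threshold rule is deterministic: every cell dies in the same step
    drops = np.nonzero(np.diff(thr.n_p))[0]
    assert len(drops) == 1


def test_threshold_age_field_bookkeeping():
    traj = run_session_threshold(Params(r=0.5, d=0.1, a=0.3), 12, 120, seed=5)
    ages = traj.age_field
    assert ages is not None and (ages >= 0).all()
    assert (ages[traj.final_grid == 0] == 0).all()
    # nobody outlives the threshold by more than the within-step lag
    assert ages[traj.final_grid == 1].max(initial=0) <= np.ceil(1 / 0.1) + 2


def test_fully_thresholded_quiescent_lattice_is_absorbing():
    """With no proliferative cells and fresh age counters, the
    threshold-death dynamics has nothing left to kill: any mixed
    quiescent/vacant configuration is absorbing."""
    grid = make_lattice(10, "empty")
    grid[2:7, 3:8] = -1
    traj = run_session_threshold(Params(r=1.0, d=0.2, a=0.1), 10, 60, seed=9,
                                 init=grid, quiescent_thresholded=True)
    assert np.array_equal(traj.final_grid, grid)
    # the base rules, by contrast, erode the quiescent patch
    base = run_session(Params(r=1.0, d=0.2, a=0.1), 10, 60, seed=9, init=grid)
    assert base.n_q[-1] < (grid == -1).sum()


def test_threshold_late_stage_quiescent_accumulation():
    """Systematic ageing: with both death channels thresholded, cells
    that arrest young become effectively immortal, so after an early
    plateau near the compact-growth equilibrium the quiescent population
    accumulates until the system freezes into one of the many absorbing
    states (no proliferative cells left)."""
    params = Params(r=1.0, d=0.2, a=0.05)
    traj = run_session_threshold(params, 24, 2000, seed=12,
                                 quiescent_thresholded=True)
    early = traj.n_q[200:400].mean()
    late = traj.n_q[-400:].mean()
    assert late > 1.2 * early
    assert traj.absorption_time is not None
    assert traj.n_q[-1] > traj.n_q[:400].max()
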