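# homeoca

A three-state stochastic cellular automaton of multicellular
homeostasis, with its mean-field analysis and absorbing-state
phase-diagram machinery.

## The problem

Tissues maintain themselves through a dynamic balance of cell
division, death and reversible cell-cycle arrest (quiescence). This
package implements a minimal lattice model of that balance — and of
its failure modes, extinction and degenerative ageing — for
computational biologists and statistical physicists studying
homeostasis as a non-equilibrium phase transition.

Sites of a periodic L×L lattice are proliferative (η = 1), quiescent
(η = −1) or vacant (η = 0). Per asynchronous update, with Von Neumann
neighbour counts (n_p, n_q, n_v):

- birth into vacancy: p(0→1) = g·n_p/4 (and p(0→−1) = 0);
- death: p(1→0) = d; arrest (contact inhibition):
  p(1→−1) = a·(n_p + n_q)/4;
- reactivation: p(−1→1) = r·(n_v/4)(n_p/4); quiescent death:
  p(−1→0) = d·n_v/4.

g is fixed at 1, which calibrates the clock: an isolated cell divides
at rate 1/4 per step, doubling time ln2/0.25 ≈ 2.77 steps ≈ 24 h, so
one step ≈ 8.66 h. Configurations without proliferative cells are
absorbing; the fate of an ensemble — extinctive (E), proliferative (P)
or degenerative (D, an expanding quiescent cluster) — depends on
(r, d, a), and quasi-stable finite-size phases (slow extinction SE,
oscillatory degeneration OD) emerge between them. The mean-field
closure is a planar ODE for the densities (ρ_p, ρ_q) whose interior
fixed point (stable spiral at low ρ_p — fragile, healthy homeostasis;
stable node at high ρ_p — robust, tumour-like) organises the phase
structure. Two variants probe robustness: a sinusoidally modulated
death rate d(t), and a threshold implementation of death driven by
per-cell active-lifespan counters.

## Worked example

Mean-field fixed points for a regrowth-dominated parameter set:

```sh
$ homeoca meanfield --r 3.0 --d 0.1 --a 0.25 --out mf_out
(0.000000, 0.000000)  saddle
(0.000000, 1.000000)  saddle
(0.326911, 0.552740)  stable spiral
```

The two absorbing states are saddles; the homeostatic equilibrium
(ρ_p ≈ 0.33, ρ_q ≈ 0.55) is a stable spiral — the oscillation-prone
regime the model identifies with healthy, quiescent-rich tissue.

A single developmental session from one seeded cell, and its summary:

```sh
$ homeoca run --r 3.0 --d 0.1 --a 0.25 --L 50 --steps 2000 --seed 7 --out demo
wrote demo/trajectory.csv (absorption=None, final N_p=144, N_q=1830)
```

The lattice settles into a fluctuating quiescent-rich homeostasis
(here ~6 % proliferative and ~73 % quiescent of 2500 sites — the
stochastic, finite-size system runs quieter than the mean-field fixed
point, as fluctuations push it toward the absorbing wall);
`demo/metadata.json` records the turnover rate (0.026 ± 0.033 births
per living cell per step for this run) and the censored lifespans.

Locating the extinction threshold at r = a = 0 from ensemble growth
curves (this is the expensive one — a few minutes):

```python
from homeoca.criticality import locate_critical_d

cp = locate_critical_d(r=0.0, a=0.0, bracket=(0.4, 0.8), boundary="ep",
                       L=64, max_steps=300, sessions=1000, base_seed=1,
                       resolution=0.02)
print(cp.d_c, "+-", cp.half_width)   # ~0.63 +- 0.006
```

Ensemble-mean proliferative numbers decay beyond d_c ≈ 0.62–0.63 and
expand below it; at the threshold the growth is a power law in time.

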