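# Methods

## The model

`homeoca` simulates a three-state stochastic cellular automaton of
multicellular homeostasis on a periodic L×L square lattice. Each site
holds at most one cell and is in one of three states: proliferative
(η = 1), quiescent (η = −1, reversible cell-cycle arrest) or vacant
(η = 0, dead or empty). Per asynchronous update of a site, transition
probabilities are built from the Von Neumann neighbour counts
(n_p, n_q, n_v), n_p + n_q + n_v = 4:

| from \ to | 1 (proliferative) | 0 (vacant) | −1 (quiescent) |
|---|---|---|---|
| 0  | g·n_p/4 | * | 0 |
| 1  | * | d | a·(n_p+n_q)/4 |
| −1 | r·(n_v/4)·(n_p/4) | d·n_v/4 | * |

The self-transition (*) absorbs the remainder so each row sums to 1.
The four constants are the growth rate g (fixed to 1, setting the time
unit), the background death probability d, the arrest tendency a
(contact inhibition: crowding promotes quiescence) and the regrowth
ability r (reactivation needs both local vacancy and proliferative
neighbours supplying growth signals). Feasibility requires every row
sum ≤ 1 for all 15 neighbour configurations; `validate_params`
enumerates all 45 cases (the binding constraints reduce to g ≤ 1,
a + d ≤ 1, and the quiescent-row maximum, which for r ≳ 4d sits at
n_v = n_p = 2).

With g = 1 an isolated cell divides at rate 1/4 per step, so the model
doubling time is ln 2/0.25 ≈ 2.77 steps; matching a 24 h in-vitro
doubling time calibrates one step to ≈ 8.66 h of real time.

### Updating

One time step updates every site exactly once, in a fresh uniform
random permutation drawn at step start, each update sampling its
transition vector against the current, partially updated configuration.
A cell born earlier within the step is seen — and, if its site occurs
later in the permutation, itself updated — within the same step; this
is the documented consequence of fixing the permutation at step start.
Sampling uses a single uniform draw against cumulative probabilities in
the fixed target order (1, 0, −1, self), which makes runs
bit-reproducible for a given seed. Death is instantaneous replacement
by the vacant state.

Two engines implement identical semantics: a numba-compiled kernel
(default; ~10⁸ site updates/s) and a pure-Python reference step used by
the exact-enumeration tests. Their RNG streams differ (numba's MT19937
permutation is not numpy.Generator's), so they agree in distribution —
verified against an exact one-step enumeration oracle by chi-square on
3×3 lattices — but not bit-for-bit with each other.

Ensembles derive one uint32 seed per session from a base seed through
`numpy.random.SeedSequence`; session order is irrelevant to the
summary. Ensemble means include absorbed sessions as zeros, and the
active probability P_act(t) is the fraction of sessions that still
contain a proliferative cell at step t. Once no proliferative cell
remains anywhere, none can reappear (both gain channels carry n_p), so
P_act is non-increasing by construction.

## Mean-field analysis

Closing the master equation with neighbour occupancies replaced by
global densities gives a planar ODE for (ρ_p, ρ_q) — see
`homeoca.meanfield` for the exact right-hand side. (0,0) and (0,1) are
always fixed points — the images of the stochastic model's absorbing
configurations — and are saddles for 0 < d < 1; ρ_p = 0 is an invariant
wall. The interior fixed point, when present, is the homeostatic
equilibrium: a stable spiral at low proliferative density (fragile,
oscillation-prone — the healthy-homeostasis regime) or a stable node at
high density (robust, tumour-like). The Jacobian is derived
analytically from the right-hand side and cross-checked against central
finite differences; classification follows the standard
trace/determinant/discriminant rules with a 10⁻⁹ degeneracy tolerance.

Interior roots are found numerically (Powell hybrid) from a 21×21
simplex grid of starts, keeping converged roots with residual < 10⁻¹⁰
and merging duplicates within 10⁻⁸; the closed-form leading-order
expressions for the interior point are exposed only as diagnostics
(`leading_order_interior`), because their correction terms are not
available in closed form. Integration uses adaptive RK45 with
rtol 10⁻⁹; the simplex is forward-invariant, so no clipping is applied.

## Observables

**Turnover** is births (0→1 events only; reactivations are the same
cell returning, not replacement) per living cell per step, averaged
over steps from a configurable burn-in to absorption; the quoted spread
is the step-to-step standard deviation (an alternative — across
sessions — would measure between-run variability instead).

**Lifespan** is measured in two modes: *active* (first step with no
proliferative cells — the event behind P_act) and *full* (lattice
entirely vacant or entirely quiescent); runs reaching the horizon
without the event are reported censored.

**Spatial correlation** C(l) = ⟨η(x)η(x+l)⟩ − ⟨η⟩² uses the literal
state values {−1, 0, 1}, axial displacements only (both +row and +col
pooled), periodic wrap, l < L/2, averaged over all sites, the supplied
equilibrated snapshots, and sessions. The time-lagged correlator is
reserved in the interface but not implemented. Near-critical C(l) is
fitted as l^−α·exp(−l/ξ) on log C (linear least squares with α fixed
from the critical point, or both free); a fitted ξ beyond 20·l_max is
reported unbounded.

## Phase classification and critical points

**Infinite-size** classification works on ensemble growth curves over
the late-time window (last half of the record), following the
short-time/modest-lattice protocol: extinctive (E) when the mean
proliferative number decays at log-slope < −ε per step (ε = 0.005);
degenerative (D) when log(N̄_q/N̄_p) grows at slope > ε — the
exponentially expanding quiescent cluster; proliferative (P) otherwise.
When both fire (at a > 0.6 there is no P band and deep-D ensembles also
lose their proliferative cells within the horizon), quiescent dominance
at the window end (ratio > 1) decides for D; otherwise the point is
flagged indeterminate. Critical death probabilities come from bisection
on d with a fixed ensemble base seed (deterministic, nested brackets).

**Critical exponents.** The ε-threshold necessarily places the E/P flip
where the decay rate equals ε, slightly on the subcritical side, where
the growth curve is not the critical power law. Exponents are therefore
measured at the zero-curvature point: within the bisection bracket, d
is refined by bisecting on the sign of the quadratic coefficient of
log(observable) vs log t (off-critical curves bend up when
supercritical, down when subcritical — the standard effective-exponent
criterion). Because each ensemble's curvature estimate is noisy while
the effective slope changes steeply across the transition, the exponent
is interpolated to zero curvature across the evaluations nearest the
transition (independent seeds per evaluation) rather than read off a
single ensemble. At the default protocol (L = 64, t ≤ 300, 10³
sessions) the refined E/P point sits at d ≈ 0.62–0.63 with growth
exponent ≈ 0.15–0.2 (finite-time corrections depress it below the
long-time limit), and the ratio observable at a = 0.7 is a clean power
law with exponent ≈ 1.2–1.3.

**Finite-size** classification reads P_act(t): P if it ends above 0.5
with no decaying tail; otherwise the exponential tail fit
P_act ≈ A·e^(−t/t_f) (from the first crossing below 0.8× the level
after the initial transient, down to the single-session floor) splits
quick collapse (t_f < 100 steps → E or D) from the quasi-stable band
(plateau of at least 10 % of the record at level ≥ 0.25, then slow
decay → SE or OD). The degeneration side is recognised by the diverging
ratio or by collapse through a quiescent-dominated structure (peak
N̄_q > peak N̄_p — the "filled with quiescent cells" absorbing state);
neither SE nor OD is issued without a detected plateau. Lifetimes
t_f(d) diverging toward the proliferative band are extrapolated as
t_f ∝ |d − d_c|^−μ by least squares with (d_c, μ) free; flat or
non-monotone lifetimes are flagged. Sub-pattern annotations
(scattered/compact/oscillatory growth) are heuristic and advisory only;
there are no rigid criteria for them.

## Model variants

**Oscillatory death rate**: d(t) = d0·(1 + A·sin(2πt/P)) replaces d in
*every* channel it enters; waveform amplitude A (default 0.5) and
period P (default 500 steps ≈ 120 days) are configurable, and
feasibility is enforced at the modulation peak. A = 0 reduces
bit-exactly to the base model. In a healthy-homeostasis regime
(e.g. r = 2, a = 0.15, d0 = 0.08) the modulation shortens active
lifespans — external rhythms destabilise the fragile spiral
equilibrium.

**Threshold death**: the stochastic proliferative death draw is
replaced by a deterministic rule — a cell dies when updated once its
active lifespan (steps spent proliferative; incremented at each step
end, frozen while quiescent, reset on vacancy) strictly exceeds
⌈1/d⌉. For an isolated cell this reproduces the base model's mean
lifetime 1/d up to O(1) (within 5 % at d = 0.02), the asserted
single-cell statistical equivalence. Every configuration without
proliferative cells becomes absorbing. Whether the quiescent death
channel is also thresholded is a flag (default off, keeping the
stochastic form): with it on, cells that arrest young are effectively
immortal and the long-run trajectory shows the systematic-ageing
signature — an early plateau near the compact equilibrium followed by
monotone quiescent accumulation into a frozen absorbing state; with it
off, the quiescent density stays stationary in every compact-growth
regime we tested. Both behaviours are exposed; neither is asserted as
canonical.

## Problem sizes and what the tests show

Reference statistics for phase diagrams are 10⁴–10⁵ sessions; this
package's defaults and its test suite use desk-scale ensembles
(10²–2×10³ sessions, L = 20–64, horizons 100–2000 steps), chosen so the
full pipeline — bisection, exponent refinement, finite-size bands,
correlation fits — runs end to end in minutes. Consequences, measured
and documented rather than hidden: critical-point estimates carry
biases of order 0.01 in d from the finite horizon and session count
(the late-time mean ratio at a = 0.7 is dominated by the ~1 % of
sessions still alive at t = 300, so the proliferative/degenerative
threshold lands near d ≈ 0.04 at these statistics); exponent estimates
carry ±0.05-ish finite-time corrections. The synthetic-recovery suites
(power law, correlation length, lifetime, divergence) test the fitting
machinery against known ground truth and are exact up to sampling
noise. All randomness flows from explicit seeds; every test is
deterministic.

## Known limitations

- Square lattice, Von Neumann neighbourhood, asynchronous
  permutation updates only; no migration, mechanics, hexagonal/3-D
  geometries or synchronous updating.
- No stem/progenitor/differentiated distinction; rules are homogeneous
  in space and time (except the two variants).
- Mean-field analysis ignores fluctuations and finite size by
  construction: it predicts no extinction or degeneration at all, and
  is used for fixed-point structure, not quantitative densities.
- Universality-class analysis (directed vs dynamical percolation) and
  pair approximations are out of scope.
- Growth-pattern sub-labels are qualitative; the transition between
  compact/scattered/oscillatory growth has no sharp boundary.
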