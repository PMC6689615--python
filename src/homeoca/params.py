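"""Rule constants of the automaton and their feasibility constraints.

The model has four rate constants:

``g``
    growth rate — probability scale for a vacant site to be filled by a
    daughter of a neighbouring proliferative cell.  Fixed to 1 in the
    reference parametrisation, which sets the time unit (the single-cell
    division rate becomes ``g/4`` per step).
``r``
    regrowth ability — scale of the quiescent → proliferative reactivation,
    which requires both local vacancy (loss of contact inhibition) and
    proliferative neighbours (growth-factor signalling).
``d``
    background death probability — per-step death probability of a
    proliferative cell; the quiescent death channel is attenuated by the
    local vacancy fraction.
``a``
    cell-cycle-arrest tendency — scale of the proliferative → quiescent
    transition (contact inhibition), increasing with living neighbours.

Because the exit probabilities of a site are built from neighbour
fractions, not every ``(r, d, a)`` triple is admissible: for each of the
three site states and each of the 15 Von Neumann neighbour configurations
``(n_p, n_q, n_v)`` with ``n_p + n_q + n_v = 4``, the total exit
probability must not exceed 1 (the self-transition absorbs the
remainder).  :func:`validate_params` enumerates all 45 cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: All Von Neumann neighbour configurations (n_p, n_q, n_v), n_p+n_q+n_v = 4.
NEIGHBOR_CONFIGS: tuple[tuple[int, int, int], ...] = tuple(
    (np_, nq, 4 - np_ - nq) for np_ in range(5) for nq in range(5 - np_)
)

PROLIFERATIVE = 1
VACANT = 0
QUIESCENT = -1

STATES = (PROLIFERATIVE, VACANT, QUIESCENT)


@dataclass(frozen=True)
class Params:
    """Rule constants ``(r, d, a, g)`` of the automaton.

    Construction does not validate feasibility; call :func:`validate_params`
    (or :meth:`Params.validated`) before running simulations.
    """

    r: float
    d: float
    a: float
    g: float = 1.0

    def validated(self) -> "Params":
        """Return ``self`` if feasible, else raise ``ValueError``."""
        report = validate_params(self)
        if not report.ok:
            raise ValueError(
                "infeasible parameters: " + "; ".join(report.messages())
            )
        return self


def exit_probability(state: int, counts: tuple[int, int, int], params: Params) -> float:
    """Total exit probability of ``state`` under neighbour ``counts``.

    This is the row sum of the transition matrix excluding the
    self-transition.
    """
    n_p, n_q, n_v = counts
    if state == VACANT:
        return params.g * n_p / 4.0
    if state == PROLIFERATIVE:
        return params.a * (n_p + n_q) / 4.0 + params.d
    if state == QUIESCENT:
        return params.r * (n_v / 4.0) * (n_p / 4.0) + params.d * (n_v / 4.0)
    raise ValueError(f"unknown state {state!r}")


@dataclass
class ValidityReport:
    """Outcome of :func:`validate_params`.

    ``violations`` lists ``(state, (n_p, n_q, n_v), exit_probability)``
    triples for every row/configuration whose exit probability exceeds 1,
    plus a sentinel for negative parameters.
    """

    ok: bool
    violations: list[tuple] = field(default_factory=list)

    def messages(self) -> list[str]:
        out = []
        for item in self.violations:
            if item[0] == "negative":
                out.append(f"parameter {item[1]} = {item[2]} is negative")
            else:
                state, counts, p = item
                out.append(
                    f"state {state} row with neighbours (n_p, n_q, n_v)="
                    f"{counts}: exit probability {p:.4g} > 1"
                )
        return out


def validate_params(params: Params) -> ValidityReport:
    """Check every row-sum constraint over all 15 neighbour configurations.

    Always returns a report (never raises).  ``ok`` is True iff all
    parameters are non-negative and, for each state and each neighbour
    configuration, the total exit probability is at most 1.
    """
    violations: list[tuple] = []
    for name in ("r", "d", "a", "g"):
        val = getattr(params, name)
        if val < 0:
            violations.append(("negative", name, val))
    if not violations:
        for state in STATES:
            for counts in NEIGHBOR_CONFIGS:
                p = exit_probability(state, counts, params)
                if p > 1.0 + 1e-12:
                    violations.append((state, counts, p))
    return ValidityReport(ok=not violations, violations=violations)


def doubling_time(params: Params) -> float:
    """Single-cell doubling time, in steps, implied by the birth rule.

    An isolated proliferative cell converts each of its 4 vacant
    neighbours with probability ``g/4`` per step, i.e. it divides at rate
    ``g/4`` per step, so the exponential doubling time is
    ``ln 2 / (g/4)`` steps (≈ 2.77 steps at ``g = 1``).
    """
    import math

    if params.g <= 0:
        raise ValueError("doubling time undefined for g <= 0")
    return math.log(2.0) / (params.g / 4.0)


def hours_per_step(params: Params, real_doubling_hours: float = 24.0) -> float:
    """Real-time calibration of one step.

    Matching the model doubling time against a measured single-cell
    doubling time (default 24 h, typical of cells in vitro) gives the
    real-time span of one automaton step (≈ 8.66 h at ``g = 1``).
    """
    return real_doubling_hours / doubling_time(params)
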