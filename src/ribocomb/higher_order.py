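"""Three-drug combinations in the slow-growth limit, and the maxent bridge.

At near-zero growth with transport-dominated drug levels, ribosome
occupancy by three independently binding drugs reduces to a reversible
jump process on the eight occupancy states (free, three single-bound,
three double-bound, triple-bound).  Pairwise competition removes states.
The stationary distribution gives closed-form responses; the
mechanism-independent entropy-maximization formula
``y_ABC = y_A*y_BC + y_B*y_AC + y_C*y_AB - 2*y_A*y_B*y_C``
reproduces them exactly from single and pairwise marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .single_drug import GrowthLaws

__all__ = [
    "TripleResponses",
    "TripleBindingDiagram",
    "maxent_laws",
    "triple_slow_growth",
    "maxent_triple",
    "consistency_report",
]

_DRUGS = ("A", "B", "C")


def maxent_laws() -> GrowthLaws:
    """Growth laws with ``lambda0 = lambda_max`` (unit slow-growth prefactor).

    The maxent formula composes responses multiplicatively, which matches
    the slow-growth closed forms exactly only when the ``lambda_max /
    lambda0`` prefactor is one; consistency checks are run at this point.
    """
    base = GrowthLaws()
    return GrowthLaws(base.kappa_t, base.r_min, base.r_max, base.lambda_max)


@dataclass(frozen=True)
class TripleResponses:
    """Single, pairwise and (optionally) triple relative responses, all in [0, 1]."""

    y_a: float
    y_b: float
    y_c: float
    y_ab: float
    y_ac: float
    y_bc: float
    y_abc: float | None = None


@dataclass(frozen=True)
class TripleBindingDiagram:
    """Rescaled concentrations plus the set of pairs that cannot co-occupy.

    ``competitive_pairs`` contains two-letter keys from {"AB", "AC", "BC"}.
    """

    c_prime: tuple[float, float, float]
    competitive_pairs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pairs = frozenset("".join(sorted(p)) for p in self.competitive_pairs)
        if not pairs <= {"AB", "AC", "BC"}:
            raise ValueError("competitive pairs must be among AB, AC, BC")
        object.__setattr__(self, "competitive_pairs", pairs)
        if any(c < 0 for c in self.c_prime):
            raise ValueError("rescaled concentrations must be >= 0")

    def allowed_states(self) -> list[frozenset[str]]:
        states = []
        for k in range(4):
            for combo in combinations(_DRUGS, k):
                s = frozenset(combo)
                if any(set(p) <= s for p in self.competitive_pairs):
                    continue
                states.append(s)
        return states


def triple_slow_growth(diagram: TripleBindingDiagram,
                       laws: GrowthLaws | None = None) -> float:
    """Relative growth from the occupancy-state balance of the diagram.

    Builds the master-equation generator over the allowed occupancy
    states (binding into state+drug at rate ``c'_i``, unbinding at unit
    rate), solves for the stationary distribution and returns
    ``(lambda_max/lambda0)`` times the unblocked fraction.  Equals
    ``(lambda_max/lambda0) / prod(1 + c'_i)`` without competition and the
    corresponding restricted-partition closed forms with it.
    """
    laws = laws or maxent_laws()
    cp = dict(zip(_DRUGS, diagram.c_prime))
    states = diagram.allowed_states()
    index = {s: k for k, s in enumerate(states)}
    n = len(states)
    gen = np.zeros((n, n))
    for s, k in index.items():
        for drug in _DRUGS:
            if drug in s:
                t = s - {drug}
                rate = 1.0  # unbinding
            else:
                t = s | {drug}
                rate = cp[drug]
                if t not in index:
                    continue
            j = index[t]
            gen[j, k] += rate
            gen[k, k] -= rate
    a = np.vstack([gen, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return float(laws.lambda_max / laws.lambda0 * pi[index[frozenset()]])


def maxent_triple(responses: TripleResponses) -> float:
    """Mechanism-independent triple response from single and pairwise responses."""
    r = responses
    for v in (r.y_a, r.y_b, r.y_c, r.y_ab, r.y_ac, r.y_bc):
        if not (0.0 <= v <= 1.0 + 1e-12):
            raise ValueError("responses must lie in [0, 1]")
    return (r.y_a * r.y_bc + r.y_b * r.y_ac + r.y_c * r.y_ab
            - 2.0 * r.y_a * r.y_b * r.y_c)


def _marginal(diagram: TripleBindingDiagram, keep: set[str],
              laws: GrowthLaws) -> float:
    cp = tuple(c if d in keep else 0.0 for d, c in zip(_DRUGS, diagram.c_prime))
    return triple_slow_growth(TripleBindingDiagram(cp, diagram.competitive_pairs), laws)


def consistency_report(diagram_samples, laws: GrowthLaws | None = None) -> float:
    """Max deviation between the maxent prediction and the diagram solver.

    ``diagram_samples`` is an iterable of :class:`TripleBindingDiagram`;
    for each, single and pairwise marginals are computed from the solver
    itself (other concentrations set to zero) and fed through the maxent
    formula.
    """
    laws = laws or maxent_laws()
    worst = 0.0
    for diagram in diagram_samples:
        resp = TripleResponses(
            y_a=_marginal(diagram, {"A"}, laws),
            y_b=_marginal(diagram, {"B"}, laws),
            y_c=_marginal(diagram, {"C"}, laws),
            y_ab=_marginal(diagram, {"A", "B"}, laws),
            y_ac=_marginal(diagram, {"A", "C"}, laws),
            y_bc=_marginal(diagram, {"B", "C"}, laws),
        )
        full = triple_slow_growth(diagram, laws)
        worst = max(worst, abs(maxent_triple(resp) - full))
    return worst
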