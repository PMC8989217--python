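"""Incremental cost-effectiveness analysis between two strategies.

Implements the standard pairwise decision rules: dominance classification
first (an ICER is meaningless when one strategy is both cheaper and more
effective), ICER = ΔCost/ΔQALYs only in the trade-off quadrants, acceptance
against a willingness-to-pay (WTP) threshold, and net monetary benefit
NMB = WTP·ΔQALYs − ΔCost.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cohort import CohortOutcome

__all__ = ["Verdict", "ComparisonResult", "compare", "DEFAULT_WTP"]

#: base-case willingness-to-pay threshold: 1x GDP per capita of Hong Kong
#: in 2020, USD per QALY.  The 3x-GDP variant is a configuration choice.
DEFAULT_WTP = 46_450.0


class Verdict(str, enum.Enum):
    """Outcome of a pairwise comparison, from the comparator's viewpoint."""

    DOMINANT = "dominant"  # comparator more effective at lower cost
    DOMINATED = "dominated"  # comparator less effective at higher cost
    ICER_BELOW_WTP = "icer_below_wtp"
    ICER_ABOVE_WTP = "icer_above_wtp"
    INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental result of comparator vs reference strategy."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    verdict: Verdict
    nmb: float
    wtp: float

    @property
    def cost_effective(self) -> bool:
        """Preferred at the stated WTP (dominant, or ICER below threshold)."""
        return self.verdict in (Verdict.DOMINANT, Verdict.ICER_BELOW_WTP)


def compare(
    reference: CohortOutcome,
    comparator: CohortOutcome,
    wtp: float = DEFAULT_WTP,
    reference_label: str = "reference",
    comparator_label: str = "comparator",
) -> ComparisonResult:
    """Incremental analysis of ``comparator`` against ``reference``.

    Deltas are comparator minus reference.  Dominance is classified before
    any division: the ICER is computed (and compared with ``wtp``) only when
    the two strategies trade cost against effectiveness.  Ties on both axes
    are *indifferent*; a tie on exactly one axis collapses to weak dominance.
    """
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    dc = comparator.cost - reference.cost
    dq = comparator.qalys - reference.qalys
    nmb = wtp * dq - dc

    icer: float | None = None
    if dq == 0.0 and dc == 0.0:
        verdict = Verdict.INDIFFERENT
    elif dq >= 0.0 and dc <= 0.0:
        verdict = Verdict.DOMINANT
    elif dq <= 0.0 and dc >= 0.0:
        verdict = Verdict.DOMINATED
    else:
        icer = dc / dq
        verdict = Verdict.ICER_BELOW_WTP if icer < wtp else Verdict.ICER_ABOVE_WTP

    return ComparisonResult(
        reference=reference_label,
        comparator=comparator_label,
        delta_cost=dc,
        delta_qalys=dq,
        icer=icer,
        verdict=verdict,
        nmb=nmb,
        wtp=wtp,
    )
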