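"""Incremental cost-effectiveness metrics and dominance classification.

Conventions follow standard health-economics practice: the
cost-effectiveness plane has incremental QALYs on the x-axis and
incremental cost on the y-axis.  An intervention in the south-east quadrant
(cheaper and more effective) dominates the comparator.  A bare negative
ICER is ambiguous — it arises in both the SE and NW quadrants — so results
always carry their quadrant label.
"""

from __future__ import annotations

import dataclasses
import math

from .tree import StrategyOutcome

__all__ = ["IncrementalResult", "incremental", "classify_quadrant", "net_benefit"]

_DOMINANCE = {
    "SE": "intervention dominant",
    "NW": "comparator dominant",
    "NE": "trade-off NE",
    "SW": "trade-off SW",
}


def classify_quadrant(delta_qaly: float, delta_cost: float) -> str:
    """CE-plane quadrant of an incremental pair.

    Boundary convention: a strictly cheaper intervention with no QALY gain
    falls in SW; a non-cheaper one with no QALY loss falls in NE.  Dominance
    therefore requires strict inequalities on both axes.
    """
    if delta_cost < 0.0:
        return "SE" if delta_qaly > 0.0 else "SW"
    return "NW" if delta_qaly < 0.0 else "NE"


def net_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` (GBP/QALY)."""
    return wtp * delta_qaly - delta_cost


@dataclasses.dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is NaN when ``delta_qaly`` is zero (undefined ratio).  ``nmb``
    is the net monetary benefit at the stored willingness-to-pay threshold;
    positive NMB means the intervention is preferred at that threshold.
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float
    quadrant: str
    dominance: str
    wtp: float
    nmb: float

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer)

    def to_dict(self) -> dict[str, float | str]:
        return dataclasses.asdict(self)


def incremental(
    intervention: StrategyOutcome,
    comparator: StrategyOutcome,
    wtp: float = 20000.0,
) -> IncrementalResult:
    """Incremental cost, QALYs, ICER, quadrant and NMB for one comparison."""
    delta_cost = intervention.expected_cost - comparator.expected_cost
    delta_qaly = intervention.expected_qaly - comparator.expected_qaly
    icer = delta_cost / delta_qaly if delta_qaly != 0.0 else math.nan
    quadrant = classify_quadrant(delta_qaly, delta_cost)
    return IncrementalResult(
        intervention=intervention.name,
        comparator=comparator.name,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        quadrant=quadrant,
        dominance=_DOMINANCE[quadrant],
        wtp=wtp,
        nmb=net_benefit(delta_cost, delta_qaly, wtp),
    )
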