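"""Pairwise incremental cost-effectiveness comparison.

The incremental cost-effectiveness ratio (ICER) is the incremental cost of
the reference arm over a comparator divided by its incremental QALYs.  When
the reference is cheaper and more effective it dominates ("cost-saving");
when costlier and less effective it is dominated; a ratio is reported only
when both increments share a sign.  South-west-quadrant ratios (cheaper and
less effective) are flagged explicitly rather than reported as bare numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

DEFAULT_WTP = 30_000.0  # EUR per QALY, customary Spanish threshold

COST_SAVING = "cost-saving"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"
CHEAPER_EQUAL = "cheaper-equal"
COSTLIER_EQUAL = "costlier-equal"
ICER_LABEL = "icer"


@dataclass(frozen=True)
class CEAResult:
    reference_arm: str
    comparator_arm: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]          # EUR/QALY; None when no ratio is defined
    label: str                     # cost-saving | dominated | icer | ...
    quadrant: str                  # NE / NW / SE / SW / degenerate
    threshold_pass: bool

    @property
    def icer_or_label(self) -> str:
        if self.label == ICER_LABEL:
            suffix = " (south-west)" if self.quadrant == "SW" else ""
            return f"{self.icer:,.0f}{suffix}"
        return self.label

    def as_dict(self) -> dict:
        return {
            "reference": self.reference_arm,
            "comparator": self.comparator_arm,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "label": self.label,
            "quadrant": self.quadrant,
            "threshold_pass": self.threshold_pass,
        }


def compare(ref: tuple[float, float], comp: tuple[float, float],
            ref_arm: str = "reference", comp_arm: str = "comparator",
            wtp: float = DEFAULT_WTP) -> CEAResult:
    """Compare (cost, QALY) pairs; reference minus comparator increments."""
    delta_cost = ref[0] - comp[0]
    delta_qaly = ref[1] - comp[1]

    icer: Optional[float] = None
    if delta_qaly == 0.0:
        if delta_cost == 0.0:
            label, quadrant = EQUIVALENT, "degenerate"
        elif delta_cost < 0.0:
            label, quadrant = CHEAPER_EQUAL, "degenerate"
        else:
            label, quadrant = COSTLIER_EQUAL, "degenerate"
    elif delta_cost < 0.0 and delta_qaly > 0.0:
        label, quadrant = COST_SAVING, "SE"
    elif delta_cost > 0.0 and delta_qaly < 0.0:
        label, quadrant = DOMINATED, "NW"
    elif delta_cost == 0.0:
        label = COST_SAVING if delta_qaly > 0.0 else DOMINATED
        quadrant = "SE" if delta_qaly > 0.0 else "NW"
    else:
        icer = delta_cost / delta_qaly
        label = ICER_LABEL
        quadrant = "NE" if delta_cost > 0.0 else "SW"

    result = CEAResult(ref_arm, comp_arm, delta_cost, delta_qaly, icer,
                       label, quadrant, threshold_pass=False)
    return CEAResult(ref_arm, comp_arm, delta_cost, delta_qaly, icer,
                     label, quadrant,
                     threshold_pass=threshold_check(result, wtp))


def threshold_check(result: CEAResult, wtp: float = DEFAULT_WTP) -> bool:
    """Is the reference acceptable at the stated willingness to pay?

    Cost-saving (and cheaper-equal) always passes; a north-east ICER passes
    below the threshold; a south-west ratio passes when the savings per QALY
    forgone exceed the threshold; dominated never passes.
    """
    if result.label in (COST_SAVING, CHEAPER_EQUAL, EQUIVALENT):
        return True
    if result.label in (DOMINATED, COSTLIER_EQUAL):
        return False
    assert result.icer is not None
    if result.quadrant == "SW":
        return result.icer > wtp
    return result.icer < wtp
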