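"""Pairwise cost-effectiveness statistics.

Incremental costs and effects between two strategies, the incremental
cost-effectiveness ratio (ICER) with full dominance-quadrant handling, and
net monetary benefit at a willingness-to-pay threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .economics import EconomicOutcome

__all__ = ["CEAResult", "compute_icer", "format_icer"]

#: dominance / quadrant labels a comparison can carry
LABELS = ("icer", "dominant", "dominated", "equivalent", "southwest")


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of a new strategy against a reference.

    ``icer`` is numeric only in the north-east quadrant (more costly, more
    effective) and — flagged via ``label == 'southwest'`` — in the south-west
    quadrant, where a *higher* ratio is favourable and a bare number would
    invert the decision rule.  ``dominant`` means less costly and more
    effective; ``dominated`` the reverse.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly: float = math.nan
    icer: float | None = None
    label: str = "icer"

    def nmb_at(self, wtp: float) -> float:
        """Incremental net monetary benefit ``wtp*ΔE − ΔC``."""
        return wtp * self.delta_qaly - self.delta_cost


def compute_icer(outcome_new: EconomicOutcome,
                 outcome_ref: EconomicOutcome) -> CEAResult:
    """Compare two arm outcomes from the same parameter draw.

    All four cost/effect quadrants are defined: a numeric ratio in the
    north-east, ``dominant``/``dominated`` labels in the off-diagonal
    quadrants, a flagged ratio in the south-west, and sign-of-cost labels
    when the effect difference is exactly zero.
    """
    dc = outcome_new.total_cost - outcome_ref.total_cost
    de = outcome_new.qaly - outcome_ref.qaly
    dly = outcome_new.ly - outcome_ref.ly

    if de == 0.0:
        if dc == 0.0:
            label, icer = "equivalent", None
        else:
            label, icer = ("dominated" if dc > 0.0 else "dominant"), None
    elif de > 0.0:
        if dc <= 0.0:
            label, icer = "dominant", None
        else:
            label, icer = "icer", dc / de
    else:  # de < 0
        if dc >= 0.0:
            label, icer = "dominated", None
        else:
            label, icer = "southwest", dc / de
    return CEAResult(delta_cost=dc, delta_qaly=de, delta_ly=dly,
                     icer=icer, label=label)


def format_icer(result: CEAResult) -> str:
    """Display form: dominance labels, or the ratio rounded to whole euros."""
    if result.icer is None:
        return result.label
    rounded = math.floor(result.icer + 0.5)  # half-up, matching reports
    suffix = " (south-west)" if result.label == "southwest" else ""
    return f"€{rounded:,.0f}/QALY{suffix}"
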