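"""Combine the RI classification and the admission MEOWS result into the
binary exposure used by the diagnostic evaluation: "moderate or high" versus
"low".

The default combination is disjunctive — a record is moderate-or-high if
its overall RI level is moderate/high OR its admission MEOWS total reaches
the review threshold (total >= 3).  Alternative rules (``ri_only``,
``meows_only``) are available so the evaluation can be rerun under either
instrument alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .meows import MEOWSResult, TriggerCategory, ValidationError
from .risk import RIResult, RiskLevel

__all__ = ["CombinedLevel", "TriageDecision", "combined_level", "COMBINATION_RULES"]

COMBINATION_RULES = ("disjunction", "ri_only", "meows_only")


class UnclassifiableError(ValueError):
    """Neither an RI result nor a MEOWS result is available for the record."""


@dataclass
class TriageDecision:
    combined_level: str                 # "low" | "moderate_or_high"
    basis: List[str] = field(default_factory=list)  # which sources fired
    meows_total: Optional[int] = None
    ri_overall: Optional[RiskLevel] = None

    @property
    def positive(self) -> bool:
        return self.combined_level == "moderate_or_high"


def combined_level(
    ri: Optional[RIResult],
    meows: Optional[MEOWSResult],
    rule: str = "disjunction",
) -> TriageDecision:
    """Dichotomize a record's admission assessment.

    ``basis`` lists the sources that fired (RI conditions at moderate/high,
    and/or the MEOWS trigger); the decision is moderate-or-high exactly when
    ``basis`` is non-empty under the chosen rule.
    """
    if rule not in COMBINATION_RULES:
        raise ValidationError(f"unknown combination rule {rule!r}")
    if ri is None and meows is None:
        raise UnclassifiableError("record has neither RI nor MEOWS result")

    basis: List[str] = []
    if rule in ("disjunction", "ri_only") and ri is not None:
        for cond in ("hemorrhage", "preeclampsia", "sepsis"):
            if getattr(ri, cond) >= RiskLevel.MODERATE:
                basis.append(f"ri:{cond}:{getattr(ri, cond).name.lower()}")
    if rule in ("disjunction", "meows_only") and meows is not None:
        if meows.trigger_category in (TriggerCategory.REVIEW, TriggerCategory.ESCALATE):
            basis.append(f"meows:{meows.trigger_category.value}")

    return TriageDecision(
        combined_level="moderate_or_high" if basis else "low",
        basis=basis,
        meows_total=None if meows is None else meows.total,
        ri_overall=None if ri is None else ri.overall,
    )
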