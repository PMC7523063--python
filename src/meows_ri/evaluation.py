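"""Diagnostic-performance and feasibility evaluation.

Given record-level triage decisions (moderate-or-high vs low) and the
composite morbidity outcome (any of postpartum hemorrhage, infection,
pre-eclampsia before discharge), this module builds the 2x2 contingency
table and derives the standard test statistics — sensitivity, specificity,
predictive values, accuracy, the relative risk with its Katz log-method 95%
confidence interval, and the Pearson chi-square association test.  It also
provides the feasibility audit (fraction of bedside forms fully / partially
/ not completed) and top-k Likert summaries of staff-experience questions.

Conventions: proportions are returned in [0, 1]; ``percent`` rounds
half-up to one decimal for chart-style reporting.  A statistic whose
denominator is zero is reported as ``None`` (undefined) while the others
are still computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .meows import ValidationError
from .triage import TriageDecision

__all__ = [
    "ContingencyTable",
    "DiagnosticSummary",
    "CompletenessReport",
    "LikertTable",
    "contingency",
    "diagnostics",
    "relative_risk",
    "chi_square",
    "summarize",
    "completeness_audit",
    "likert_summary",
    "composite_morbidity",
    "percent",
    "DEFAULT_LIKERT_QUESTIONS",
]


def percent(p: Optional[float], decimals: int = 1) -> Optional[float]:
    """Proportion -> percentage, rounded half-up (97.25% -> 97.3)."""
    if p is None:
        return None
    q = Decimal(10) ** -decimals
    return float(Decimal(str(p * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: exposure = moderate/high triage, outcome = morbidity.

    tp = moderate/high & morbid, fp = moderate/high & not,
    fn = low & morbid, tn = low & not.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n == 0:
            raise ValidationError("empty contingency table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


@dataclass
class DiagnosticSummary:
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    relative_risk: Optional[float] = None
    rr_ci_low: Optional[float] = None
    rr_ci_high: Optional[float] = None
    chi_square: Optional[float] = None
    p_value: Optional[float] = None
    n: int = 0


def contingency(
    decisions: Sequence[TriageDecision],
    outcomes: Sequence[bool],
) -> ContingencyTable:
    """Cross-tabulate triage decisions against morbidity outcomes.

    Inputs must be record-aligned and already restricted to analyzable
    records (both predictor and outcome present).
    """
    if len(decisions) != len(outcomes):
        raise ValidationError(
            f"{len(decisions)} decisions vs {len(outcomes)} outcomes"
        )
    if not decisions:
        raise ValidationError("no analyzable records")
    tp = fp = fn = tn = 0
    for d, y in zip(decisions, outcomes):
        pos = d.positive if isinstance(d, TriageDecision) else bool(d)
        if pos and y:
            tp += 1
        elif pos:
            fp += 1
        elif y:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def diagnostics(t: ContingencyTable) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV and accuracy from the 2x2 table."""
    return DiagnosticSummary(
        sensitivity=_ratio(t.tp, t.tp + t.fn),
        specificity=_ratio(t.tn, t.tn + t.fp),
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.tn + t.fn),
        accuracy=_ratio(t.tp + t.tn, t.n),
        n=t.n,
    )


def relative_risk(
    t: ContingencyTable,
    alpha: float = 0.05,
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Relative risk of morbidity (moderate/high vs low) with Katz CI.

    rr = [tp/(tp+fp)] / [fn/(fn+tn)]; the 100(1-alpha)% CI is the Katz
    log method, exp(ln rr +/- z * sqrt(1/tp - 1/(tp+fp) + 1/fn - 1/(fn+tn))).
    When any cell is zero the Haldane-Anscombe 0.5 continuity correction is
    applied to all four cells; a zero exposed or unexposed margin leaves the
    statistic undefined (None).
    """
    tp, fp, fn, tn = float(t.tp), float(t.fp), float(t.fn), float(t.tn)
    if tp + fp == 0 or fn + tn == 0:
        return None, None, None
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    risk_exposed = tp / (tp + fp)
    risk_unexposed = fn / (fn + tn)
    if risk_unexposed == 0:
        return None, None, None
    rr = risk_exposed / risk_unexposed
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / tp - 1 / (tp + fp) + 1 / fn - 1 / (fn + tn))
    return rr, rr * math.exp(-z * se), rr * math.exp(z * se)


def chi_square(
    t: ContingencyTable,
    correction: bool = False,
) -> Tuple[Optional[float], Optional[float]]:
    """Pearson chi-square (1 df) on the 2x2 table; Yates correction optional.

    Undefined (None, None) when a row or column margin is zero.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return None, None
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def summarize(t: ContingencyTable, alpha: float = 0.05) -> DiagnosticSummary:
    """Full diagnostic summary: proportions + relative risk + chi-square."""
    s = diagnostics(t)
    s.relative_risk, s.rr_ci_low, s.rr_ci_high = relative_risk(t, alpha)
    s.chi_square, s.p_value = chi_square(t)
    return s


# ---------------------------------------------------------------------------
# Feasibility audit
# ---------------------------------------------------------------------------


@dataclass
class CompletenessReport:
    n_total: int
    n_completed: int
    n_partial: int
    n_empty: int
    required_fields: List[str]

    @property
    def frac_completed(self) -> float:
        return self.n_completed / self.n_total

    @property
    def frac_partial(self) -> float:
        return self.n_partial / self.n_total

    @property
    def frac_empty(self) -> float:
        return self.n_empty / self.n_total


def completeness_audit(records, required_fields: Sequence[str]) -> CompletenessReport:
    """Audit bedside-form documentation over a cohort.

    ``records`` is a pandas DataFrame (one row per record); a required field
    counts as present when it is neither NA nor an empty string.  A form is
    completed when all required fields are present, empty when none are, and
    partially completed otherwise.
    """
    import pandas as pd

    if len(records) == 0:
        raise ValidationError("empty cohort")
    required_fields = list(required_fields)
    if not required_fields:
        raise ValidationError("empty required-field list")
    missing_cols = [f for f in required_fields if f not in records.columns]
    if missing_cols:
        raise ValidationError(f"required fields not in cohort: {missing_cols}")
    sub = records[required_fields]
    present = sub.notna() & (sub.astype(str) != "")
    n_present = present.sum(axis=1)
    k = len(required_fields)
    n_completed = int((n_present == k).sum())
    n_empty = int((n_present == 0).sum())
    n_partial = len(records) - n_completed - n_empty
    return CompletenessReport(
        n_total=len(records),
        n_completed=n_completed,
        n_partial=n_partial,
        n_empty=n_empty,
        required_fields=required_fields,
    )


# ---------------------------------------------------------------------------
# Likert summaries
# ---------------------------------------------------------------------------


@dataclass
class LikertTable:
    """Ordered response counts for one question, least to most favourable."""

    question: str
    labels: List[str]
    counts: List[int]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValidationError("labels and counts must align")
        if len(self.labels) < 2:
            raise ValidationError("need at least 2 Likert categories")
        if any(c < 0 for c in self.counts):
            raise ValidationError("negative Likert count")


def likert_summary(q: LikertTable, top_k: int = 2) -> float:
    """Fraction of responses in the ``top_k`` most favourable categories."""
    if not 0 < top_k < len(q.counts):
        raise ValidationError(f"top_k={top_k} out of range")
    total = sum(q.counts)
    if total == 0:
        raise ValidationError("no responses")
    return sum(q.counts[-top_k:]) / total


#: Staff-experience questions from the implementation survey, with their
#: observed response counts (least to most favourable).
DEFAULT_LIKERT_QUESTIONS = {
    "ease_of_use": LikertTable(
        "How was using the RI and MEOWS tool within the existing patient file?",
        ["very_difficult", "difficult", "easy", "very_easy"],
        [0, 2, 16, 7],
    ),
    "willingness": LikertTable(
        "To what extent are you willing to use the tool regularly?",
        ["very_resistant", "resistant", "willing", "very_willing"],
        [0, 2, 9, 11],
    ),
    "awareness": LikertTable(
        "Has the tool improved awareness of patient safety?",
        ["not_at_all", "somewhat_significant", "significant", "very_significant"],
        [0, 2, 9, 12],
    ),
    "delay_reduction": LikertTable(
        "Has the tool decreased delay in recognition and management?",
        ["not_at_all", "somewhat_significant", "significant", "very_significant"],
        [0, 3, 4, 15],
    ),
}


def composite_morbidity(pph, infection, preeclampsia) -> Optional[bool]:
    """Composite outcome: any of PPH, infection, pre-eclampsia.

    Returns None when every component is missing (outcome unascertained).
    """
    components = [pph, infection, preeclampsia]
    if all(c is None for c in components):
        return None
    return any(bool(c) for c in components if c is not None)
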