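"""Record-level pipeline: cohort rows -> MEOWS scores -> RI levels ->
triage decisions -> diagnostic evaluation.

Preeclampsia and sepsis share the admission vitals (SBP, DBP, heart rate,
respiratory rate, temperature, urine output) with the MEOWS observation;
their condition-specific columns supply the remaining findings.  A record
whose vitals and checklist inputs are all missing is unclassifiable and is
excluded listwise from the evaluation with a logged count, as is a record
whose morbidity outcome is unascertained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import pandas as pd

from . import io as cohort_io
from .evaluation import (
    CompletenessReport,
    ContingencyTable,
    DiagnosticSummary,
    completeness_audit,
    composite_morbidity,
    contingency,
    summarize,
)
from .meows import (
    DEFAULT_BANDS,
    NOT_MEASURED,
    MEOWSResult,
    ScoreBandTable,
    UnscorableError,
    VitalSignsObservation,
    compute_meows,
)
from .risk import (
    HemorrhageChecklist,
    PreeclampsiaFindings,
    RIResult,
    SepsisFindings,
    classify_record,
)
from .triage import TriageDecision, combined_level

logger = logging.getLogger("meows_ri")

__all__ = [
    "observation_from_row",
    "ri_inputs_from_row",
    "score_cohort",
    "triage_cohort",
    "evaluate_cohort",
    "EvaluationReport",
    "run_pipeline",
]


def observation_from_row(row) -> Optional[VitalSignsObservation]:
    """Admission vitals from a cohort row; None when every component is absent."""
    kwargs = {p: row[p] for p in cohort_io.VITAL_COLUMNS}
    if all(v is None for v in kwargs.values()):
        return None
    return VitalSignsObservation(**kwargs)


def _strip_prefix(row, prefix: str, names) -> dict:
    return {n[len(prefix):]: row[n] for n in names}


def ri_inputs_from_row(row):
    """Build the three RI findings objects from a cohort row.

    Returns ``None`` when the record carries no RI input at all (no
    checklist flag, no condition-specific finding, no shared vital).
    """
    hem = _strip_prefix(row, "hem_", cohort_io.HEM_COLUMNS)
    pe = _strip_prefix(row, "pe_", cohort_io.PE_COLUMNS)
    sep = _strip_prefix(row, "sep_", cohort_io.SEP_COLUMNS)
    vitals = {p: row[p] for p in cohort_io.VITAL_COLUMNS}
    if (
        all(v is None for v in hem.values())
        and all(v is None for v in pe.values())
        and all(v is None for v in sep.values())
        and all(v is None for v in vitals.values())
    ):
        return None

    checklist = HemorrhageChecklist(**{k: bool(v) for k, v in hem.items() if v is not None})

    urine = row["urine_output"]
    if urine == NOT_MEASURED:
        urine = None
    pe_kwargs = {k: v for k, v in pe.items() if v is not None}
    for flag in ("chest_pain", "nausea_vomiting", "abdominal_pain"):
        if flag in pe_kwargs:
            pe_kwargs[flag] = bool(pe_kwargs[flag])
    pe_findings = PreeclampsiaFindings(
        systolic_bp=row["systolic_bp"],
        diastolic_bp=row["diastolic_bp"],
        heart_rate=row["pulse"],
        respiratory_rate=row["respiratory_rate"],
        urine_output=urine,
        **pe_kwargs,
    )

    sep_kwargs = {
        k.replace("urine_output_ml_kg_h", "urine_output"): v
        for k, v in sep.items()
        if v is not None
    }
    for flag in ("diabetes_or_comorbidity", "invasive_procedure_6wk", "prolonged_rom",
                 "bleeding_or_offensive_discharge", "needs_fio2_over_40"):
        if flag in sep_kwargs:
            sep_kwargs[flag] = bool(sep_kwargs[flag])
    sep_findings = SepsisFindings(
        respiratory_rate=row["respiratory_rate"],
        systolic_bp=row["systolic_bp"],
        heart_rate=row["pulse"],
        temperature=row["temperature"],
        **sep_kwargs,
    )
    return checklist, pe_findings, sep_findings


def _score_row(row, bands: ScoreBandTable):
    obs = observation_from_row(row)
    if obs is None:
        return None
    try:
        return compute_meows(obs, bands)
    except UnscorableError:
        return None


def score_cohort(df: pd.DataFrame, bands: ScoreBandTable = DEFAULT_BANDS) -> pd.DataFrame:
    """Per-record MEOWS results (total, trigger, component scores)."""
    rows = []
    for _, row in df.iterrows():
        res = _score_row(row, bands)
        out = {"record_id": row["record_id"]}
        if res is None:
            out.update(meows_total=None, trigger_category=None,
                       n_missing_components=None, pulse_rule_applied=None)
        else:
            out.update(
                meows_total=res.total,
                trigger_category=res.trigger_category.value,
                n_missing_components=res.n_missing_components,
                pulse_rule_applied=res.pulse_rule_applied,
            )
            for param, score in res.component_scores.items():
                out[f"score_{param}"] = score
        rows.append(out)
    return pd.DataFrame(rows)


def triage_cohort(
    df: pd.DataFrame,
    bands: ScoreBandTable = DEFAULT_BANDS,
    rule: str = "disjunction",
) -> pd.DataFrame:
    """Per-record triage decisions; unclassifiable records flagged, not dropped."""
    rows = []
    for _, row in df.iterrows():
        meows = _score_row(row, bands)
        ri_inputs = ri_inputs_from_row(row)
        ri: Optional[RIResult] = None
        if ri_inputs is not None:
            ri = classify_record(*ri_inputs)
        out = {"record_id": row["record_id"]}
        if ri is None and meows is None:
            out.update(combined_level="unclassifiable", basis="",
                       meows_total=None, ri_overall=None,
                       triggered_criteria="")
        else:
            decision = combined_level(ri, meows, rule=rule)
            out.update(
                combined_level=decision.combined_level,
                basis=";".join(decision.basis),
                meows_total=decision.meows_total,
                ri_overall=None if ri is None else ri.overall.name.lower(),
                triggered_criteria="" if ri is None else ";".join(ri.triggered_criteria),
            )
        rows.append(out)
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    table: ContingencyTable
    summary: DiagnosticSummary
    completeness: CompletenessReport
    n_records: int
    n_analyzable: int
    n_excluded_no_predictor: int
    n_excluded_no_outcome: int
    prevalence: Optional[float]          # over records with an ascertained outcome
    combination_rule: str = "disjunction"


def evaluate_cohort(
    df: pd.DataFrame,
    bands: ScoreBandTable = DEFAULT_BANDS,
    rule: str = "disjunction",
    required_fields=None,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Full evaluation: completeness audit + 2x2 diagnostics on analyzable records."""
    if required_fields is None:
        required_fields = cohort_io.FORM_MARKER_COLUMNS
    completeness = completeness_audit(df, required_fields)

    decisions: List[TriageDecision] = []
    outcomes: List[bool] = []
    n_no_predictor = 0
    n_no_outcome = 0
    n_outcome_known = 0
    n_morbid = 0
    for _, row in df.iterrows():
        outcome = composite_morbidity(
            row["morbidity_pph"], row["morbidity_infection"], row["morbidity_preeclampsia"]
        )
        if outcome is not None:
            n_outcome_known += 1
            n_morbid += int(outcome)
        meows = _score_row(row, bands)
        ri_inputs = ri_inputs_from_row(row)
        if meows is None and ri_inputs is None:
            n_no_predictor += 1
            continue
        if outcome is None:
            n_no_outcome += 1
            continue
        ri = None if ri_inputs is None else classify_record(*ri_inputs)
        decisions.append(combined_level(ri, meows, rule=rule))
        outcomes.append(outcome)
    if n_no_predictor or n_no_outcome:
        logger.info(
            "excluded %d records without predictor and %d without outcome "
            "(%d analyzable of %d)",
            n_no_predictor, n_no_outcome, len(decisions), len(df),
        )
    table = contingency(decisions, outcomes)
    return EvaluationReport(
        table=table,
        summary=summarize(table, alpha=alpha),
        completeness=completeness,
        n_records=len(df),
        n_analyzable=len(decisions),
        n_excluded_no_predictor=n_no_predictor,
        n_excluded_no_outcome=n_no_outcome,
        prevalence=None if n_outcome_known == 0 else n_morbid / n_outcome_known,
        combination_rule=rule,
    )


def run_pipeline(
    cohort_path,
    out_dir,
    bands_path=None,
    rule: str = "disjunction",
) -> EvaluationReport:
    """score -> triage -> evaluate over a cohort file, writing report files.

    Writes ``scores.csv``, ``decisions.csv`` and ``evaluation.txt`` under
    ``out_dir`` and returns the :class:`EvaluationReport`.
    """
    import os

    bands = DEFAULT_BANDS if bands_path is None else ScoreBandTable.from_yaml(bands_path)
    df = cohort_io.read_cohort(cohort_path)
    os.makedirs(out_dir, exist_ok=True)
    score_cohort(df, bands).to_csv(os.path.join(out_dir, "scores.csv"), index=False)
    triage_cohort(df, bands, rule).to_csv(os.path.join(out_dir, "decisions.csv"), index=False)
    report = evaluate_cohort(df, bands, rule)
    with open(os.path.join(out_dir, "evaluation.txt"), "w") as fh:
        fh.write(format_report(report))
    return report


def format_report(r: EvaluationReport) -> str:
    """Human-readable evaluation summary."""
    from .evaluation import percent

    s = r.summary
    t = r.table
    c = r.completeness
    lines = [
        f"records: {r.n_records}  analyzable: {r.n_analyzable}  "
        f"excluded (no predictor): {r.n_excluded_no_predictor}  "
        f"(no outcome): {r.n_excluded_no_outcome}",
        f"combination rule: {r.combination_rule}",
        "",
        "form completeness:",
        f"  completed {c.n_completed} ({percent(c.frac_completed)}%)  "
        f"partial {c.n_partial} ({percent(c.frac_partial)}%)  "
        f"empty {c.n_empty} ({percent(c.frac_empty)}%)",
        "",
        "contingency (rows: moderate/high, low; cols: morbid, not morbid):",
        f"  {t.tp:5d} {t.fp:5d}",
        f"  {t.fn:5d} {t.tn:5d}",
        "",
        f"morbidity prevalence: {percent(r.prevalence)}%",
        f"sensitivity: {percent(s.sensitivity)}%",
        f"specificity: {percent(s.specificity)}%",
        f"PPV: {percent(s.ppv)}%",
        f"NPV: {percent(s.npv)}%",
        f"accuracy: {percent(s.accuracy)}%",
        f"relative risk: {s.relative_risk:.1f} "
        f"(95% CI {s.rr_ci_low:.1f}-{s.rr_ci_high:.1f})"
        if s.relative_risk is not None else "relative risk: undefined",
        f"chi-square: {s.chi_square:.1f} (p = {s.p_value:.2g})"
        if s.chi_square is not None else "chi-square: undefined",
    ]
    return "\n".join(lines) + "\n"
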