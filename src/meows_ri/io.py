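"""Cohort file I/O: the delimited-text dialect shared by all subcommands.

One row per parturient encounter, comma-delimited UTF-8 with a header row;
lines starting with ``#`` carry provenance (package version, seed, config)
and are ignored on read.  The missing-value token is the empty string.
In memory a cohort is a pandas DataFrame of parsed Python values
(floats / bools / enum strings) with ``None`` marking missing fields.

Column dictionary (dialect version "rw-cohort-v1"):

* identifiers / demographics: ``record_id``, ``district``, ``age``,
  ``gravida``, ``parity`` (cosmetic; never used by the classifiers)
* admission vitals (the seven MEOWS inputs): ``temperature`` (C),
  ``systolic_bp``/``diastolic_bp`` (mmHg), ``pulse`` (/min),
  ``respiratory_rate`` (/min), ``avpu``, ``urine_output`` (mL/h or
  ``not_measured``)
* hemorrhage checklist: ``hem_*`` booleans
* preeclampsia findings: ``pe_*`` (CVS values are taken from the shared
  admission vitals; lab and symptom fields live here)
* sepsis findings: ``sep_*`` (RR/SBP/HR/temperature likewise shared)
* bedside-form documentation markers for the feasibility audit:
  ``form_vitals``, ``form_hemorrhage``, ``form_preeclampsia``,
  ``form_sepsis`` (present = documented)
* morbidity outcome components: ``morbidity_pph``,
  ``morbidity_infection``, ``morbidity_preeclampsia`` booleans
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

from .meows import AVPU, NOT_MEASURED, ValidationError

__all__ = [
    "DIALECT_VERSION",
    "MISSING",
    "COLUMNS",
    "FORM_MARKER_COLUMNS",
    "read_cohort",
    "write_cohort",
]

DIALECT_VERSION = "rw-cohort-v1"
MISSING = ""

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


@dataclass(frozen=True)
class ColumnSpec:
    kind: str                    # str | float | bool | enum | urine | marker
    allowed: Optional[frozenset] = None


def _enum(*values: str) -> ColumnSpec:
    return ColumnSpec("enum", frozenset(values))


HEM_COLUMNS = [
    "hem_placenta_previa_or_low_lying",
    "hem_suspected_accreta_percreta",
    "hem_hct_below_30_with_refusal_and_other_risk",
    "hem_platelets_below_100k",
    "hem_active_bleeding",
    "hem_known_coagulopathy",
    "hem_prior_cesarean_or_uterine_surgery",
    "hem_multiple_gestation",
    "hem_over_4_vaginal_births",
    "hem_chorioamnionitis",
    "hem_prior_pph_history",
    "hem_large_fibroids",
    "hem_prolonged_second_stage",
    "hem_prolonged_oxytocin",
    "hem_magnesium_sulfate_treatment",
]

VITAL_COLUMNS = [
    "temperature",
    "systolic_bp",
    "diastolic_bp",
    "pulse",
    "respiratory_rate",
    "avpu",
    "urine_output",
]

FORM_MARKER_COLUMNS = [
    "form_vitals",
    "form_hemorrhage",
    "form_preeclampsia",
    "form_sepsis",
]

OUTCOME_COLUMNS = ["morbidity_pph", "morbidity_infection", "morbidity_preeclampsia"]

PE_COLUMNS = [
    "pe_awareness", "pe_headache", "pe_vision", "pe_chest_pain",
    "pe_nausea_vomiting", "pe_abdominal_pain", "pe_proteinuria",
    "pe_platelets", "pe_transaminases", "pe_creatinine",
    "pe_mgso4_respiration", "pe_patellar_reflex",
]

SEP_COLUMNS = [
    "sep_diabetes_or_comorbidity", "sep_invasive_procedure_6wk",
    "sep_prolonged_rom", "sep_bleeding_or_offensive_discharge",
    "sep_altered_mental_state", "sep_needs_fio2_over_40",
    "sep_hours_without_urine", "sep_urine_output_ml_kg_h", "sep_skin",
]

COLUMNS: Dict[str, ColumnSpec] = {
    "record_id": ColumnSpec("str"),
    "district": ColumnSpec("str"),
    "age": ColumnSpec("float"),
    "gravida": ColumnSpec("float"),
    "parity": ColumnSpec("float"),
    "temperature": ColumnSpec("float"),
    "systolic_bp": ColumnSpec("float"),
    "diastolic_bp": ColumnSpec("float"),
    "pulse": ColumnSpec("float"),
    "respiratory_rate": ColumnSpec("float"),
    "avpu": _enum(*(a.value for a in AVPU)),
    "urine_output": ColumnSpec("urine"),
    **{c: ColumnSpec("bool") for c in HEM_COLUMNS},
    "pe_awareness": _enum("alert", "agitated_confused", "drowsy",
                          "difficulty_speaking", "unresponsive"),
    "pe_headache": _enum("none", "mild", "unrelieved"),
    "pe_vision": _enum("none", "blurred_impaired", "temporary_blindness"),
    "pe_chest_pain": ColumnSpec("bool"),
    "pe_nausea_vomiting": ColumnSpec("bool"),
    "pe_abdominal_pain": ColumnSpec("bool"),
    "pe_proteinuria": _enum("none", "trace", "plus1_or_300mg24h"),
    "pe_platelets": ColumnSpec("float"),
    "pe_transaminases": ColumnSpec("float"),
    "pe_creatinine": ColumnSpec("float"),
    "pe_mgso4_respiration": ColumnSpec("float"),
    "pe_patellar_reflex": _enum("normal", "depressed"),
    "sep_diabetes_or_comorbidity": ColumnSpec("bool"),
    "sep_invasive_procedure_6wk": ColumnSpec("bool"),
    "sep_prolonged_rom": ColumnSpec("bool"),
    "sep_bleeding_or_offensive_discharge": ColumnSpec("bool"),
    "sep_altered_mental_state": _enum("none", "history_only", "current_exam"),
    "sep_needs_fio2_over_40": ColumnSpec("bool"),
    "sep_hours_without_urine": ColumnSpec("float"),
    "sep_urine_output_ml_kg_h": ColumnSpec("float"),
    "sep_skin": _enum("normal", "wound_infection_signs", "mottled_cyanosis_rash"),
    **{c: ColumnSpec("marker") for c in FORM_MARKER_COLUMNS},
    **{c: ColumnSpec("bool") for c in OUTCOME_COLUMNS},
}


def _parse_cell(raw: str, spec: ColumnSpec, row: int, col: str):
    if raw == MISSING:
        return None
    if spec.kind == "str":
        return raw
    if spec.kind == "marker":
        if raw.lower() in _TRUE:
            return True
        raise ValidationError(
            f"row {row}, column {col!r}: marker value {raw!r} (use '1' or leave empty)"
        )
    if spec.kind == "bool":
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValidationError(f"row {row}, column {col!r}: not a boolean: {raw!r}")
    if spec.kind == "float":
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(
                f"row {row}, column {col!r}: not numeric: {raw!r}"
            ) from None
    if spec.kind == "enum":
        if raw not in spec.allowed:
            raise ValidationError(
                f"row {row}, column {col!r}: {raw!r} not in {sorted(spec.allowed)}"
            )
        return raw
    if spec.kind == "urine":
        if raw == NOT_MEASURED:
            return NOT_MEASURED
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(
                f"row {row}, column {col!r}: expected mL/h or 'not_measured': {raw!r}"
            ) from None
    raise AssertionError(spec.kind)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort file; ``None`` marks missing fields.

    Raises :class:`ValidationError` naming the row and column for any
    unknown column, out-of-vocabulary categorical value or unparseable
    number; an empty file is an error.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty cohort: {path}") from None
    if raw.empty:
        raise ValidationError(f"empty cohort: {path}")
    unknown = [c for c in raw.columns if c not in COLUMNS]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")
    absent = [c for c in COLUMNS if c not in raw.columns]
    if absent:
        raise ValidationError(f"missing columns: {absent}")
    data = {}
    for col in COLUMNS:
        spec = COLUMNS[col]
        data[col] = [
            _parse_cell(v, spec, i + 1, col)
            for i, v in enumerate(raw[col].tolist())
        ]
    return objectify(pd.DataFrame(data, columns=list(COLUMNS)))


def objectify(df: pd.DataFrame) -> pd.DataFrame:
    """Force object dtype with ``None`` (not NaN) as the missing marker."""
    df = df.astype(object)
    return df.where(df.notna(), None)


def _format_cell(value) -> str:
    if value is None or value is pd.NA or (isinstance(value, float) and pd.isna(value)):
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.10g}"
    return str(value)


def write_cohort(df: pd.DataFrame, path, header_comments=None) -> None:
    """Write a cohort DataFrame in the shared dialect (lossless round trip)."""
    lines = []
    for comment in header_comments or []:
        lines.append(f"# {comment}")
    cols = [c for c in COLUMNS if c in df.columns]
    lines.append(",".join(cols))
    for _, row in df.iterrows():
        lines.append(",".join(_format_cell(row[c]) for c in cols))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
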