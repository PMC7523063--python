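"""Synthetic parturient-cohort generation.

The study's raw hospital data is not deposited, so this module generates
cohorts with the statistical structure the analysis assumes.  Generation is
class-first (inverse construction): each record's latent morbidity is drawn
at the configured prevalence, its intended triage class is drawn at the
configured operating point (positive with probability ``target_sensitivity``
given morbid, ``1 - target_specificity`` given not), and only then are
vitals and checklist findings sampled uniformly within bands that guarantee
the intended class — positive records receive either a moderate/high RI
criterion or vitals totalling MEOWS >= 3, negative records receive all-low
criteria and vitals totalling <= 2.  Running the actual scorer and
classifiers on a generated record therefore reproduces its intended class
exactly, which is asserted by the round-trip tests.

Demographics (age, gravida, parity, district) are cosmetic covariates drawn
from truncated normals / categorical frequencies matching the study cohort;
the classifiers never read them.  Bedside-form status (completed / partial /
empty) is assigned per configured fractions; field masking within partial
forms touches only the form-documentation markers and cosmetic covariates,
never the classification inputs or the latent outcome.

:func:`study_replica_fixture` builds the deterministic 478-record cohort
whose form statuses are exactly 363/79/36 and whose 399 analyzable records
reproduce the published 2x2 table (13, 23, 32, 331) when triaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as cohort_io
from .meows import ValidationError

__all__ = ["CohortConfig", "generate_cohort", "study_replica_fixture"]

_DISTRICTS = ("kibagabaga", "muhima", "kabutare", "nyanza")
_DISTRICT_P = np.array([0.282, 0.285, 0.291, 0.136])
_DISTRICT_P = _DISTRICT_P / _DISTRICT_P.sum()

_DRIVERS = ("hemorrhage", "preeclampsia", "sepsis", "vitals")


@dataclass
class CohortConfig:
    """Simulator parameters.

    Defaults reproduce the study conditions: n = 478 encounters, morbidity
    prevalence 49/478 (10.3%), instrument operating point 28.9% sensitivity
    / 93.5% specificity, and form-completeness fractions 363/79/36 of 478.
    """

    n: int
    seed: int
    prevalence: float = 49 / 478
    target_sensitivity: float = 0.289
    target_specificity: float = 0.935
    completeness_probs: tuple = (363 / 478, 79 / 478, 36 / 478)
    missing_field_rate_within_partial: float = 0.5
    positive_driver_weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("prevalence", "target_sensitivity", "target_specificity",
                     "missing_field_rate_within_partial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        probs = tuple(self.completeness_probs)
        if len(probs) != 3 or any(p < 0 for p in probs):
            raise ValidationError("completeness_probs must be 3 non-negative values")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("completeness_probs must sum to 1")
        if self.positive_driver_weights is not None:
            bad = set(self.positive_driver_weights) - set(_DRIVERS)
            if bad:
                raise ValidationError(f"unknown positive drivers: {sorted(bad)}")
            if sum(self.positive_driver_weights.values()) <= 0:
                raise ValidationError("positive_driver_weights must have positive mass")

    def driver_probs(self) -> np.ndarray:
        if self.positive_driver_weights is None:
            return np.full(len(_DRIVERS), 1 / len(_DRIVERS))
        w = np.array([self.positive_driver_weights.get(d, 0.0) for d in _DRIVERS])
        return w / w.sum()


# ---------------------------------------------------------------------------
# Record construction
# ---------------------------------------------------------------------------


def _baseline(rng: np.random.Generator) -> dict:
    """A fully low-risk record: MEOWS total <= 1 and every RI condition low.

    The baseline ranges deliberately avoid every moderate/high threshold of
    the shared vitals (sepsis SBP <= 100 and HR >= 100, preeclampsia urine
    output < 50 mL/h, hypothermia < 36 C), so the only permitted deviation
    is a single score-1 MEOWS component with no RI counterpart.
    """
    rec = {c: None for c in cohort_io.COLUMNS}
    rec.update(
        temperature=round(float(rng.uniform(36.0, 37.4)), 1),
        systolic_bp=float(rng.integers(101, 140)),
        diastolic_bp=float(rng.integers(46, 90)),
        pulse=float(rng.integers(51, 100)),
        respiratory_rate=float(rng.integers(15, 21)),
        avpu="alert",
        urine_output=float(rng.integers(50, 121)),
    )
    for c in cohort_io.HEM_COLUMNS:
        rec[c] = False
    rec.update(
        pe_awareness="alert",
        pe_headache="none",
        pe_vision="none",
        pe_chest_pain=False,
        pe_nausea_vomiting=False,
        pe_abdominal_pain=False,
        pe_proteinuria="trace" if rng.random() < 0.10 else "none",
        pe_platelets=float(rng.integers(150, 351)),
        pe_transaminases=float(rng.integers(10, 61)),
        pe_creatinine=round(float(rng.uniform(0.40, 0.70)), 2),
        pe_patellar_reflex="normal",
        sep_diabetes_or_comorbidity=bool(rng.random() < 0.08),
        sep_invasive_procedure_6wk=bool(rng.random() < 0.15),
        sep_prolonged_rom=bool(rng.random() < 0.10),
        sep_bleeding_or_offensive_discharge=bool(rng.random() < 0.05),
        sep_altered_mental_state="none",
        sep_needs_fio2_over_40=False,
        sep_skin="normal",
    )
    # occasional benign score-1 deviation (keeps MEOWS total <= 1)
    if rng.random() < 0.4:
        if rng.random() < 0.5:
            rec["temperature"] = round(float(rng.uniform(37.5, 39.0)), 1)
        else:
            rec["respiratory_rate"] = float(rng.integers(11, 15))
    return rec


_HEM_FLAGS = cohort_io.HEM_COLUMNS[:12]  # admission checklist (high + moderate tiers)


def _make_positive(rec: dict, driver: str, rng: np.random.Generator) -> None:
    """Mutate a baseline record so the triage decision is moderate-or-high."""
    if driver == "hemorrhage":
        rec[_HEM_FLAGS[int(rng.integers(len(_HEM_FLAGS)))]] = True
    elif driver == "preeclampsia":
        option = int(rng.integers(6))
        if option == 0:
            rec["pe_proteinuria"] = "plus1_or_300mg24h"
        elif option == 1:
            rec["pe_platelets"] = float(rng.integers(20, 96))
        elif option == 2:
            rec["pe_headache"] = "mild"
        elif option == 3:
            rec["pe_vision"] = "blurred_impaired"
        elif option == 4:
            rec["pe_creatinine"] = round(float(rng.uniform(0.9, 1.5)), 2)
        else:
            rec["pe_transaminases"] = float(rng.integers(80, 201))
    elif driver == "sepsis":
        option = int(rng.integers(5))
        if option == 0:
            rec["sep_skin"] = "wound_infection_signs"
        elif option == 1:
            rec["sep_altered_mental_state"] = "history_only"
        elif option == 2:
            rec["sep_hours_without_urine"] = float(rng.integers(13, 25))
        elif option == 3:
            rec["sep_urine_output_ml_kg_h"] = round(float(rng.uniform(0.2, 0.9)), 2)
        else:
            rec["temperature"] = round(float(rng.uniform(39.1, 40.5)), 1)
    elif driver == "vitals":
        option = int(rng.integers(6))
        if option == 0:
            rec["systolic_bp"] = float(rng.integers(160, 201))
        elif option == 1:
            rec["diastolic_bp"] = float(rng.integers(110, 136))
        elif option == 2:
            rec["respiratory_rate"] = float(rng.integers(31, 46))
        elif option == 3:
            rec["pulse"] = float(rng.integers(131, 161))
        elif option == 4:
            rec["urine_output"] = float(rng.integers(0, 10))
        else:  # two score-2 components
            rec["diastolic_bp"] = float(rng.integers(100, 110))
            rec["pulse"] = float(rng.integers(111, 126))
    else:  # pragma: no cover
        raise ValidationError(f"unknown driver {driver!r}")


def _demographics(rec: dict, rng: np.random.Generator) -> None:
    rec["district"] = _DISTRICTS[int(rng.choice(len(_DISTRICTS), p=_DISTRICT_P))]
    rec["age"] = round(float(np.clip(rng.normal(28.30, 6.38), 15, 49)), 1)
    rec["gravida"] = float(int(np.clip(round(rng.normal(2.58, 1.91)), 1, 12)))
    rec["parity"] = float(int(np.clip(round(rng.normal(1.43, 1.67)), 0,
                                      rec["gravida"])))


def _outcome(rec: dict, morbid: bool, rng: np.random.Generator) -> None:
    rec["morbidity_pph"] = False
    rec["morbidity_infection"] = False
    rec["morbidity_preeclampsia"] = False
    if morbid:
        component = ("morbidity_pph", "morbidity_infection", "morbidity_preeclampsia")[
            int(rng.integers(3))
        ]
        rec[component] = True


_COSMETIC = ("age", "gravida", "parity")


def _form_status(rec: dict, status: str, rng: np.random.Generator,
                 mask_rate: float) -> None:
    markers = cohort_io.FORM_MARKER_COLUMNS
    if status == "completed":
        for m in markers:
            rec[m] = True
    elif status == "empty":
        for m in markers:
            rec[m] = None
    else:  # partial: 1-3 of the 4 sections documented
        k = 1 + int(rng.integers(3))
        present = rng.permutation(len(markers))[:k]
        for i, m in enumerate(markers):
            rec[m] = True if i in present else None
        for c in _COSMETIC:
            if rng.random() < mask_rate:
                rec[c] = None


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a synthetic cohort, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    driver_p = config.driver_probs()
    statuses = np.array(["completed", "partial", "empty"])
    rows = []
    intended_positive = []
    latent_morbid = []
    for i in range(config.n):
        morbid = bool(rng.random() < config.prevalence)
        p_pos = config.target_sensitivity if morbid else 1 - config.target_specificity
        positive = bool(rng.random() < p_pos)
        rec = _baseline(rng)
        rec["record_id"] = f"S{i + 1:05d}"
        _demographics(rec, rng)
        if positive:
            driver = _DRIVERS[int(rng.choice(len(_DRIVERS), p=driver_p))]
            _make_positive(rec, driver, rng)
        _outcome(rec, morbid, rng)
        status = statuses[int(rng.choice(3, p=np.array(config.completeness_probs)))]
        _form_status(rec, status, rng, config.missing_field_rate_within_partial)
        rows.append(rec)
        intended_positive.append(positive)
        latent_morbid.append(morbid)
    df = cohort_io.objectify(pd.DataFrame(rows, columns=list(cohort_io.COLUMNS)))
    # in-memory provenance for round-trip checks (not serialized to file)
    df.attrs["intended_positive"] = intended_positive
    df.attrs["latent_morbid"] = latent_morbid
    df.attrs["config"] = config
    return df


# ---------------------------------------------------------------------------
# Study-replica fixture
# ---------------------------------------------------------------------------


def _excluded_record(rng: np.random.Generator, morbid: bool) -> dict:
    """A record with no usable predictor data (vitals and checklists missing)."""
    rec = {c: None for c in cohort_io.COLUMNS}
    _demographics(rec, rng)
    _outcome(rec, morbid, rng)
    return rec


def study_replica_fixture() -> pd.DataFrame:
    """Deterministic 478-record cohort replicating the published margins.

    Form statuses are exactly 363 completed / 79 partial / 36 empty; the 399
    records with predictor data reproduce the 2x2 table (13, 23, 32, 331)
    when triaged, and 49 of 478 records (10.3%) carry the composite
    morbidity outcome.  Analyzable records are the 363 completed forms plus
    36 partially-completed forms whose admission data were still abstracted;
    the remaining 43 partial and all 36 empty forms lack predictor data and
    are excluded listwise by the evaluation.
    """
    rng = np.random.default_rng(20190401)
    rows = []

    def analyzable(positive: bool, morbid: bool, status: str) -> dict:
        rec = _baseline(rng)
        _demographics(rec, rng)
        if positive:
            driver = _DRIVERS[int(rng.integers(len(_DRIVERS)))]
            _make_positive(rec, driver, rng)
        _outcome(rec, morbid, rng)
        _form_status(rec, status, rng, mask_rate=0.5)
        return rec

    # published cross-tabulation: 36 moderate/high (13 morbid), 363 low (32 morbid)
    for _ in range(13):
        rows.append(analyzable(True, True, "partial"))
    for _ in range(23):
        rows.append(analyzable(True, False, "partial"))
    for _ in range(32):
        rows.append(analyzable(False, True, "completed"))
    for _ in range(331):
        rows.append(analyzable(False, False, "completed"))
    # 79 excluded: 43 further partial forms and 36 empty forms; 4 of the 49
    # morbid records fall here so morbidity totals 49/478
    for i in range(43):
        rec = _excluded_record(rng, morbid=i < 2)
        _form_status(rec, "partial", rng, mask_rate=0.5)
        rows.append(rec)
    for i in range(36):
        rec = _excluded_record(rng, morbid=i < 2)
        _form_status(rec, "empty", rng, mask_rate=0.5)
        rows.append(rec)

    order = np.random.default_rng(478).permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order], columns=list(cohort_io.COLUMNS))
    df["record_id"] = [f"R{i + 1:04d}" for i in range(len(df))]
    return cohort_io.objectify(df)
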