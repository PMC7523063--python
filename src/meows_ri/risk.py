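"""Risk Identification (RI): rule-based hemorrhage / preeclampsia-eclampsia /
sepsis risk stratification for parturients at admission.

Each condition has a catalogue of criteria, each assigned to the high or
moderate tier; a record is classified by the max-rule — any satisfied
high-tier criterion makes the condition high risk, otherwise any satisfied
moderate-tier criterion makes it moderate, otherwise low.  The overall RI
level is the maximum across the three conditions.  Each tier carries a
static list of recommended response actions.

The catalogue is declarative configuration: every criterion is a
(field, comparison, threshold) predicate with a stable identifier and the
human-readable chart text, so alternative threshold maps can be loaded
without code changes.  Printed charts are not always tidy; where thresholds
leave numeric gaps between tiers, the gap is resolved to the more severe
tier, and criteria printed under two tiers are assigned the higher one
(both choices are clinically conservative and deterministic).

Sepsis screening risk factors (diabetes/comorbidity, recent invasive
procedure, prolonged rupture of membranes, bleeding or offensive discharge)
prompt assessment but never change the tier on their own; only the
diagnosis criteria carry tier logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from enum import IntEnum
from typing import List, Optional, Tuple

import yaml

from .meows import ConfigurationError, ValidationError

__all__ = [
    "RiskLevel",
    "Criterion",
    "CRITERIA_CATALOGUE",
    "HemorrhageChecklist",
    "PreeclampsiaFindings",
    "SepsisFindings",
    "RIResult",
    "classify_hemorrhage",
    "classify_preeclampsia",
    "classify_sepsis",
    "classify_record",
    "overall_ri",
    "recommended_response",
    "criteria_catalogue_to_yaml",
]


class RiskLevel(IntEnum):
    """Ordered risk tier: low < moderate < high."""

    LOW = 0
    MODERATE = 1
    HIGH = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


# ---------------------------------------------------------------------------
# Findings containers
# ---------------------------------------------------------------------------


@dataclass
class HemorrhageChecklist:
    """Admission hemorrhage risk-factor checklist (absent fields default false).

    The hematocrit criterion ("hematocrit < 30, refusal of transfusion, AND
    other risk factors") is conjunctive on the chart and is supplied as a
    single pre-evaluated flag.
    """

    # high tier
    placenta_previa_or_low_lying: bool = False
    suspected_accreta_percreta: bool = False
    hct_below_30_with_refusal_and_other_risk: bool = False
    platelets_below_100k: bool = False
    active_bleeding: bool = False
    known_coagulopathy: bool = False
    # moderate tier
    prior_cesarean_or_uterine_surgery: bool = False
    multiple_gestation: bool = False
    over_4_vaginal_births: bool = False
    chorioamnionitis: bool = False
    prior_pph_history: bool = False
    large_fibroids: bool = False
    # labor/postpartum re-evaluation triggers (moderate tier when flagged)
    prolonged_second_stage: bool = False
    prolonged_oxytocin: bool = False
    magnesium_sulfate_treatment: bool = False


@dataclass
class PreeclampsiaFindings:
    """Preeclampsia/eclampsia findings.

    Numeric fields are ``None`` when missing; a missing field never
    satisfies a criterion.  ``urine_output`` is in mL/h; a 2-hour collected
    volume should be halved before entry (:meth:`from_two_hour_volume`).
    """

    awareness: str = "alert"        # alert | agitated_confused | drowsy | difficulty_speaking | unresponsive
    headache: str = "none"          # none | mild | unrelieved
    vision: str = "none"            # none | blurred_impaired | temporary_blindness
    systolic_bp: Optional[float] = None       # mmHg
    diastolic_bp: Optional[float] = None      # mmHg
    heart_rate: Optional[float] = None        # beats/min
    chest_pain: bool = False
    respiratory_rate: Optional[float] = None  # breaths/min
    nausea_vomiting: bool = False
    abdominal_pain: bool = False
    urine_output: Optional[float] = None      # mL/h
    proteinuria: str = "none"       # none | trace | plus1_or_300mg24h
    platelets: Optional[float] = None         # x10^3 / uL
    transaminases: Optional[float] = None     # ASAT/ALAT, U/L
    creatinine: Optional[float] = None        # mg/dL
    mgso4_respiration: Optional[float] = None  # breaths/min while on MgSO4
    patellar_reflex: str = "normal"  # normal | depressed

    _AWARENESS = {"alert", "agitated_confused", "drowsy", "difficulty_speaking", "unresponsive"}
    _HEADACHE = {"none", "mild", "unrelieved"}
    _VISION = {"none", "blurred_impaired", "temporary_blindness"}
    _PROTEINURIA = {"none", "trace", "plus1_or_300mg24h"}
    _REFLEX = {"normal", "depressed"}

    def __post_init__(self) -> None:
        _check_enum("awareness", self.awareness, self._AWARENESS)
        _check_enum("headache", self.headache, self._HEADACHE)
        _check_enum("vision", self.vision, self._VISION)
        _check_enum("proteinuria", self.proteinuria, self._PROTEINURIA)
        _check_enum("patellar_reflex", self.patellar_reflex, self._REFLEX)
        _check_nonneg(self, ("systolic_bp", "diastolic_bp", "heart_rate",
                             "respiratory_rate", "urine_output", "platelets",
                             "transaminases", "creatinine", "mgso4_respiration"))

    @classmethod
    def from_two_hour_volume(cls, volume_ml: float, **kwargs) -> "PreeclampsiaFindings":
        """Build findings from a 2-hour urine collection, normalized to mL/h."""
        return cls(urine_output=volume_ml / 2.0, **kwargs)


@dataclass
class SepsisFindings:
    """Sepsis screening flags and diagnosis findings."""

    # screening risk factors: recorded, never tier-changing on their own
    diabetes_or_comorbidity: bool = False
    invasive_procedure_6wk: bool = False
    prolonged_rom: bool = False
    bleeding_or_offensive_discharge: bool = False
    # diagnosis criteria
    altered_mental_state: str = "none"   # current_exam | history_only | none
    respiratory_rate: Optional[float] = None   # breaths/min
    needs_fio2_over_40: bool = False
    systolic_bp: Optional[float] = None        # mmHg
    heart_rate: Optional[float] = None         # beats/min
    hours_without_urine: Optional[float] = None
    urine_output: Optional[float] = None       # mL/kg/h via catheter
    temperature: Optional[float] = None        # degrees C
    skin: str = "normal"  # mottled_cyanosis_rash | wound_infection_signs | normal

    _AMS = {"none", "history_only", "current_exam"}
    _SKIN = {"normal", "wound_infection_signs", "mottled_cyanosis_rash"}

    def __post_init__(self) -> None:
        _check_enum("altered_mental_state", self.altered_mental_state, self._AMS)
        _check_enum("skin", self.skin, self._SKIN)
        _check_nonneg(self, ("respiratory_rate", "systolic_bp", "heart_rate",
                             "hours_without_urine", "urine_output", "temperature"))


def _check_enum(name: str, value: str, allowed: set) -> None:
    if value not in allowed:
        raise ValidationError(f"{name}={value!r} not in {sorted(allowed)}")


def _check_nonneg(obj, names: Tuple[str, ...]) -> None:
    for name in names:
        v = getattr(obj, name)
        if v is not None and float(v) < 0:
            raise ValidationError(f"{name}={v} must be non-negative")


# ---------------------------------------------------------------------------
# Criteria catalogue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Criterion:
    """One chart criterion: a predicate on a single findings field.

    ``op`` is one of ``is_true``, ``eq``, ``lt``, ``le``, ``gt``, ``ge``,
    ``between`` (closed interval, ``value=(lo, hi)``).  ``tier`` is the
    risk tier the criterion confers; ``screening`` criteria are recorded
    but never change the tier.
    """

    id: str
    condition: str       # hemorrhage | preeclampsia | sepsis
    tier: Optional[RiskLevel]  # None -> screening flag
    field: str
    op: str
    value: object
    text: str

    def satisfied(self, findings) -> bool:
        v = getattr(findings, self.field)
        if v is None:
            return False
        if self.op == "is_true":
            return bool(v)
        if self.op == "eq":
            return v == self.value
        if self.op == "lt":
            return float(v) < self.value
        if self.op == "le":
            return float(v) <= self.value
        if self.op == "gt":
            return float(v) > self.value
        if self.op == "ge":
            return float(v) >= self.value
        if self.op == "between":
            lo, hi = self.value
            return lo <= float(v) <= hi
        raise ConfigurationError(f"unknown predicate op {self.op!r}")


def _c(id, condition, tier, field, op, value, text) -> Criterion:
    return Criterion(id, condition, tier, field, op, value, text)


H, M = RiskLevel.HIGH, RiskLevel.MODERATE

CRITERIA_CATALOGUE: List[Criterion] = [
    # ---- hemorrhage: admission checklist ---------------------------------
    _c("hem_previa", "hemorrhage", H, "placenta_previa_or_low_lying", "is_true", True,
       "Placenta previa or low-lying placenta"),
    _c("hem_accreta", "hemorrhage", H, "suspected_accreta_percreta", "is_true", True,
       "Suspected placenta accreta or percreta"),
    _c("hem_hct_refusal", "hemorrhage", H, "hct_below_30_with_refusal_and_other_risk", "is_true", True,
       "Hematocrit < 30 with refusal of transfusion and other risk factors"),
    _c("hem_platelets", "hemorrhage", H, "platelets_below_100k", "is_true", True,
       "Platelets < 100,000"),
    _c("hem_active_bleeding", "hemorrhage", H, "active_bleeding", "is_true", True,
       "Active bleeding (greater than show)"),
    _c("hem_coagulopathy", "hemorrhage", H, "known_coagulopathy", "is_true", True,
       "Known coagulopathy"),
    _c("hem_prior_cesarean", "hemorrhage", M, "prior_cesarean_or_uterine_surgery", "is_true", True,
       "Prior cesarean birth(s) or uterine surgery"),
    _c("hem_multiple_gestation", "hemorrhage", M, "multiple_gestation", "is_true", True,
       "Multiple gestation"),
    _c("hem_grand_multipara", "hemorrhage", M, "over_4_vaginal_births", "is_true", True,
       "More than 4 previous vaginal births"),
    _c("hem_chorioamnionitis", "hemorrhage", M, "chorioamnionitis", "is_true", True,
       "Chorioamnionitis"),
    _c("hem_prior_pph", "hemorrhage", M, "prior_pph_history", "is_true", True,
       "History of previous postpartum hemorrhage"),
    _c("hem_fibroids", "hemorrhage", M, "large_fibroids", "is_true", True,
       "Large uterine fibroids"),
    # labor/postpartum re-evaluation triggers -> moderate when flagged
    _c("hem_prolonged_second_stage", "hemorrhage", M, "prolonged_second_stage", "is_true", True,
       "Prolonged second stage of labor"),
    _c("hem_prolonged_oxytocin", "hemorrhage", M, "prolonged_oxytocin", "is_true", True,
       "Prolonged oxytocin use"),
    _c("hem_mgso4", "hemorrhage", M, "magnesium_sulfate_treatment", "is_true", True,
       "Magnesium sulfate treatment"),
    # ---- preeclampsia / eclampsia ----------------------------------------
    _c("pe_unresponsive", "preeclampsia", H, "awareness", "eq", "unresponsive",
       "Awareness: unresponsive"),
    _c("pe_awareness_agitated", "preeclampsia", M, "awareness", "eq", "agitated_confused",
       "Awareness: agitated or confused"),
    _c("pe_awareness_drowsy", "preeclampsia", M, "awareness", "eq", "drowsy",
       "Awareness: drowsy"),
    _c("pe_awareness_speech", "preeclampsia", M, "awareness", "eq", "difficulty_speaking",
       "Awareness: difficulty speaking"),
    _c("pe_headache_unrelieved", "preeclampsia", H, "headache", "eq", "unrelieved",
       "Unrelieved headache"),
    _c("pe_headache_mild", "preeclampsia", M, "headache", "eq", "mild",
       "Mild headache"),
    _c("pe_vision_blindness", "preeclampsia", H, "vision", "eq", "temporary_blindness",
       "Temporary blindness"),
    _c("pe_vision_blurred", "preeclampsia", M, "vision", "eq", "blurred_impaired",
       "Blurred or impaired vision"),
    _c("pe_sbp_high", "preeclampsia", H, "systolic_bp", "ge", 160,
       "Systolic BP >= 160 mmHg"),
    _c("pe_sbp_mod", "preeclampsia", M, "systolic_bp", "between", (140, 159),
       "Systolic BP 140-159 mmHg"),
    _c("pe_dbp_high", "preeclampsia", H, "diastolic_bp", "ge", 110,
       "Diastolic BP >= 110 mmHg"),
    _c("pe_dbp_mod", "preeclampsia", M, "diastolic_bp", "between", (90, 109),
       "Diastolic BP 90-109 mmHg"),
    _c("pe_hr_high", "preeclampsia", H, "heart_rate", "ge", 130,
       "Heart rate > 130 /min"),
    _c("pe_hr_mod", "preeclampsia", M, "heart_rate", "between", (111, 129),
       "Heart rate 111-129 /min"),
    _c("pe_chest_pain", "preeclampsia", H, "chest_pain", "is_true", True,
       "Chest pain"),
    _c("pe_rr_low", "preeclampsia", H, "respiratory_rate", "lt", 10,
       "Respiratory rate < 10 /min"),
    _c("pe_rr_high", "preeclampsia", H, "respiratory_rate", "gt", 30,
       "Respiratory rate > 30 /min"),
    _c("pe_rr_mod", "preeclampsia", M, "respiratory_rate", "between", (25, 30),
       "Respiratory rate 25-30 /min"),
    _c("pe_nausea", "preeclampsia", H, "nausea_vomiting", "is_true", True,
       "Nausea and vomiting"),
    _c("pe_abdominal_pain", "preeclampsia", H, "abdominal_pain", "is_true", True,
       "Abdominal pain"),
    _c("pe_oliguria_high", "preeclampsia", H, "urine_output", "lt", 30,
       "Urine output <= 30 mL in 2 h (< 30 mL/h after gap closure)"),
    _c("pe_oliguria_mod", "preeclampsia", M, "urine_output", "between", (30, 49),
       "Urine output 30-49 mL/h"),
    _c("pe_proteinuria", "preeclampsia", M, "proteinuria", "eq", "plus1_or_300mg24h",
       "Proteinuria > +1 or 300 mg / 24 h"),
    _c("pe_platelets_high", "preeclampsia", H, "platelets", "lt", 50,
       "Platelets < 50 x10^3/uL"),
    _c("pe_platelets_mod", "preeclampsia", M, "platelets", "between", (50, 100),
       "Platelets 50-100 x10^3/uL"),
    _c("pe_transaminases", "preeclampsia", H, "transaminases", "gt", 70,
       "ASAT/ALAT > 70 U/L"),
    _c("pe_creatinine_high", "preeclampsia", H, "creatinine", "gt", 1.1,
       "Creatinine > 1.2 mg/dL (> 1.1 after gap closure)"),
    _c("pe_creatinine_mod", "preeclampsia", M, "creatinine", "between", (0.8, 1.1),
       "Creatinine 0.9-1.1 mg/dL (0.8-1.1 after gap closure)"),
    _c("pe_mgso4_resp", "preeclampsia", H, "mgso4_respiration", "lt", 12,
       "MgSO4 toxicity: respiration < 12 /min"),
    _c("pe_mgso4_reflex", "preeclampsia", M, "patellar_reflex", "eq", "depressed",
       "MgSO4 toxicity: depressed patellar reflexes"),
    # ---- sepsis: screening flags (recorded, never tier-changing) ---------
    _c("sep_screen_diabetes", "sepsis", None, "diabetes_or_comorbidity", "is_true", True,
       "Gestational diabetes, diabetes or other comorbidity"),
    _c("sep_screen_invasive", "sepsis", None, "invasive_procedure_6wk", "is_true", True,
       "Invasive procedure within 6 weeks"),
    _c("sep_screen_prom", "sepsis", None, "prolonged_rom", "is_true", True,
       "Prolonged rupture of membranes"),
    _c("sep_screen_discharge", "sepsis", None, "bleeding_or_offensive_discharge", "is_true", True,
       "Continued vaginal bleeding or offensive vaginal discharge"),
    # ---- sepsis: diagnosis criteria --------------------------------------
    _c("sep_ams_current", "sepsis", H, "altered_mental_state", "eq", "current_exam",
       "New altered mental state on examination"),
    _c("sep_ams_history", "sepsis", M, "altered_mental_state", "eq", "history_only",
       "History of new altered mental state"),
    _c("sep_rr_high", "sepsis", H, "respiratory_rate", "ge", 25,
       "Respiratory rate > 25 /min (>= 25 after gap closure)"),
    _c("sep_rr_mod", "sepsis", M, "respiratory_rate", "between", (21, 24),
       "Respiratory rate 21-24 /min"),
    _c("sep_fio2", "sepsis", H, "needs_fio2_over_40", "is_true", True,
       "Needs FiO2 > 40% to keep saturation > 92%"),
    _c("sep_sbp_high", "sepsis", H, "systolic_bp", "le", 90,
       "Systolic BP < 90 mmHg (<= 90 after gap closure)"),
    _c("sep_sbp_mod", "sepsis", M, "systolic_bp", "between", (91, 100),
       "Systolic BP 91-100 mmHg"),
    _c("sep_hr_high", "sepsis", H, "heart_rate", "ge", 130,
       "Heart rate > 130 /min (>= 130, duplicate boundary to higher tier)"),
    _c("sep_hr_mod", "sepsis", M, "heart_rate", "between", (100, 129),
       "Heart rate 100-130 /min"),
    _c("sep_anuria_high", "sepsis", H, "hours_without_urine", "ge", 18,
       "No urine for 18 h"),
    _c("sep_anuria_mod", "sepsis", M, "hours_without_urine", "between", (12, 18),
       "No urine for 12-18 h"),
    _c("sep_oliguria_high", "sepsis", H, "urine_output", "lt", 0.5,
       "Catheter urine output < 0.5 mL/kg/h"),
    _c("sep_oliguria_mod", "sepsis", M, "urine_output", "le", 1.0,
       "Catheter urine output 0.5-1 mL/kg/h"),
    _c("sep_fever", "sepsis", H, "temperature", "gt", 39,
       "Temperature > 39 C"),
    _c("sep_hypothermia", "sepsis", M, "temperature", "lt", 36,
       "Temperature < 36 C"),
    _c("sep_skin_high", "sepsis", H, "skin", "eq", "mottled_cyanosis_rash",
       "Mottled appearance, cyanosis, or non-blanching rash"),
    _c("sep_skin_mod", "sepsis", M, "skin", "eq", "wound_infection_signs",
       "Signs of potential wound/surgical-site infection"),
]

_BY_CONDITION = {
    cond: [c for c in CRITERIA_CATALOGUE if c.condition == cond]
    for cond in ("hemorrhage", "preeclampsia", "sepsis")
}
_BY_ID = {c.id: c for c in CRITERIA_CATALOGUE}


def criteria_catalogue_to_yaml(path) -> None:
    """Export the criteria catalogue (ids, tiers, predicates, chart text)."""
    entries = [
        {
            "id": c.id,
            "condition": c.condition,
            "tier": c.tier.name.lower() if c.tier is not None else "screening",
            "field": c.field,
            "op": c.op,
            "value": list(c.value) if isinstance(c.value, tuple) else c.value,
            "text": c.text,
        }
        for c in CRITERIA_CATALOGUE
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"version": "rw-ri-v1", "criteria": entries}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _classify(condition: str, findings) -> Tuple[RiskLevel, List[str], List[str]]:
    level = RiskLevel.LOW
    triggered: List[str] = []
    screening: List[str] = []
    for crit in _BY_CONDITION[condition]:
        if not crit.satisfied(findings):
            continue
        if crit.tier is None:
            screening.append(crit.id)
        else:
            triggered.append(crit.id)
            level = max(level, crit.tier)
    return level, triggered, screening


def classify_hemorrhage(checklist: HemorrhageChecklist) -> Tuple[RiskLevel, List[str]]:
    """Hemorrhage tier by the max-rule over the admission checklist."""
    level, triggered, _ = _classify("hemorrhage", checklist)
    return level, triggered


def classify_preeclampsia(findings: PreeclampsiaFindings) -> Tuple[RiskLevel, List[str]]:
    """Preeclampsia/eclampsia tier by the max-rule over CNS/CVS/RS/renal/lab criteria."""
    level, triggered, _ = _classify("preeclampsia", findings)
    return level, triggered


def classify_sepsis(findings: SepsisFindings) -> Tuple[RiskLevel, List[str]]:
    """Sepsis tier by the max-rule over diagnosis criteria (screening flags recorded only)."""
    level, triggered, _ = _classify("sepsis", findings)
    return level, triggered


def overall_ri(h: RiskLevel, p: RiskLevel, s: RiskLevel) -> RiskLevel:
    """Overall RI level: the maximum of the three condition levels."""
    return max(RiskLevel(h), RiskLevel(p), RiskLevel(s))


@dataclass
class RIResult:
    hemorrhage: RiskLevel
    preeclampsia: RiskLevel
    sepsis: RiskLevel
    overall: RiskLevel
    triggered_criteria: List[str] = field(default_factory=list)
    screening_flags: List[str] = field(default_factory=list)
    responses: List[str] = field(default_factory=list)


def classify_record(
    hemorrhage: HemorrhageChecklist,
    preeclampsia: PreeclampsiaFindings,
    sepsis: SepsisFindings,
) -> RIResult:
    """Classify all three conditions and bundle levels, criteria and responses."""
    hl, ht = classify_hemorrhage(hemorrhage)
    pl, pt = classify_preeclampsia(preeclampsia)
    sl, st, = classify_sepsis(sepsis)
    _, _, screening = _classify("sepsis", sepsis)
    responses = []
    for cond, lvl in (("hemorrhage", hl), ("preeclampsia", pl), ("sepsis", sl)):
        responses.extend(a.id for a in recommended_response(cond, lvl))
    return RIResult(
        hemorrhage=hl,
        preeclampsia=pl,
        sepsis=sl,
        overall=overall_ri(hl, pl, sl),
        triggered_criteria=ht + pt + st,
        screening_flags=screening,
        responses=responses,
    )


# ---------------------------------------------------------------------------
# Recommended responses (static chart transcription)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseAction:
    id: str
    text: str


_R = ResponseAction

RESPONSES = {
    ("hemorrhage", RiskLevel.HIGH): [
        _R("consider_referral_if_not_in_labor", "Consider referral if not in labor"),
        _R("close_monitoring", "If in labor: close monitoring"),
        _R("type_and_screen", "Type and screen"),
        _R("order_2_units_blood", "Order 2 units of blood"),
        _R("delivery", "Delivery"),
    ],
    ("hemorrhage", RiskLevel.MODERATE): [
        _R("consider_referral_if_not_in_labor", "Consider referral if not in labor (clinical judgment)"),
        _R("close_monitoring", "If in labor: close monitoring"),
        _R("type_and_screen", "Type and screen"),
        _R("book_2_units_blood", "Book 2 units of blood"),
        _R("delivery", "Delivery"),
    ],
    ("hemorrhage", RiskLevel.LOW): [
        _R("standard_of_care", "Standard of care"),
    ],
    ("preeclampsia", RiskLevel.HIGH): [
        _R("immediate_evaluation_abcde", "Immediate evaluation (ABCDE approach)"),
        _R("transfer_higher_acuity", "Transfer to higher acuity level"),
        _R("one_to_one_staffing", "1:1 staff ratio"),
        _R("labetalol_hydralazine_30min", "Labetalol/hydralazine within 30 min"),
        _R("in_person_evaluation", "In-person evaluation"),
        _R("mgso4_loading_or_maintenance", "Magnesium sulfate loading or maintenance infusion"),
        _R("o2_10l_rebreather", "O2 at 10 L per rebreather mask"),
        _R("rule_out_pulmonary_edema", "Rule out pulmonary edema"),
        _R("chest_xray", "Chest x-ray"),
        _R("safe_referral_tertiary", "Safe referral to tertiary center"),
    ],
    ("preeclampsia", RiskLevel.MODERATE): [
        _R("notify_in_charge", "Notify in-charge RN or midwife"),
        _R("in_person_evaluation", "In-person evaluation"),
        _R("order_labs_tests", "Order labs/tests"),
        _R("anesthesia_consult", "Anesthesia consult"),
        _R("consider_mgso4", "Consider magnesium sulfate"),
        _R("supplemental_oxygen", "Supplemental oxygen"),
        _R("notify_physician_proteinuria", "Physician made aware of worsening or new-onset proteinuria"),
    ],
    ("preeclampsia", RiskLevel.LOW): [
        _R("normal_pregnancy_protocol", "Proceed with protocol for normal pregnancy"),
    ],
    ("sepsis", RiskLevel.HIGH): [
        _R("immediate_senior_review_abcde", "Immediate review by senior clinical decision maker (ABCDE approach)"),
        _R("sepsis_blood_tests", "Blood tests: gas (glucose/lactate), culture, FBC, CRP, urea/electrolytes, creatinine, clotting"),
        _R("iv_antibiotics_within_1h", "IV antibiotics within 1 h"),
        _R("fluid_bolus_500ml", "500 mL bolus every 15 min, repeat up to 3 times; adrenaline if SBP < 90 to keep MAP > 65"),
        _R("refer_tertiary", "Refer to a tertiary hospital"),
    ],
    ("sepsis", RiskLevel.MODERATE): [
        _R("sepsis_blood_tests", "Blood tests: gas (glucose/lactate), culture, FBC, CRP, urea/electrolytes, creatinine, clotting"),
        _R("senior_review_within_1h", "Review by senior clinical decision maker within 1 h"),
        _R("iv_antibiotics_within_1h", "IV antibiotics within 1 h"),
        _R("fluid_bolus_500ml", "500 mL bolus every 15 min, repeat up to 3 times"),
        _R("source_control_6h", "Source control within 6 h; if deep infection, refer to a tertiary hospital"),
        _R("hourly_reassessment", "If no definitive condition identified, repeat structured assessment hourly"),
    ],
    ("sepsis", RiskLevel.LOW): [
        _R("clinical_judgement", "Clinical assessment; manage according to clinical judgement"),
        _R("meows_monitoring", "Continue MEOWS monitoring"),
    ],
}


def recommended_response(condition: str, level: RiskLevel) -> List[ResponseAction]:
    """Static response-action list for a condition at a tier."""
    key = (condition, RiskLevel(level))
    if key not in RESPONSES:
        raise ConfigurationError(f"unknown condition {condition!r}")
    return list(RESPONSES[key])
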