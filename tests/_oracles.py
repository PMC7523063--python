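"""Independent brute-force oracles used by the test suite.

These are literal if/else transcriptions of the scoring charts, kept
deliberately free of the package's band-table machinery so that agreement
between the two is a meaningful check.
"""

import math

AVPU_SCORES = {"alert": 0, "voice": 1, "pain": 2, "unconscious": 3}


def _round_half_up(x, step):
    return math.floor(x / step + 0.5) * step


def oracle_score(param, value):
    """Chart lookup ladder for one MEOWS component."""
    if param == "avpu":
        return AVPU_SCORES[value]
    if param == "urine_output" and value == "not_measured":
        return 0
    if param == "temperature":
        v = _round_half_up(float(value), 0.1)
        if v < 34.95:
            return 2
        if v <= 37.45:
            return 0
        if v <= 39.05:
            return 1
        return 2
    v = int(_round_half_up(float(value), 1))
    if param == "systolic_bp":
        if v <= 70:
            return 3
        if v <= 80:
            return 2
        if v <= 89:
            return 1
        if v <= 139:
            return 0
        if v <= 149:
            return 1
        if v <= 159:
            return 2
        return 3
    if param == "diastolic_bp":
        if v <= 45:
            return 2
        if v <= 89:
            return 0
        if v <= 99:
            return 1
        if v <= 109:
            return 2
        return 3
    if param == "pulse":
        if v <= 40:
            return 2
        if v <= 50:
            return 1
        if v <= 100:
            return 0
        if v <= 110:
            return 1
        if v <= 129:
            return 2
        return 3
    if param == "respiratory_rate":
        if v <= 8:
            return 3
        if v <= 14:
            return 1
        if v <= 20:
            return 0
        if v <= 29:
            return 2
        return 3
    if param == "urine_output":
        if v <= 9:
            return 3
        if v <= 29:
            return 2
        return 0
    raise ValueError(param)


def oracle_meows_total(obs_dict):
    """Sum of present component scores with the pulse-vs-SBP floor."""
    total = 0
    scores = {}
    for param, value in obs_dict.items():
        if value is None:
            continue
        scores[param] = oracle_score(param, value)
    if obs_dict.get("pulse") is not None and obs_dict.get("systolic_bp") is not None:
        if obs_dict["pulse"] > obs_dict["systolic_bp"]:
            scores["pulse"] = max(scores["pulse"], 2)
    return sum(scores.values())


def oracle_trigger(total):
    if total <= 2:
        return "current_plan"
    if total <= 5:
        return "review"
    return "escalate"


# ---------------------------------------------------------------------------
# RI ladders (per-criterion tiers; condition level = max)
# ---------------------------------------------------------------------------

LOW, MODERATE, HIGH = 0, 1, 2

_HEM_HIGH = (
    "placenta_previa_or_low_lying", "suspected_accreta_percreta",
    "hct_below_30_with_refusal_and_other_risk", "platelets_below_100k",
    "active_bleeding", "known_coagulopathy",
)
_HEM_MODERATE = (
    "prior_cesarean_or_uterine_surgery", "multiple_gestation",
    "over_4_vaginal_births", "chorioamnionitis", "prior_pph_history",
    "large_fibroids", "prolonged_second_stage", "prolonged_oxytocin",
    "magnesium_sulfate_treatment",
)


def oracle_hemorrhage(checklist):
    level = LOW
    for name in _HEM_HIGH:
        if getattr(checklist, name):
            level = max(level, HIGH)
    for name in _HEM_MODERATE:
        if getattr(checklist, name):
            level = max(level, MODERATE)
    return level


def oracle_preeclampsia(f):
    tiers = [LOW]
    if f.awareness == "unresponsive":
        tiers.append(HIGH)
    elif f.awareness in ("agitated_confused", "drowsy", "difficulty_speaking"):
        tiers.append(MODERATE)
    if f.headache == "unrelieved":
        tiers.append(HIGH)
    elif f.headache == "mild":
        tiers.append(MODERATE)
    if f.vision == "temporary_blindness":
        tiers.append(HIGH)
    elif f.vision == "blurred_impaired":
        tiers.append(MODERATE)
    if f.systolic_bp is not None:
        if f.systolic_bp >= 160:
            tiers.append(HIGH)
        elif f.systolic_bp >= 140:
            tiers.append(MODERATE)
    if f.diastolic_bp is not None:
        if f.diastolic_bp >= 110:
            tiers.append(HIGH)
        elif f.diastolic_bp >= 90:
            tiers.append(MODERATE)
    if f.heart_rate is not None:
        if f.heart_rate >= 130:
            tiers.append(HIGH)
        elif f.heart_rate >= 111:
            tiers.append(MODERATE)
    if f.chest_pain:
        tiers.append(HIGH)
    if f.respiratory_rate is not None:
        if f.respiratory_rate < 10 or f.respiratory_rate > 30:
            tiers.append(HIGH)
        elif f.respiratory_rate >= 25:
            tiers.append(MODERATE)
    if f.nausea_vomiting:
        tiers.append(HIGH)
    if f.abdominal_pain:
        tiers.append(HIGH)
    if f.urine_output is not None:
        if f.urine_output < 30:
            tiers.append(HIGH)
        elif f.urine_output <= 49:
            tiers.append(MODERATE)
    if f.proteinuria == "plus1_or_300mg24h":
        tiers.append(MODERATE)
    if f.platelets is not None:
        if f.platelets < 50:
            tiers.append(HIGH)
        elif f.platelets <= 100:
            tiers.append(MODERATE)
    if f.transaminases is not None and f.transaminases > 70:
        tiers.append(HIGH)
    if f.creatinine is not None:
        if f.creatinine > 1.1:
            tiers.append(HIGH)
        elif f.creatinine >= 0.8:
            tiers.append(MODERATE)
    if f.mgso4_respiration is not None and f.mgso4_respiration < 12:
        tiers.append(HIGH)
    if f.patellar_reflex == "depressed":
        tiers.append(MODERATE)
    return max(tiers)


def oracle_sepsis(f):
    tiers = [LOW]
    if f.altered_mental_state == "current_exam":
        tiers.append(HIGH)
    elif f.altered_mental_state == "history_only":
        tiers.append(MODERATE)
    if f.respiratory_rate is not None:
        if f.respiratory_rate >= 25:
            tiers.append(HIGH)
        elif f.respiratory_rate >= 21:
            tiers.append(MODERATE)
    if f.needs_fio2_over_40:
        tiers.append(HIGH)
    if f.systolic_bp is not None:
        if f.systolic_bp <= 90:
            tiers.append(HIGH)
        elif f.systolic_bp <= 100:
            tiers.append(MODERATE)
    if f.heart_rate is not None:
        if f.heart_rate >= 130:
            tiers.append(HIGH)
        elif f.heart_rate >= 100:
            tiers.append(MODERATE)
    if f.hours_without_urine is not None:
        if f.hours_without_urine >= 18:
            tiers.append(HIGH)
        elif f.hours_without_urine >= 12:
            tiers.append(MODERATE)
    if f.urine_output is not None:
        if f.urine_output < 0.5:
            tiers.append(HIGH)
        elif f.urine_output <= 1.0:
            tiers.append(MODERATE)
    if f.temperature is not None:
        if f.temperature > 39:
            tiers.append(HIGH)
        elif f.temperature < 36:
            tiers.append(MODERATE)
    if f.skin == "mottled_cyanosis_rash":
        tiers.append(HIGH)
    elif f.skin == "wound_infection_signs":
        tiers.append(MODERATE)
    return max(tiers)
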