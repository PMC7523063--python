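"""Risk Identification classifiers: chart examples, the max-rule against an
independent per-criterion ladder (hypothesis), tier monotonicity, the
criteria catalogue, and recommended responses."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_hemorrhage, oracle_preeclampsia, oracle_sepsis
from meows_ri import (
    CRITERIA_CATALOGUE,
    HemorrhageChecklist,
    PreeclampsiaFindings,
    RiskLevel,
    SepsisFindings,
    classify_hemorrhage,
    classify_preeclampsia,
    classify_record,
    classify_sepsis,
    overall_ri,
    recommended_response,
)
from meows_ri.meows import ConfigurationError, ValidationError
from meows_ri.risk import criteria_catalogue_to_yaml

# ---------------------------------------------------------------------------
# chart examples
# ---------------------------------------------------------------------------


def test_hemorrhage_chart_examples():
    assert classify_hemorrhage(
        HemorrhageChecklist(placenta_previa_or_low_lying=True)
    )[0] is RiskLevel.HIGH
    assert classify_hemorrhage(
        HemorrhageChecklist(prior_cesarean_or_uterine_surgery=True)
    )[0] is RiskLevel.MODERATE
    level, triggered = classify_hemorrhage(HemorrhageChecklist())
    assert level is RiskLevel.LOW and triggered == []


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        ({"systolic_bp": 165}, RiskLevel.HIGH),
        ({"platelets": 40}, RiskLevel.HIGH),
        ({"proteinuria": "plus1_or_300mg24h"}, RiskLevel.MODERATE),
        ({}, RiskLevel.LOW),
        ({"diastolic_bp": 95}, RiskLevel.MODERATE),
        ({"diastolic_bp": 112}, RiskLevel.HIGH),
        ({"heart_rate": 120}, RiskLevel.MODERATE),
        ({"heart_rate": 130}, RiskLevel.HIGH),     # boundary to severe tier
        ({"respiratory_rate": 9}, RiskLevel.HIGH),
        ({"respiratory_rate": 27}, RiskLevel.MODERATE),
        ({"creatinine": 0.85}, RiskLevel.MODERATE),  # printed gap, severe side
        ({"creatinine": 1.15}, RiskLevel.HIGH),      # printed gap, severe side
        ({"urine_output": 10}, RiskLevel.HIGH),      # <= 30 mL in 2 h cell
        ({"urine_output": 40}, RiskLevel.MODERATE),
        ({"mgso4_respiration": 10}, RiskLevel.HIGH),
        ({"patellar_reflex": "depressed"}, RiskLevel.MODERATE),
        ({"awareness": "drowsy"}, RiskLevel.MODERATE),
        ({"awareness": "unresponsive"}, RiskLevel.HIGH),
    ],
)
def test_preeclampsia_chart_examples(kwargs, expected):
    assert classify_preeclampsia(PreeclampsiaFindings(**kwargs))[0] is expected


def test_preeclampsia_two_hour_urine_normalized():
    f = PreeclampsiaFindings.from_two_hour_volume(28.0)  # 14 mL/h
    assert f.urine_output == 14.0
    assert classify_preeclampsia(f)[0] is RiskLevel.HIGH


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        ({"temperature": 39.5}, RiskLevel.HIGH),
        ({"temperature": 35.5}, RiskLevel.MODERATE),
        ({"respiratory_rate": 23}, RiskLevel.MODERATE),
        ({"systolic_bp": 85}, RiskLevel.HIGH),
        ({"systolic_bp": 95}, RiskLevel.MODERATE),
        ({"heart_rate": 130}, RiskLevel.HIGH),     # duplicate boundary, severe tier
        ({"heart_rate": 110}, RiskLevel.MODERATE),
        ({"hours_without_urine": 19}, RiskLevel.HIGH),
        ({"hours_without_urine": 14}, RiskLevel.MODERATE),
        ({"urine_output": 0.3}, RiskLevel.HIGH),
        ({"urine_output": 0.8}, RiskLevel.MODERATE),
        ({"altered_mental_state": "current_exam"}, RiskLevel.HIGH),
        ({"altered_mental_state": "history_only"}, RiskLevel.MODERATE),
        ({"skin": "mottled_cyanosis_rash"}, RiskLevel.HIGH),
        ({"skin": "wound_infection_signs"}, RiskLevel.MODERATE),
        ({}, RiskLevel.LOW),
    ],
)
def test_sepsis_chart_examples(kwargs, expected):
    assert classify_sepsis(SepsisFindings(**kwargs))[0] is expected


def test_sepsis_screening_flags_never_raise_level():
    f = SepsisFindings(
        diabetes_or_comorbidity=True, invasive_procedure_6wk=True,
        prolonged_rom=True, bleeding_or_offensive_discharge=True,
    )
    level, triggered = classify_sepsis(f)
    assert level is RiskLevel.LOW and triggered == []
    result = classify_record(HemorrhageChecklist(), PreeclampsiaFindings(), f)
    assert result.overall is RiskLevel.LOW
    assert len(result.screening_flags) == 4


def test_findings_validation():
    with pytest.raises(ValidationError):
        PreeclampsiaFindings(awareness="sleepy")
    with pytest.raises(ValidationError):
        SepsisFindings(hours_without_urine=-1)


# ---------------------------------------------------------------------------
# max-rule equivalence with the independent ladder (property tests)
# ---------------------------------------------------------------------------

hem_strategy = st.builds(
    HemorrhageChecklist,
    **{f.name: st.booleans() for f in dataclasses.fields(HemorrhageChecklist)},
)


def _opt(strategy):
    return st.one_of(st.none(), strategy)


pe_strategy = st.builds(
    PreeclampsiaFindings,
    awareness=st.sampled_from(sorted(PreeclampsiaFindings._AWARENESS)),
    headache=st.sampled_from(sorted(PreeclampsiaFindings._HEADACHE)),
    vision=st.sampled_from(sorted(PreeclampsiaFindings._VISION)),
    systolic_bp=_opt(st.integers(60, 250).map(float)),
    diastolic_bp=_opt(st.integers(30, 160).map(float)),
    heart_rate=_opt(st.integers(40, 200).map(float)),
    chest_pain=st.booleans(),
    respiratory_rate=_opt(st.integers(4, 60).map(float)),
    nausea_vomiting=st.booleans(),
    abdominal_pain=st.booleans(),
    urine_output=_opt(st.integers(0, 150).map(float)),
    proteinuria=st.sampled_from(sorted(PreeclampsiaFindings._PROTEINURIA)),
    platelets=_opt(st.integers(5, 450).map(float)),
    transaminases=_opt(st.integers(5, 300).map(float)),
    creatinine=_opt(st.decimals(min_value="0.1", max_value="3.0", places=2).map(float)),
    mgso4_respiration=_opt(st.integers(4, 40).map(float)),
    patellar_reflex=st.sampled_from(sorted(PreeclampsiaFindings._REFLEX)),
)

sep_strategy = st.builds(
    SepsisFindings,
    diabetes_or_comorbidity=st.booleans(),
    invasive_procedure_6wk=st.booleans(),
    prolonged_rom=st.booleans(),
    bleeding_or_offensive_discharge=st.booleans(),
    altered_mental_state=st.sampled_from(sorted(SepsisFindings._AMS)),
    respiratory_rate=_opt(st.integers(4, 60).map(float)),
    needs_fio2_over_40=st.booleans(),
    systolic_bp=_opt(st.integers(50, 250).map(float)),
    heart_rate=_opt(st.integers(40, 200).map(float)),
    hours_without_urine=_opt(st.integers(0, 48).map(float)),
    urine_output=_opt(st.decimals(min_value="0.0", max_value="4.0", places=2).map(float)),
    temperature=_opt(st.decimals(min_value="33.0", max_value="42.0", places=1).map(float)),
    skin=st.sampled_from(sorted(SepsisFindings._SKIN)),
)


@settings(max_examples=400, derandomize=True)
@given(checklist=hem_strategy)
def test_hemorrhage_max_rule(checklist):
    level, triggered = classify_hemorrhage(checklist)
    assert int(level) == oracle_hemorrhage(checklist)
    assert (level > RiskLevel.LOW) == bool(triggered)


@settings(max_examples=400, derandomize=True)
@given(findings=pe_strategy)
def test_preeclampsia_max_rule(findings):
    level, triggered = classify_preeclampsia(findings)
    assert int(level) == oracle_preeclampsia(findings)
    assert (level > RiskLevel.LOW) == bool(triggered)


@settings(max_examples=400, derandomize=True)
@given(findings=sep_strategy)
def test_sepsis_max_rule(findings):
    level, triggered = classify_sepsis(findings)
    assert int(level) == oracle_sepsis(findings)
    assert (level > RiskLevel.LOW) == bool(triggered)


@settings(max_examples=200, derandomize=True)
@given(checklist=hem_strategy, data=st.data())
def test_adding_a_criterion_never_lowers_the_level(checklist, data):
    base, _ = classify_hemorrhage(checklist)
    name = data.draw(
        st.sampled_from([f.name for f in dataclasses.fields(HemorrhageChecklist)])
    )
    raised, _ = classify_hemorrhage(dataclasses.replace(checklist, **{name: True}))
    assert raised >= base


# ---------------------------------------------------------------------------
# overall level and responses
# ---------------------------------------------------------------------------


def test_overall_ri_is_max_and_commutative_associative_idempotent():
    levels = list(RiskLevel)
    for h in levels:
        for p in levels:
            for s in levels:
                out = overall_ri(h, p, s)
                assert out == max(h, p, s)
                assert out == overall_ri(s, p, h)
                assert overall_ri(out, out, out) == out


def test_recommended_responses_match_chart_cells():
    high_hem = [a.id for a in recommended_response("hemorrhage", RiskLevel.HIGH)]
    assert "order_2_units_blood" in high_hem
    mod_sep = [a.id for a in recommended_response("sepsis", RiskLevel.MODERATE)]
    assert "iv_antibiotics_within_1h" in mod_sep
    low_hem = [a.id for a in recommended_response("hemorrhage", RiskLevel.LOW)]
    assert low_hem == ["standard_of_care"]
    with pytest.raises(ConfigurationError):
        recommended_response("cardiomyopathy", RiskLevel.LOW)


def test_classify_record_bundles_levels_criteria_and_responses():
    result = classify_record(
        HemorrhageChecklist(multiple_gestation=True),
        PreeclampsiaFindings(systolic_bp=170),
        SepsisFindings(),
    )
    assert result.hemorrhage is RiskLevel.MODERATE
    assert result.preeclampsia is RiskLevel.HIGH
    assert result.sepsis is RiskLevel.LOW
    assert result.overall is RiskLevel.HIGH
    assert "hem_multiple_gestation" in result.triggered_criteria
    assert "pe_sbp_high" in result.triggered_criteria
    assert "labetalol_hydralazine_30min" in result.responses


# ---------------------------------------------------------------------------
# criteria catalogue integrity
# ---------------------------------------------------------------------------


def test_catalogue_ids_unique_and_fields_resolvable():
    ids = [c.id for c in CRITERIA_CATALOGUE]
    assert len(ids) == len(set(ids))
    containers = {
        "hemorrhage": HemorrhageChecklist(),
        "preeclampsia": PreeclampsiaFindings(),
        "sepsis": SepsisFindings(),
    }
    for c in CRITERIA_CATALOGUE:
        assert hasattr(containers[c.condition], c.field), c.id
        assert c.tier in (None, RiskLevel.MODERATE, RiskLevel.HIGH)
        assert c.text


def test_triggered_ids_round_trip_to_single_catalogue_entries():
    result = classify_record(
        HemorrhageChecklist(active_bleeding=True),
        PreeclampsiaFindings(platelets=75),
        SepsisFindings(temperature=39.6),
    )
    by_id = {c.id: c for c in CRITERIA_CATALOGUE}
    for cid in result.triggered_criteria:
        assert cid in by_id
    assert {by_id[c].condition for c in result.triggered_criteria} == {
        "hemorrhage", "preeclampsia", "sepsis"
    }


def test_catalogue_yaml_export(tmp_path):
    import yaml

    path = tmp_path / "criteria.yaml"
    criteria_catalogue_to_yaml(path)
    loaded = yaml.safe_load(path.read_text())
    assert len(loaded["criteria"]) == len(CRITERIA_CATALOGUE)
    entry = {c["id"]: c for c in loaded["criteria"]}["pe_sbp_high"]
    assert entry["tier"] == "high" and entry["op"] == "ge" and entry["value"] == 160
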