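"""Modified Early Obstetric Warning Score (MEOWS) band scoring.

MEOWS is a bedside track-and-trigger instrument for parturients: each of
seven physiologic parameters (temperature, systolic and diastolic blood
pressure, pulse, respiratory rate, AVPU consciousness level, urine output)
is scored 0-3 against a band table, the component scores are summed, and
the total maps to an escalation tier (continue current plan / repeat
observations with senior review / escalate and refer).

The default band table shipped here ("rw-meows-v1") is the Rwandan
district-hospital adaptation, fully enumerated so that every admissible
value falls in exactly one band.  Custom band tables can be loaded from
YAML; printed charts often leave gaps or overlaps between bands, so a
gap-resolution policy (default: score as the more severe adjacent band)
is applied for tables that do not tile the domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "AVPU",
    "TriggerCategory",
    "NOT_MEASURED",
    "Band",
    "ScoreBandTable",
    "VitalSignsObservation",
    "MEOWSResult",
    "ValidationError",
    "ConfigurationError",
    "UnscorableError",
    "default_band_table",
    "score_component",
    "apply_pulse_rule",
    "classify_trigger",
    "compute_meows",
    "MEOWS_PARAMETERS",
    "NUMERIC_PARAMETERS",
]


class ValidationError(ValueError):
    """A measurement or record violates its admissible domain."""


class ConfigurationError(ValueError):
    """A band table or criteria catalogue is malformed."""


class UnscorableError(ValueError):
    """No component of an observation is present, so no total exists."""


class AVPU(str, Enum):
    """Consciousness scale: Alert / responds to Voice / responds to Pain / Unconscious."""

    ALERT = "alert"
    VOICE = "voice"
    PAIN = "pain"
    UNCONSCIOUS = "unconscious"


class TriggerCategory(str, Enum):
    """Escalation tier implied by a MEOWS total."""

    CURRENT_PLAN = "current_plan"  # total <= 2: continue current plan
    REVIEW = "review"              # total 3-5: repeat observations, senior midwife review
    ESCALATE = "escalate"          # total >= 6: inform coordinator, medical/anesthesia review, referral


#: Marker for urine output recorded as "Not Measured" on the chart.
NOT_MEASURED = "not_measured"

NUMERIC_PARAMETERS = (
    "temperature",
    "systolic_bp",
    "diastolic_bp",
    "pulse",
    "respiratory_rate",
    "urine_output",
)
MEOWS_PARAMETERS = NUMERIC_PARAMETERS + ("avpu",)

#: Instrument precision per parameter; values are rounded to this grid before
#: band lookup so that printed closed-interval boundaries are unambiguous.
PRECISION = {
    "temperature": 0.1,
    "systolic_bp": 1.0,
    "diastolic_bp": 1.0,
    "pulse": 1.0,
    "respiratory_rate": 1.0,
    "urine_output": 1.0,
}

#: Admissible measurement domains (inclusive); outside -> ValidationError.
ADMISSIBLE = {
    "temperature": (25.0, 45.0),
    "systolic_bp": (0.0, 320.0),
    "diastolic_bp": (0.0, 250.0),
    "pulse": (0.0, 320.0),
    "respiratory_rate": (0.0, 120.0),
    "urine_output": (0.0, 5000.0),
}


def _snap(parameter: str, value: float) -> float:
    """Round ``value`` to the instrument precision of ``parameter`` (half-up)."""
    step = PRECISION[parameter]
    return math.floor(value / step + 0.5) * step


@dataclass(frozen=True)
class Band:
    """A closed scoring interval ``[lo, hi] -> score``; ``None`` bound = unbounded."""

    lo: Optional[float]
    hi: Optional[float]
    score: int

    def contains(self, value: float, tol: float = 1e-9) -> bool:
        if self.lo is not None and value < self.lo - tol:
            return False
        if self.hi is not None and value > self.hi + tol:
            return False
        return True


@dataclass
class ScoreBandTable:
    """Per-parameter ordered band lists plus categorical maps and gap policy.

    ``numeric`` maps each numeric parameter to bands ordered by interval;
    ``avpu_scores`` maps consciousness levels to scores; urine output
    recorded as "Not Measured" receives ``not_measured_score`` (0 by default,
    flagged as a data-quality issue rather than a physiologic finding).
    """

    numeric: Mapping[str, Sequence[Band]]
    avpu_scores: Mapping[AVPU, int]
    not_measured_score: int = 0
    gap_policy: str = "most_severe_adjacent"
    version: str = "rw-meows-v1"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for param in NUMERIC_PARAMETERS:
            if param not in self.numeric:
                raise ConfigurationError(f"band table missing parameter {param!r}")
        for param, bands in self.numeric.items():
            if param not in NUMERIC_PARAMETERS:
                raise ConfigurationError(f"unknown parameter {param!r} in band table")
            if not bands:
                raise ConfigurationError(f"no bands for parameter {param!r}")
            for b in bands:
                if b.score not in (0, 1, 2, 3):
                    raise ConfigurationError(
                        f"{param}: band score {b.score} outside 0-3"
                    )
                if b.lo is not None and b.hi is not None and b.lo > b.hi:
                    raise ConfigurationError(f"{param}: band lo > hi ({b.lo} > {b.hi})")
            ordered = sorted(
                bands, key=lambda b: -math.inf if b.lo is None else b.lo
            )
            for prev, nxt in zip(ordered, ordered[1:]):
                if prev.hi is None or nxt.lo is None or nxt.lo <= prev.hi:
                    raise ConfigurationError(
                        f"{param}: overlapping bands after normalization"
                    )
        if set(self.avpu_scores) != set(AVPU):
            raise ConfigurationError("avpu_scores must cover all four AVPU levels")
        if self.gap_policy != "most_severe_adjacent":
            raise ConfigurationError(f"unknown gap policy {self.gap_policy!r}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "gap_policy": self.gap_policy,
            "not_measured_score": self.not_measured_score,
            "avpu": {level.value: int(s) for level, s in self.avpu_scores.items()},
            "bands": {
                param: [
                    {"min": b.lo, "max": b.hi, "score": b.score} for b in bands
                ]
                for param, bands in self.numeric.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreBandTable":
        try:
            numeric = {
                param: tuple(
                    Band(e.get("min"), e.get("max"), int(e["score"]))
                    for e in entries
                )
                for param, entries in d["bands"].items()
            }
            avpu = {AVPU(k): int(v) for k, v in d["avpu"].items()}
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed band table: {exc}") from exc
        return cls(
            numeric=numeric,
            avpu_scores=avpu,
            not_measured_score=int(d.get("not_measured_score", 0)),
            gap_policy=d.get("gap_policy", "most_severe_adjacent"),
            version=d.get("version", "custom"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoreBandTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_band_table() -> ScoreBandTable:
    """The fully-enumerated Rwandan adaptation band table ("rw-meows-v1").

    Printed charts leave the odd gap (systolic 80) or overlap (pulse 40);
    this enumeration closes each one toward the more severe band, so no
    runtime gap resolution is needed for the default table.
    """
    return ScoreBandTable(
        numeric={
            "temperature": (
                Band(None, 34.9, 2),
                Band(35.0, 37.4, 0),
                Band(37.5, 39.0, 1),
                Band(39.1, None, 2),
            ),
            "systolic_bp": (
                Band(None, 70, 3),
                Band(71, 80, 2),
                Band(81, 89, 1),
                Band(90, 139, 0),
                Band(140, 149, 1),
                Band(150, 159, 2),
                Band(160, None, 3),
            ),
            "diastolic_bp": (
                Band(None, 45, 2),
                Band(46, 89, 0),
                Band(90, 99, 1),
                Band(100, 109, 2),
                Band(110, None, 3),
            ),
            "pulse": (
                Band(None, 40, 2),
                Band(41, 50, 1),
                Band(51, 100, 0),
                Band(101, 110, 1),
                Band(111, 129, 2),
                Band(130, None, 3),
            ),
            "respiratory_rate": (
                Band(None, 8, 3),
                Band(9, 14, 1),
                Band(15, 20, 0),
                Band(21, 29, 2),
                Band(30, None, 3),
            ),
            "urine_output": (
                Band(None, 9, 3),
                Band(10, 29, 2),
                Band(30, None, 0),
            ),
        },
        avpu_scores={
            AVPU.ALERT: 0,
            AVPU.VOICE: 1,
            AVPU.PAIN: 2,
            AVPU.UNCONSCIOUS: 3,
        },
    )


DEFAULT_BANDS = default_band_table()


@dataclass
class VitalSignsObservation:
    """One timestamped set of the seven MEOWS physiologic inputs.

    Every field is individually optional; ``None`` marks a missing
    measurement.  Urine output may also carry the :data:`NOT_MEASURED`
    marker when the chart explicitly records it as not measured.
    """

    timestamp: Optional[str] = None
    temperature: Optional[float] = None          # degrees C
    systolic_bp: Optional[float] = None          # mmHg
    diastolic_bp: Optional[float] = None         # mmHg
    pulse: Optional[float] = None                # beats/min
    respiratory_rate: Optional[float] = None     # breaths/min
    avpu: Optional[AVPU] = None
    urine_output: Union[float, str, None] = None  # mL/h or NOT_MEASURED

    def __post_init__(self) -> None:
        if self.avpu is not None:
            self.avpu = AVPU(self.avpu)
        for param in NUMERIC_PARAMETERS:
            value = getattr(self, param)
            if value is None:
                continue
            if param == "urine_output" and value == NOT_MEASURED:
                continue
            value = float(value)
            lo, hi = ADMISSIBLE[param]
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"{param}={value} outside admissible range [{lo}, {hi}]"
                )
            setattr(self, param, value)

    def present_components(self) -> list:
        return [p for p in MEOWS_PARAMETERS if getattr(self, p) is not None]


@dataclass
class MEOWSResult:
    component_scores: dict       # parameter -> 0-3 for present components
    total: int
    n_missing_components: int
    trigger_category: TriggerCategory
    pulse_rule_applied: bool
    urine_not_measured: bool = False


def score_component(
    parameter: str,
    value,
    bands: ScoreBandTable = DEFAULT_BANDS,
) -> int:
    """Score one measurement against the band table.

    Values in a printed gap are resolved by the table's gap policy (the more
    severe of the adjacent bands); overlaps cannot occur in a validated
    table.  Deterministic for a fixed table.
    """
    if parameter == "avpu":
        try:
            return bands.avpu_scores[AVPU(value)]
        except ValueError as exc:
            raise ValidationError(f"unknown AVPU level {value!r}") from exc
    if parameter not in NUMERIC_PARAMETERS:
        raise ConfigurationError(f"unknown MEOWS parameter {parameter!r}")
    if parameter == "urine_output" and value == NOT_MEASURED:
        return bands.not_measured_score
    value = float(value)
    lo, hi = ADMISSIBLE[parameter]
    if not (lo <= value <= hi):
        raise ValidationError(
            f"{parameter}={value} outside admissible range [{lo}, {hi}]"
        )
    v = _snap(parameter, value)
    band_list = bands.numeric[parameter]
    for band in band_list:
        if band.contains(v):
            return band.score
    # value fell in a printed gap: most-severe-adjacent policy
    below = [b for b in band_list if b.hi is not None and b.hi < v]
    above = [b for b in band_list if b.lo is not None and b.lo > v]
    candidates = []
    if below:
        candidates.append(max(below, key=lambda b: b.hi).score)
    if above:
        candidates.append(min(above, key=lambda b: b.lo).score)
    if not candidates:  # unreachable for a non-empty validated table
        raise ConfigurationError(f"{parameter}: no band adjacent to {value}")
    return max(candidates)


def apply_pulse_rule(band_score: int, pulse: float, systolic_bp: float) -> int:
    """Floor the pulse score at 2 whenever pulse exceeds systolic pressure.

    The chart rule reads: if the pulse rate is higher than the systolic
    blood pressure, score 2 for pulse.  Interpreted as a floor
    (``max(band_score, 2)``) so it can never lower a band score of 3.
    """
    if pulse is None or systolic_bp is None:
        raise ValidationError("pulse rule needs both pulse and systolic_bp")
    if pulse > systolic_bp:
        return max(band_score, 2)
    return band_score


def classify_trigger(total: int) -> TriggerCategory:
    """Map a MEOWS total to its escalation tier (<=2 / 3-5 / >=6)."""
    if total < 0:
        raise ValidationError(f"negative MEOWS total {total}")
    if total <= 2:
        return TriggerCategory.CURRENT_PLAN
    if total <= 5:
        return TriggerCategory.REVIEW
    return TriggerCategory.ESCALATE


def compute_meows(
    obs: VitalSignsObservation,
    bands: ScoreBandTable = DEFAULT_BANDS,
) -> MEOWSResult:
    """Score an observation: per-component bands, pulse rule, total, trigger.

    Missing components contribute nothing to the total and are counted in
    ``n_missing_components``; an observation with no component at all is
    unscorable.
    """
    present = obs.present_components()
    if not present:
        raise UnscorableError("all MEOWS components missing")
    scores: dict = {}
    for param in present:
        scores[param] = score_component(param, getattr(obs, param), bands)
    pulse_rule_applied = False
    if obs.pulse is not None and obs.systolic_bp is not None:
        floored = apply_pulse_rule(scores["pulse"], obs.pulse, obs.systolic_bp)
        pulse_rule_applied = floored != scores["pulse"]
        scores["pulse"] = floored
    total = int(sum(scores.values()))
    return MEOWSResult(
        component_scores=scores,
        total=total,
        n_missing_components=len(MEOWS_PARAMETERS) - len(present),
        trigger_category=classify_trigger(total),
        pulse_rule_applied=pulse_rule_applied,
        urine_not_measured=obs.urine_output == NOT_MEASURED,
    )
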