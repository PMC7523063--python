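# Methods

This note documents the scoring rules, statistical procedures and design
choices behind `meows-ri`, and what the synthetic data can and cannot show.

## The instrument

### MEOWS band scoring

Seven physiologic parameters are scored 0–3 per observation and summed.
The shipped default table, version tag `rw-meows-v1`, is fully enumerated:

| parameter | 3 | 2 | 1 | 0 | 1 | 2 | 3 |
|---|---|---|---|---|---|---|---|
| temperature (°C) | | < 35 | | 35.0–37.4 | 37.5–39.0 | > 39 | |
| systolic BP (mmHg) | ≤ 70 | 71–80 | 81–89 | 90–139 | 140–149 | 150–159 | ≥ 160 |
| diastolic BP (mmHg) | | ≤ 45 | | 46–89 | 90–99 | 100–109 | ≥ 110 |
| pulse (/min) | | ≤ 40 | 41–50 | 51–100 | 101–110 | 111–129 | ≥ 130 |
| respiratory rate (/min) | ≤ 8 | | 9–14 | 15–20 | | 21–29 | ≥ 30 |
| AVPU | | | | Alert | Voice | Pain | Unconscious |
| urine output (mL/h) | < 10 | 10–29 | | ≥ 30 / not measured | | | |

Conventions and open points resolved here:

- **Column alignment.** Printed bedside charts are often typeset with fewer
  cells than score columns; the alignment above follows the printed
  left-to-right cell order around the 0 column. Because the table is
  configuration (YAML-loadable, exportable via `export-defaults`), an
  alternative alignment is a data change, not a code change.
- **Gaps and overlaps.** Printed charts leave small holes (systolic 80
  between "71–79" and "81–89") and double-bookings (pulse 40). Both resolve
  to the **more severe adjacent band** — clinically conservative and
  deterministic. The default table is pre-closed so the policy only fires
  for user-supplied tables.
- **Boundaries.** All printed interval endpoints are closed. Values are
  snapped to instrument precision first (temperature 0.1 °C, all else
  integer, half-up), which removes float-boundary ambiguity.
- **"Not measured" urine** scores 0 but is flagged on the result
  (`urine_not_measured`), so absent data never inflates a total; form
  completeness is accounted for by the audit, not the scorer.
- **Pulse rule.** "If the pulse rate is higher than the systolic blood
  pressure, score 2 for pulse" is implemented as a floor,
  `max(band_score, 2)`, so it can never lower a band score of 3.
- **Missing components** contribute nothing; the result records how many
  of the seven were absent, and an observation with no component at all is
  an error (`UnscorableError`). Every observation is scored, not only the
  admission one; the trigger tiers are ≤ 2 / 3–5 / ≥ 6.

### RI classification

Each condition (hemorrhage, preeclampsia/eclampsia, sepsis) is the
**max-rule** over a declarative criteria catalogue: any satisfied high-tier
criterion ⇒ high; else any moderate-tier criterion ⇒ moderate; else low.
The overall RI level is the max of the three. Choices made where the
printed chart is ambiguous:

- **Preeclampsia CVS thresholds** are internally inconsistent in print
  (the same DBP range under two tiers, a tachycardic threshold under
  "low"). The catalogue uses standard obstetric severity thresholds:
  SBP ≥ 160 high / 140–159 moderate; DBP ≥ 110 high / 90–109 moderate;
  HR ≥ 130 high / 111–129 moderate.
- **Criteria printed under two tiers** (nausea/vomiting, abdominal pain,
  chest pain, ASAT/ALAT > 70) take the higher tier.
- **Numeric gaps between tiers** (creatinine 0.8–0.9 and 1.1–1.2, sepsis
  SBP at 90, sepsis RR at 25, HR at 130, preeclampsia urine output between
  15 and 30 mL/h once the 2-hour high-tier volume is halved to mL/h) go to
  the more severe tier, matching the MEOWS gap rule.
- **Sepsis screening risk factors** (diabetes/comorbidity, recent invasive
  procedure, prolonged rupture of membranes, bleeding/offensive discharge)
  are recorded as flags but never change the tier by themselves; only the
  diagnosis criteria carry tier logic.
- The conjunctive hematocrit criterion ("Hct < 30 AND refusal of
  transfusion AND other risk factors") is a single user-supplied boolean;
  the package does not attempt to decompose it.
- Labor/postpartum re-evaluation factors (prolonged second stage,
  prolonged oxytocin, magnesium sulfate) map to moderate-tier hemorrhage
  criteria when flagged — the least severe actionable tier, since the chart
  lists them without a tier.
- Absent checklist fields default to false; absent numeric findings never
  satisfy a criterion.

### Triage dichotomy

The evaluation's binary exposure is *moderate-or-high* vs *low*. The chart
defines the dichotomy but not its construction, so the default is the
disjunction **RI ≥ moderate OR MEOWS total ≥ 3** (i.e. the review trigger
counts as moderate), applied to the first observation per record. Both
assumptions are switchable (`rule="ri_only" | "meows_only"`), enabling
sensitivity analyses. The decision is monotone in both inputs.

## Statistical procedures

- Sensitivity, specificity, PPV, NPV, accuracy as the usual 2×2
  proportions; any statistic with a zero denominator is reported as
  undefined while the others are still computed.
- **Relative risk** RR = [TP/(TP+FP)] / [FN/(FN+TN)] with the **Katz
  log-method** CI. The method choice matters: on the table
  (13, 23, 32, 331) it gives 4.10 (2.37–7.07), i.e. 4.1 (2.4–7.1) at one
  decimal. When a cell is zero, the Haldane–Anscombe 0.5 correction is
  applied to all four cells; a zero margin leaves RR undefined. Tests
  verify the interval against statsmodels' `Table2x2`, a multinomial
  bootstrap, and ~95% empirical coverage over simulated tables.
- **Chi-square**: Pearson on the 2×2 without Yates correction by default
  (the correction is a flag); computed via `scipy.stats.chi2_contingency`.
- **Composite morbidity** is the logical OR of the PPH / infection /
  pre-eclampsia components; a record with all components unrecorded has an
  unascertained outcome.
- **Listwise exclusion**: records lacking the predictor (no vitals and no
  checklist data) or the outcome are excluded from the 2×2 with logged
  counts. Reported percentages are rounded half-up to one decimal. NPV on
  the replica table is 331/363 = 91.18% → 91.2% at one decimal; the
  package accepts a ±0.1-point band around published prints of this
  quantity, treating discrepancies at the last digit as truncation.
- **Completeness audit**: a form is completed when all required fields are
  present, empty when none are, partial otherwise. The default required
  fields are the four bedside-form section markers (vitals, hemorrhage,
  preeclampsia, sepsis sections), which separates *bedside documentation*
  (feasibility) from the *analysis dataset* (vitals/checklists/outcomes as
  abstracted from charts) — a record whose form was never filled can still
  be analyzable, and a partially documented one can still lack outcome
  data.
- **Likert summaries**: fraction of responses in the top-k most favourable
  categories (k = 2 by default), per question.

## Synthetic cohorts

The generator emulates the statistical structure the evaluation assumes;
no patient-level data ships with the package.

- **Inverse (class-first) construction.** Morbidity ~ Bernoulli(prevalence);
  intended triage class positive with probability `target_sensitivity`
  given morbid and `1 − target_specificity` given not. Only then are the
  record's vitals and findings drawn, uniformly within bands that guarantee
  the class: negatives stay inside ranges that avoid every moderate/high
  threshold of both instruments (MEOWS total ≤ 1), positives receive one of
  four mechanisms — a hemorrhage checklist flag, a preeclampsia lab/symptom
  finding, a sepsis finding, or a vital-sign derangement with MEOWS ≥ 3
  (mixing proportions uniform by default, configurable). This makes the
  round-trip test exact: re-scoring every generated record reproduces its
  intended class, asserted at 100%.
- **Defaults are the study conditions**: n = 478, prevalence 49/478
  (10.3%), operating point 28.9% / 93.5%, form-status fractions
  363/79/36 of 478.
- **Demographics** (age 28.3 ± 6.4 years truncated to 15–49, gravida,
  parity, four district labels at the observed frequencies) are cosmetic:
  the classifiers never read them.
- **Masking** for partially-completed forms touches only the form markers
  and cosmetic demographics — never the classification inputs or the
  outcome — so data-quality simulation cannot silently change a class.
- **Determinism**: one `numpy` Generator stream seeded from the mandatory
  config seed; equal seeds give byte-identical cohorts, and the seed is
  echoed in the file's provenance header.
- **Study-replica cohort** (`study_replica_fixture`): deterministic 478
  records. The 399 analyzable ones reproduce the 2×2 table
  (13, 23, 32, 331); the 79 excluded records (43 further partial forms +
  36 empty forms) lack predictor data, 4 of them carrying the morbidity
  outcome so that 49/478 = 10.3% of records are morbid. The arithmetic
  coincidence in the published margins (analyzable 399 = 363 completed +
  36, excluded 79 = 43 + 36 empty) is resolved this way deliberately; it
  is one consistent reading, not the only possible one.

**What passing tests do and do not show.** Because generation is
class-first, round-trip consistency validates the *scoring and triage
logic*, not any physiologic realism: real vital signs are correlated over
time and across parameters, real risk factors co-occur, and real
missingness is informative. None of that is modelled (single admission
observation, independent uniform draws within bands, covariate-only
masking), so recovered sensitivity/specificity on synthetic cohorts says
nothing about the instrument's clinical performance — only that the
pipeline measures faithfully whatever structure the data contain.

## Numerical choices and problem sizes

- Band membership uses closed intervals on the precision-snapped grid with
  a 1e-9 tolerance; half-up rounding via `floor(x/step + 0.5)`.
- z-quantiles from `scipy.stats.norm.ppf`; no exact/mid-p small-sample
  variants are offered (out of scope for a fixed-dichotomy instrument).
- Test problem sizes: 10,000 random observations for scorer–oracle
  equivalence; exhaustive integer scans of every parameter's admissible
  domain; 10,000-record simulated cohorts for operating-point recovery
  (binomial-3SE bands); 2,000 simulated tables for CI coverage; 100,000
  multinomial draws for the bootstrap cross-check. These sizes keep the
  whole suite in the low minutes on one CPU while leaving Monte-Carlo noise
  well below the assertion bands.

## Known limitations

- The instrument is ordinal with a fixed dichotomy; no ROC over continuous
  thresholds, no multivariable adjustment, no longitudinal trigger
  escalation across serial observations, and no mortality modelling.
- The band-table column alignment and the repaired preeclampsia thresholds
  are documented editorial choices where the printed chart is ambiguous;
  both are configuration, so alternatives can be evaluated without code
  changes.
- Free-text clinical notes, drug dosing logic and care-process modelling
  (training, coaching, referral logistics) are out of scope; response
  recommendations are static chart transcriptions.
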