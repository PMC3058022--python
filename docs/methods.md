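# Methods

## Scope and design

`icubench` evaluates four daily ICU severity scores — CASUS, SOFA,
APACHE II and SAPS II — as predictors of ICU mortality in postoperative
cardiac surgery stays. The unit of scoring is the stay-day: day 1 is the
operative/admission calendar day, and a stay with ICU length of stay
(ICULOS) *L* contributes exactly days 1..*L*. The unit of evaluation is a
(system, day) or (system, derivative) pair.

## Worst-value-per-day reduction

Raw observations arrive as repeated measurements per variable per day.
Before scoring they are reduced to a per-day panel holding, for every
continuous variable, **both** daily extremes (min, max). "Most abnormal
value of the day" is then defined per scoring system, not per variable:
each engine evaluates its own point bands at both extremes and keeps the
larger point value. Every published band function is quasiconvex around
the normal range (points grow with abnormality in either direction), so
the maximum over all raw readings of a day is always attained at one of
the two extremes; a property test verifies this against brute-force
scoring of every reading. Urine output is summed over the day, device and
support flags are OR-ed, GCS takes the daily minimum, and ordinal strata
(neurologic state, catecholamine dose class) take the daily maximum.

Missing variables are imputed with their zero-point (normal) value and
logged, matching the convention of the original scoring systems; a strict
mode raises instead. Readmissions are reduced to the first admission per
patient (identical admission timestamps are an error, not a silent pick).

## Scoring engines

Point tables are shipped as versioned YAML data (`icubench/tables/`), one
file per system, with band semantics `[lower, upper, points]`, lower
inclusive / upper exclusive, so any band can be diffed against its source
publication without reading code. Engine code contains only the
conditional logic that tables cannot express:

- **SOFA** (six organ components, each 0–4, total 0–24): respiratory
  strata 3–4 require mechanical ventilation (otherwise capped at 2); the
  cardiovascular component is the worse of the MAP stratum and the
  catecholamine dose-class stratum; the renal component the worse of
  creatinine and urine-output strata.
- **APACHE II** (acute physiology + age + chronic health, computed every
  ICU day with the admission-level components held constant):
  oxygenation uses the alveolar–arterial gradient
  `FiO2·713 − PaCO2/0.8 − PaO2` when the worst FiO2 ≥ 0.5 and PaO2
  otherwise; GCS contributes `15 − GCS`. Creatinine points are not
  doubled (the input vocabulary carries no acute-renal-failure flag) and
  serum HCO3 is never substituted for pH (blood gases are always
  present in this pipeline). Any qualifying severe chronic organ
  insufficiency or immunocompromise scores 2 points for scheduled
  surgical admissions and 5 otherwise.
- **SAPS II** (17 items, max 163): the oxygenation item applies only on
  ventilated days; the chronic-disease item takes the single worst
  applicable category (metastatic cancer 9 / hematologic malignancy 10 /
  AIDS 17). The published points-to-probability transform
  `logit p = −7.7631 + 0.0737·S + 0.9971·ln(S+1)` is exposed as
  `saps2_probability` but deliberately **not** used by the benchmark,
  which recalibrates all four systems uniformly (below).
- **CASUS** (ten descriptors, each 0–4, max 40): the ten-descriptor
  structure treats IABP/VAD as one mechanical-assist descriptor (VAD 4,
  IABP 3) and creatinine/renal-replacement as one renal descriptor
  (dialysis scores 4 outright). Neurologic state is a dedicated ordinal
  bedside variable, never derived from GCS. The band edges in
  `tables/casus.yaml` are reconstructed from the original publication's
  descriptor set; the file is data precisely so individual edges can be
  corrected independently of code.

GCS is taken as recorded (possibly under sedation); the daily-minimum
reduction makes no attempt to reconstruct a pre-sedation value.

**Derivatives.** For one stay and system with daily totals
`t_1..t_L`: Mean-score `= Σt_d / L` and Max-score `= max t_d`, with `L`
the number of scored calendar days.

## Validation battery

For each evaluation cell (system × day *d*, or system × derivative):

1. **At-risk set**: stays with ICULOS ≥ *d* (all stays for derivatives).
   The response is the stay's final ICU outcome. Cells below a minimum
   at-risk size (default 100) are reported as unevaluable, generalizing
   the convention of stopping per-day analyses once too few patients
   remain.
2. **Logistic recalibration** (`statsmodels` ML fit): odds ratio per
   point `exp(β)` with 95% Wald CI `exp(β ± 1.96·SE)`. Complete or
   quasi-complete separation and degenerate designs (one outcome class,
   constant scores) raise typed errors rather than returning silent huge
   odds ratios.
3. **Hosmer–Lemeshow** on the recalibrated probabilities: subjects ranked
   into g = 10 decile-of-risk groups (quantile cuts; tied predictions stay
   together, so fewer groups can result), χ² = Σ (O−E)²/(E(1−E/n_g)),
   df = groups − 2, upper-tail p. Groups with zero expected deaths merge
   into an adjacent group with a warning. Recalibrated probabilities are
   used for every system — including SAPS II — because two of the four
   systems publish no native probability; uniform recalibration is the
   only comparable treatment.
4. **ROC/AUC** on the raw points: Mann–Whitney with ties ½; the 95% CI by
   DeLong's structural-components variance (validated against R `pROC`
   to 1e−12 on a frozen dataset) or Hanley–McNeil; anti-discrimination
   (AUC < 0.5) is reported as-is. CIs are clipped to [0, 1].
5. **OCC**: share of subjects with `1{p̂ ≥ 0.5} = outcome`, ×100; the
   cutoff is configurable.

Significance is fixed at p < 0.05; rows with HL p below it carry a
`significant_miscalibration` flag mirrored as `*` in rendered tables.
No multiple-testing correction is applied and no AUC-difference test
between systems is computed.

## Synthetic cohort generator

Each stay carries a scalar latent severity `s_d ≥ 0`:

- `s_1 ~ Gamma(2, 0.92)`;
- a stay is a "decliner" with probability `expit(−3.08 + 0.5·s_1)`;
- recoverers follow `s_{d+1} = max(0, −0.1 + 0.96·s_d + ε)`,
  decliners `s_{d+1} = max(0, 0.15 + s_d + ε)`, `ε ~ N(0, 1.05²)`;
- each day, death occurs with probability `expit(−7.2 + 0.55·s_d)`;
  otherwise discharge with probability `expit(2.2 − 1.28·s_d)` (minus a
  4.5-logit offset on day 1: patients are not discharged on the
  operative day), otherwise the stay continues (hard cap 189 days).

Every physiological variable is emitted `readings_per_day = 3` times per
day through a monotone link `base + slope·s_d + N(0, σ)` clipped to a
physiological range; oxygenation is generated through the PaO2/FiO2-ratio
link so the ratio itself is monotone in severity; GCS, neurologic state,
catecholamine class and device flags derive from thresholds on `s_d`
(ventilation is always on for day 1). EuroSCORE fields are toy noisy
monotone functions of baseline severity, present only so file schemas are
complete.

A single scalar severity (rather than per-organ processes) is a
deliberate choice: the benchmark needs controllable discrimination and
calibration, not physiological realism. Consequences to keep in mind when
interpreting green tests: all organ systems worsen in lockstep, inter-score
correlations are higher than in real cohorts, and measurement artifacts
(sedated GCS, transfusion-driven hematocrit, pacing) do not exist. Passing
tests demonstrate correctness of the engines and statistics and sane
operating characteristics under a known generating process — not clinical
performance of any score.

### Calibration of the default configuration

The packaged defaults (`tables/default_generator.yaml`) were tuned once,
by simulation during development, to published cardiac-surgery ICU cohort
margins, then frozen: asymptotic ICU mortality 5.23 % (target ≈ 5.2 %),
mean ICULOS 4.19 d (target 4.3), median ICULOS 2 d, 75th percentile 4 d,
female fraction 29.6 %, age truncated-normal with realized mean 66.85 y
and SD 10.65 y (targets 66.9/10.7) on [19, 89], and a fixed surgery-type
mix led by CABG (54.5 %). The survivor/decliner mixture, not a parametric
LOS draw, produces the long right tail (typical maxima 60–110 d at
n = 2801 against a published-range ceiling of 189 d); the realized LOS SD
(≈ 4.7–5.2 d) underestimates the heavy-tailed target of 6.8 d — a known
limitation of a two-component hazard mixture, accepted to keep the event
process day-indexed and hazard-based.

The per-stay latent severities and event labels are returned in a truth
table separate from the public cohort files; recovery tests read truth
through that path only, so the benchmark itself never sees the latent
state. A `null_config()` variant zeroes both hazard slopes (with
intercepts reset to per-day death 0.0234 and discharge 0.438, preserving
marginal mortality ≈ 5.2 % and median LOS 2) so that outcome is
independent of severity; under it every system's AUC converges to 0.5,
which the acceptance suite checks over 50 cohorts.

## Numerical and operating-characteristic checks

- Engines: ≥ 10 hand-scored fixture panels per system, frozen as data and
  matched exactly; additivity, published-range bounds and
  creatinine-monotonicity verified on randomized panels (hypothesis,
  derandomized).
- AUC: equality with exhaustive pair enumeration to 1e−12 on 100 random
  datasets of n ≤ 200.
- Hosmer–Lemeshow: exact agreement with an independently computed decile
  table at n = 200; type-I error within [0.03, 0.07] over 1000 simulated
  cohorts of n = 1000 under a correctly specified logistic model.
- Logistic recalibration: slope agreement to 1e−3 with a nested
  grid-search MLE; 95 % Wald coverage of a planted slope within 95 ± 3 %
  over 500 cohorts.
- Generator: margins of the n = 2801 default cohort within binomial 95 %
  bands (rates) or ±0.5 (means) of the design values; median ICULOS
  exactly 2.
- End-to-end: two `run-all` invocations with one seed produce
  byte-identical evaluation CSVs.

Problem sizes in the test suite (cohorts of 120–2801 stays, 50–1000
simulation replicates) were chosen to keep Monte-Carlo error well inside
each asserted tolerance while the whole suite runs in a couple of
minutes.

## Known limitations

- CASUS band edges are a reconstruction (see above); the YAML data file
  is the single point of correction.
- APACHE II omits the acute-renal-failure creatinine doubling and the
  HCO3 fallback; both require inputs outside the vocabulary.
- Worst-value panels lose within-day pairing of PaO2/FiO2/PaCO2; the
  oxygenation items pair the day's worst components, which can slightly
  overstate severity on days with discordant readings.
- The generator emits calendar-day data only; sub-daily windows,
  inter-organ divergence, readmissions and hospital (post-ICU) mortality
  are out of scope.
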