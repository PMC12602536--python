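# Methods

This note documents the model implemented in `obesim`: its structure and
assumptions, the parameters that matter, what the synthetic defaults emulate,
and the numerical and design choices made where the published description of
this class of model leaves the design open.

## Model structure

The cohort is deterministic (no microsimulation): a state-occupancy vector
over 65 states — the empty state, all combinations of up to three of seven
comorbidities (type 2 diabetes, ACS, hypertension, dyslipidaemia, asthma,
CKD, obstructive sleep apnoea), and absorbing death — is advanced through
per-cycle row-stochastic transition matrices.  States are ordered by
combination size, then by the fixed condition order, with death last;
conditions are never lost (no remission), and a state carrying three
conditions can only stay or die.

The cycle calendar is quarterly for the first year (to resolve the 12-week
response assessment and early discontinuation) and annual thereafter to a
40-year horizon (43 cycles).  Rewards use the half-cycle correction — each
cycle's reward is `cycle length × rate · (v_start + v_end)/2` — and are
discounted at the cycle midpoint, `(1+r)^-(start + length/2)`, which pairs
naturally with mid-cycle-valued rewards; a `discount_timing="start"` flag
switches to start-of-cycle discounting for sensitivity.  Both costs and
outcomes discount at 3.5 %/year by default.

**Competing risks within a cycle.**  Annual incidences convert to cycle
probabilities via `1 − (1−p)^len`.  Within a cycle, the joint mass of the
independent per-condition probabilities is redistributed proportionally over
single acquisitions (factor `(1 − Π(1−p_c)) / Σ p_c`), so at most one
condition is acquired per cycle; at quarterly/annual granularity with
incidences of a few percent the correction is second-order.  A
`joint_acquisition` flag instead allocates each subset of absent conditions
its independent product mass (subsets above the three-condition cap are
truncated to the cap in condition order); it is off by default.

## BMI trajectories

BMI is the sole surrogate risk factor; the cohort-level mean BMI path per
arm is a mixture of pathways, each sampled at cycle midpoints:

* **Responders** (1 − non-responder rate) follow the arm's percent-weight-
  change anchor timeline (linear interpolation between anchors, plateau
  beyond the last) for at most `max_treatment_years` (2).  An adverse-event
  discontinuation hazard (annual rate, resolved at cycle boundaries) splits
  them into stop-time sub-cohorts.  After stopping, the residual effect
  fades linearly toward the diet-and-exercise trajectory over
  `catch_up_years` (3); a scenario flag retargets the fade to pure natural
  progression.
* **Non-responders** fail the ≥ 5 % weight-loss criterion at week 12
  (assessed at the end of the cycle containing the rule week, i.e. week ≈ 13
  on the quarterly grid).  While on treatment they achieve a configurable
  fraction (default 0.5) of the arm-mean percent change — sub-threshold by
  definition — and switch to the diet-and-exercise timeline at the
  assessment, with no separate catch-up.  When the stopping rule is
  disabled for an arm they instead stay on treatment to the maximum
  duration with that sub-threshold effect, then catch up like responders.
* The **diet-and-exercise** trajectory follows its own modest timeline and
  then fades to natural progression over the catch-up period.

Natural progression adds 0.47 kg/year of weight, applied to BMI through
height² (`0.47/1.70² ≈ 0.163` BMI units/year); a `bmi_per_year` units flag
supports the alternative reading that the drift is in BMI units directly.
All pathways rejoin the natural-progression path within a few years of
stopping, so arms differ only transiently — the central mechanism of the
economic question.

## Risks and mortality

Each complication's incidence is a calibrated log-linear function of BMI:
`p(BMI) = base_rate × exp(log_RR × (BMI − reference))`, optionally scaled by
prevalence-weighted covariate multipliers (`1 − f + f·m`), capped at 1.
This is a deliberately pluggable interface: published multi-covariate risk
equations (QDiabetes-, QRISK3-, Framingham-style) enter this cohort model
only through their BMI gradient, and any calibrated function can be dropped
in (including a `rate-table` kind for banded rates).

Background mortality starts from an age- and sex-indexed life table,
subtracts the fraction of all-cause deaths attributable to the modelled
diseases (proportional deduction, not cause-deleted life-table algebra —
the difference is second-order at these magnitudes), and multiplies by a
BMI-band hazard ratio (HR = 1 at 18.5–25) for residual obesity-attributable
risk.  Disease mortality is added back state-specifically: per-condition
excess multipliers compose on the hazard scale,
`q_state = 1 − (1−q_residual)^(Πm × len)`, which guarantees the modelled
all-cause mortality never falls below background.  Ages advance with cycle
time; lookups use `floor(age)` and refuse to extrapolate outside the table.

## Valuation

**Utilities.**  Complication-free utility comes from the published
regression (cubic in BMI with age, cardiovascular history, hypertension
treatment, smoking and prediabetes covariates, evaluated at cohort
prevalence fractions).  Evaluated at the cohort's baseline means the
regression gives ≈ 0.881, while the separately published cohort baseline
utility is 0.78 (SE 0.023); the two cannot be reconciled from printed
information.  The default `anchored` mode therefore pins model-entry
utility at 0.78 and applies the regression only through per-cycle
*differences* as BMI and age evolve, preserving the dynamic BMI–utility
link at the published level; `regression` mode evaluates the polynomial
directly.  Condition disutilities are additive and persistent; the result
clamps to [0, 1] (clamped evaluations are counted and reported by the PSA).
Acute-event disutilities are one-time decrements in the cycle of occurrence.
Adverse-event disutilities (GI events, non-severe hypoglycaemia) apply only
during active treatment, scaled by the on-treatment cohort fraction.

**Costs** (2025 €, payer perspective; no indirect costs).  Drug acquisition
walks the titration calendar (semaglutide: 4 weeks each at 0.25/0.5/1/1.7 mg
then 2.4 mg maintenance; liraglutide: flat 3 mg) and dispenses continuous
pack counts — days at each dose divided by `pack_coverage_days`, weighted by
on-treatment exposure — at the statutory 75 % payer share.  The default
pack coverage is **7 days**: calibrating the dispensing model against the
published per-arm discounted treatment spend (≈ €10,261 semaglutide over two
years) implies the listed prices cover about one week of maintenance
therapy; a 28-day reading under-spends by roughly a factor of four.  The
field is fully configurable.  Consumables (needles) pro-rate over treated
time and are reimbursed in full by default.  Monitoring (€124.88/year) is
charged to every alive state, with condition costs additive on top — the
printed "no complications" state cost equals the annual monitoring cost, so
the additive convention treats it as universal monitoring (a flag restricts
it to the empty state instead).  Incident ACS triggers a one-time acute
cost mixing MI and unstable angina with fatal/non-fatal tariff splits
(70 % MI; fatal fractions 12 %/4 %, synthetic), and the ACS event
disutility.  Stroke and TIA tariffs are carried in the cost table for
completeness but no modelled state generates those events.

## Decision metrics

ICERs are computed from full-precision increments; printed-rounded
increments are used only in cross-checks that are themselves defined on
printed numbers (the published tables are internally inconsistent at the
third decimal: printed ΔC/ΔQ = 1,083.37/0.09 = 12,037 while the published
headline ICER is 12,724, implying unrounded ΔQ ≈ 0.0852).  Dominance is
labelled rather than reported as a negative ratio; CE-plane quadrants use
the conventions ΔC = 0 → SE (for ΔQ > 0) and ΔQ = 0 → NW.  NMB is
`λ·ΔQ − ΔC`, reported rounded to whole euros.

## Sensitivity machinery

*One-way DSA*: ±25 % around base values where no empirical uncertainty is
published, two full model runs per parameter, ranked by ICER span; the
default report shows the eleven most influential parameters (configurable).
*Scenarios*: ten packaged specs (disease-specific mortality only; treatment
for 3/4/5/6/9 years; trial-product estimand with and without the stopping
rule — the latter retaining the rule for the comparator arm; reversion to
natural progression; one-year regain).  The estimand scenarios use
synthetic effect multipliers (1.08/1.05) because estimand-specific
timelines were not published.
*PSA*: 1,000 independent draws by default — Gamma for costs
(method-of-moments shape/scale), Beta for probabilities and utilities
(method-of-moments, published SEs where available, otherwise SE = 20 % of
the point estimate; disutilities sampled on their magnitude and negated),
Lognormal for the arm-level efficacy multiplier, which perturbs all
timeline anchors jointly and preserves trajectory shape.  Administered drug
tariffs are not sampled.  Draws are uncorrelated, matching the described
practice; correlated sampling is a known omission.  Summaries report mean,
SD, percentile 95 % CI, min and max; the CEAC is the fraction of draws with
positive NMB on a 0–50,000 € grid (step 500, always including 9,000 and the
decision thresholds).

## Synthetic defaults and what tests do (and do not) show

The source evaluation's efficacy timelines, risk calibrations, life table,
BMI hazard-ratio bands and excess-mortality multipliers were published only
in unavailable supplementary material.  The packaged defaults
(`obesim.fixtures`) are synthetic stand-ins chosen once to be clinically
plausible: arm timelines patterned on the head-to-head trial's topline
magnitudes (−15.9 %/−6.4 % at 68 weeks) with the printed non-responder
rates; Gompertz–Makeham life table (q(48) ≈ 0.002, q(80) ≈ 0.04);
obesity-graded mortality HR bands (1.0 at healthy weight to 2.35 above
BMI 45); complication incidences of 0.4–3.5 %/year at the cohort's baseline
BMI with RRs of 1.025–1.09 per BMI unit.  Every such value carries a
[FIXTURE] provenance tag, and the loader refuses configurations containing
untagged numbers.

Consequently the test suite verifies *arithmetic identities on the
published tables* (component sums, NMB, percent changes, PSA increments)
and *structural properties of the engine* (oracle equivalence against a
naive loop-based reference, half-cycle hand cases, mass conservation,
monotonicities, distribution-moment recovery, CEAC decomposition,
degenerate-PSA collapse).  Passing tests demonstrate the machinery is
correct, not that the fixture inputs reproduce the published headline ICER
— which is not recoverable from printed information and is deliberately not
an acceptance quantity.  Problem sizes used by the default suite and the
acceptance script — the full 65-state/43-cycle model, 100 random toy
instances for oracle equivalence, 1,000 PSA iterations, 10,000-draw moment
checks — are the package's standard working sizes.

## Known limitations

* Cohort means only; no individual-level heterogeneity or microsimulation.
* No remission, no tunnel states, no recurrent-event counting beyond the
  one-time ACS event reward; stroke/TIA valuation hooks exist but no
  incidence model feeds them.
* Regression covariates other than age and BMI stay at baseline prevalence
  (comorbidity onset enters utility only through additive disutilities).
* Independent PSA draws; no correlation structure, no EVPI.
* Fixture-dependent absolute outputs, as discussed above.
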