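# obesim

A Markov cohort state-transition model for the long-term cost-effectiveness
of obesity pharmacotherapy: **semaglutide 2.4 mg versus liraglutide 3.0 mg**
in adults with BMI ≥ 35 kg/m² and at least one weight-related comorbidity,
from the perspective of the Greek third-party payer (EOPYY).  It is written
for health-economics analysts who need a transparent, fully configurable and
testable re-implementation of this class of BMI-driven decision model —
every input enters through a provenance-tagged configuration, and every
stage (trajectory, risks, cohort engine, valuation, decision metrics,
sensitivity analyses) is an importable, separately tested component.

## The model

A hypothetical cohort enters a 65-state Markov model: the complication-free
state, all single / double / triple combinations of seven comorbidities
(type 2 diabetes, acute coronary syndrome, hypertension, dyslipidaemia,
asthma, chronic kidney disease, obstructive sleep apnoea), and an absorbing
death state.  Cycles are quarterly in year one and annual thereafter over a
40-year horizon, with half-cycle correction and mid-cycle discounting at
3.5 %/year for both costs and outcomes.

BMI is the sole surrogate risk factor.  Each arm's cohort BMI path mixes:

* **responders** — on-treatment percent-weight-change timeline for at most
  2 years, then a linear *catch-up* toward the diet-and-exercise trajectory
  over 3 years, then natural weight gain of 0.47 kg/year;
* **non-responders** (24.6 % semaglutide, 38.6 % liraglutide) — failure to
  lose ≥ 5 % of baseline weight by week 12 stops treatment and reverts them
  to diet and exercise alone.

Per cycle, BMI maps to complication incidence through calibrated log-linear
risk functions (a pluggable stand-in for published risk equations), and to
mortality through a cause-deleted life table with BMI-band hazard ratios and
per-state excess-mortality multipliers.  States and events map to utilities
(published baseline-utility regression, additive disutilities) and 2025 €
costs (drug acquisition at a 75 % payer share, monitoring, annual state
costs, acute-event tariffs).  Two strategies are compared by

ICER = ΔC/ΔE  and  NMB(λ) = λ·ΔQALY − ΔC  at λ ∈ {27 117, 30 000, 34 000} €/QALY,

with one-way DSA (±25 %, tornado ranking), a ten-scenario structural
battery, and a 1,000-iteration PSA (Gamma costs, Beta probabilities and
utilities, Lognormal treatment effects; SE = 20 % of the point estimate
where unpublished) summarised as CE-plane shares and a CEAC.

The efficacy timelines, risk calibrations, life table and hazard-ratio bands
of the source evaluation were published only in unavailable supplementary
material; the packaged defaults for these are clearly-tagged synthetic
fixtures (see `docs/methods.md`), so absolute model outputs are illustrative
while all arithmetic, structure and machinery are exact.

## Worked example

```python
import obesim

config = obesim.load_base_case()          # packaged Greek-payer inputs
result = obesim.run_comparison(config)    # two full cohort runs
print(obesim.comparison_table(result).to_string(index=False))
```

prints (abridged):

```
                                     parameter  semaglutide  liraglutide  incremental
Discounted total lifetime direct medical costs 32346.690472 30341.271325  2005.419148
                       Obesity treatment costs 10251.004600  7758.449816  2492.554784
            Obesity complications: state costs 19589.120001 20113.660955  -524.540954
                              Discounted QALYs    12.548358    12.463606     0.084752
                                Discounted LYs    17.019099    16.979120     0.039979
                    ICER (EUR per QALY gained)                            23662.211534
                    NMB at WTP EUR 27,117/QALY                              293.000000
```

Semaglutide costs €2,005 more over a lifetime — almost entirely drug
acquisition (+€2,493), partly offset by fewer complications (−€525) — and
yields 0.085 extra QALYs, an ICER of ~€23,700/QALY: cost-effective at the
€27,117 threshold (positive NMB of €293) under the synthetic-fixture inputs.
The scripts in `examples/` walk through each capability the same way
(`base_case.py`, `scenarios.py`, `tornado.py`, `psa_ceac.py`,
`bmi_trajectories.py`).

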