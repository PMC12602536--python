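# Base-case configuration: Greek third-party payer evaluation of
# semaglutide 2.4 mg vs liraglutide 3.0 mg for obesity.
# All costs in 2025 EUR. Sections not listed here (arms, risk_functions,
# mortality) are inflated from the packaged synthetic fixture set at load
# time and tagged [FIXTURE].

horizon_years: 40.0
cycle_schedule: [0.25, 0.25, 0.25, 0.25,
                 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
discount_rate_costs: 0.035
discount_rate_outcomes: 0.035
wtp_thresholds: [27117.0, 30000.0, 34000.0]
max_treatment_years: 2.0
stopping_rule_week: 12.0
stopping_rule_threshold: 0.05
stopping_rule_enabled: true
catch_up_years: 3.0
natural_weight_gain: 0.47
weight_gain_units: kg_per_year
post_discontinuation: diet_exercise
payer_share: 0.75
joint_acquisition: false
discount_timing: mid
seed: 0

cohort:
  age: 48.6
  bmi: 41.5
  height: 1.70
  female_fraction: 0.736
  sbp: 128.4
  tchol: 186.0
  hdl: 50.9
  trig: 128.2
  smoker_fraction: 0.452
  smoker_previous_fraction: 0.0
  prediabetes_fraction: 0.488
  t2d_fraction: 0.108
  normoglycemic_fraction: 0.404
  cvd_history_fraction: 0.05
  on_lipid_lowering: 0.314
  on_antihypertensive: 0.447
  hba1c_t2d: 0.075
  t2d_duration: 6.0

costs:
  drug_prices:
    semaglutide_0_25mg: 123.62
    semaglutide_0_5mg: 123.62
    semaglutide_1mg: 123.62
    semaglutide_1_7mg: 167.93
    semaglutide_2_4mg: 190.21
    liraglutide_3mg: 162.98
  pack_coverage_days: 7.0
  consumables_annual: 33.58
  monitoring_annual: 124.88
  state_costs_annual:
    none: 124.88
    t2d: 1125.91
    hypertension: 593.84
    ckd: 811.46
    osa: 1688.40
    dyslipidemia: 924.21
    asthma: 796.58
    acs: 1819.31
  event_costs:
    mi_fatal: 4166.00
    mi_nonfatal: 2724.00
    angina_fatal: 940.00
    angina_nonfatal: 424.00
    stroke_fatal: 2475.00
    stroke_nonfatal: 1625.00
    tia: 806.50
    major_gi: 654.50
  ae_costs:
    minor_hypoglycemia: 287.77
    major_hypoglycemia: 805.77
    major_gi: 654.50
  cpi_reference_year: 2025

utility:
  coefficients:
    intercept: 0.942975
    age: -0.0005414
    heart_circ: -0.0742818
    hypertension: -0.0097531
    smoke_current: 0.0039044
    smoke_previous: -0.0081972
    bmi: 0.0065954
    bmi2: -0.0002476
    bmi3: 0.00000175
    prediabetes: -0.0031133
  baseline_utility: {mean: 0.78, se: 0.023}
  mode: anchored
  state_disutilities:
    t2d: {mean: -0.029, se: 0.006}
    acs: {mean: -0.037, se: 0.008}
    osa: {mean: -0.013, se: 0.004}
    asthma: {mean: -0.021, se: 0.005}
    dyslipidemia: {mean: -0.037, se: 0.004}
    hypertension: {mean: -0.014, se: 0.003}
    ckd: {mean: -0.049, se: 0.002}
  event_disutilities:
    acs: {mean: -0.129, se: 0.032}
    stroke: {mean: -0.181, se: 0.045}
    tia: {mean: -0.033, se: 0.008}
    severe_gi: {mean: -0.001, se: 0.0002}
    severe_hypoglycemia: {mean: -0.015, se: 0.002}
    nonsevere_hypoglycemia: {mean: -0.0062, se: 0.004}

valuation:
  monitoring_additive: true
  acs_mi_fraction: 0.7
  acs_mi_fatal_fraction: 0.12
  acs_angina_fatal_fraction: 0.04
  payer_share_applies_to_consumables: false

provenance:
  horizon_years: "[PAPER] 40-year horizon"
  cycle_schedule: "[PAPER] 3-month cycles in the first year, annual thereafter"
  discount_rate_costs: "[PAPER] 3.5%/year"
  discount_rate_outcomes: "[PAPER] 3.5%/year"
  wtp_thresholds: "[PAPER] EUR 27,117 / 30,000 / 34,000 per QALY"
  max_treatment_years: "[PAPER] maximum treatment duration 2 years"
  stopping_rule_week: "[PAPER] 12-week non-responder rule"
  stopping_rule_threshold: "[PAPER] >=5% weight loss"
  catch_up_years: "[ASSUMED] progressive catch-up over 3 years (rate not published)"
  natural_weight_gain: "[PAPER] 0.47 kg/year natural weight gain"
  payer_share: "[PAPER] statutory 25% co-payment"
  seed: "[DERIVED] run seed"
  cohort: "[PAPER] baseline cohort characteristics table"
  costs: "[PAPER] cost table, 2025 EUR"
  costs.pack_coverage_days: "[DERIVED] listed price ~ one 7-day supply (calibrated to published per-arm treatment spend)"
  utility.coefficients: "[PAPER] baseline-utility regression"
  utility.baseline_utility: "[PAPER] baseline utility 0.78 (SE 0.023)"
  utility.state_disutilities: "[PAPER] health-state disutility table"
  utility.event_disutilities: "[PAPER] acute-event disutility table"
  valuation: "[ASSUMED] reward-mapping conventions (see docs/methods.md)"
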