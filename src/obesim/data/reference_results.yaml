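# Published base-case, scenario and probabilistic results of the Greek-payer
# evaluation this package re-implements, exactly as printed (costs in EUR,
# rounded as in the source tables).  Used only for arithmetic-identity
# cross-checks (component sums, NMB, percent changes); never fed back into
# the simulation engine.

base_case:
  # per-arm discounted lifetime results
  semaglutide:
    total_cost: 27730.63
    treatment_cost: 10261.39
    monitoring_cost: 2172.22
    state_cost: 14827.84
    event_cost: 469.18
    qalys: 13.90
    lys: 17.06
  liraglutide:
    total_cost: 26647.26
    treatment_cost: 8843.97
    monitoring_cost: 2166.16
    state_cost: 15165.16
    event_cost: 471.97
    qalys: 13.81
    lys: 17.03
  incremental:
    total_cost: 1083.37
    treatment_cost: 1417.42
    monitoring_cost: 6.05
    state_cost: -337.31
    event_cost: -2.79
    qalys: 0.09
    lys: 0.04
  icer_per_qaly: 12724
  icer_per_ly: 28051
  nmb:
    "27117": 1357
    "30000": 1617

scenarios:
  # printed scenario ICERs (EUR/QALY) and integer percent change vs the
  # printed base-case ICER of 12,724
  - {row: 1, name: "Disease-specific mortality only", icer: 16071, pct_change: 26}
  - {row: 2, name: "Treatment duration: 3 years", icer: 14020, pct_change: 10}
  - {row: 3, name: "Treatment duration: 4 years", icer: 14655, pct_change: 15}
  - {row: 4, name: "Treatment duration: 5 years", icer: 15018, pct_change: 18}
  - {row: 5, name: "Treatment duration: 6 years", icer: 15239, pct_change: 20}
  - {row: 6, name: "Treatment duration: 9 years", icer: 15487, pct_change: 22}
  - {row: 7, name: "Trial product estimand with a stopping rule", icer: 12331, pct_change: -3}
  - {row: 8, name: "Trial product estimand without a stopping rule", icer: 19249, pct_change: 51}
  - {row: 9, name: "Post-treatment discontinuation to no treatment", icer: 12669, pct_change: 0}
  - {row: 10, name: "Weight returns to baseline in 1 year", icer: 12410, pct_change: -2}

psa:
  semaglutide:
    mean_cost: 24902.28
    mean_qalys: 14.77
    sd_cost: 1479.58
    sd_qalys: 0.18
  liraglutide:
    mean_cost: 25202.93
    mean_qalys: 14.70
    sd_cost: 1498.27
    sd_qalys: 0.17
  incremental:
    mean_cost: -300.65
    mean_qalys: 0.07
    sd_cost: 330.05
    sd_qalys: 0.01
    lci_cost: -942.68
    uci_cost: 334.89
    lci_qalys: 0.04
    uci_qalys: 0.09
  se_quadrant_share: 0.808
  ceac_certain_threshold: 9000.0
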