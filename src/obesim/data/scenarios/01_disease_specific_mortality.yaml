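name: "Disease-specific mortality only"
description: "Exclude BMI-dependent residual excess mortality (all BMI hazard ratios = 1)."
overrides:
  mortality.bmi_hr_enabled: false
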