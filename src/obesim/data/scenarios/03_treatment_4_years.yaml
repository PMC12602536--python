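name: "Treatment duration: 4 years"
overrides:
  max_treatment_years: 4.0
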