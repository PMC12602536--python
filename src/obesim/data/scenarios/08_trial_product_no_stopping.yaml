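name: "Trial product estimand without a stopping rule"
description: "As the trial-product scenario but semaglutide non-responders are kept on treatment (no 12-week rule for the intervention arm)."
overrides:
  arms.semaglutide.efficacy_scale: 1.08
  arms.liraglutide.efficacy_scale: 1.05
  arms.semaglutide.apply_stopping_rule: false
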