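name: "Trial product estimand with a stopping rule"
description: "On-treatment (trial product) effect sizes; synthetic multipliers stand in for unpublished estimand-specific timelines."
overrides:
  arms.semaglutide.efficacy_scale: 1.08
  arms.liraglutide.efficacy_scale: 1.05
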