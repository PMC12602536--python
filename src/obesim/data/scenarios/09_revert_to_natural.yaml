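name: "Post-treatment discontinuation to no treatment"
description: "After stopping, weight reverts toward natural progression with no residual diet-and-exercise benefit."
overrides:
  post_discontinuation: natural
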