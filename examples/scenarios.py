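"""Scenario battery.

Applies the ten packaged structural scenarios (mortality restricted to
disease-specific causes, treatment durations of 3-9 years, trial-product
estimand with/without the 12-week stopping rule, alternative post-treatment
weight-regain assumptions) and prints each scenario's ICER next to its
percent change from the base case.  The ICER is most sensitive to treatment
duration and to how quickly lost weight is regained.
"""

import pandas as pd

import obesim

pd.set_option("display.width", 140)

config = obesim.load_base_case()
table = obesim.run_scenarios(config, obesim.load_packaged_scenarios())
table["icer"] = table["icer"].map(
    lambda x: f"{x:,.0f}" if isinstance(x, float) else x
)
table["pct_change_vs_base"] = table["pct_change_vs_base"].map(lambda x: f"{x:+.0f}%")
print(table.to_string(index=False))
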