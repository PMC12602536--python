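"""Probabilistic sensitivity analysis, CE plane and CEAC.

Draws 1,000 joint parameter realisations (Gamma costs, Beta probabilities
and utilities, Lognormal treatment effect), runs the full model per draw,
and prints the PSA summary (mean, SD, percentile 95% CI, min, max of costs
and QALYs per arm and incrementally), the CE-plane quadrant shares, and the
probability of cost-effectiveness at selected willingness-to-pay thresholds.
"""

import obesim
from obesim.sensitivity import PSASpec, ceac, quadrant_shares, run_psa

config = obesim.load_base_case()
psa = run_psa(PSASpec(n_iterations=1000, seed=config.seed), config)

print(psa.summary.round(3).to_string())
print("\nCE-plane quadrant shares:", quadrant_shares(psa.draws))
print("draws with clamped utilities:", psa.n_clamped_runs)

curve = ceac(psa.draws)
for wtp in (0.0, 9000.0, 27117.0, 30000.0, 34000.0, 50000.0):
    p = curve.loc[curve.wtp == wtp, "probability"].iloc[0]
    print(f"P(cost-effective at EUR {wtp:>9,.0f}/QALY) = {p:.1%}")
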