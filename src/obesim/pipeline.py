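"""End-to-end orchestration: config -> trajectories -> risks -> cohort run ->
decision metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import risk as _risk
from .config import ModelConfig, ScenarioSpec, apply_scenario
from .economics import ArmResult, ComparisonResult, compare
from .markov import RunTrace, StateSpace, build_matrix, enumerate_states, run_cohort
from .trajectory import BMIPath, build_cohort_bmi_path
from .valuation import build_rewards

__all__ = ["ArmRun", "run_arm", "run_comparison", "run_scenarios"]

CONDITIONS = ("t2d", "acs", "hypertension", "dyslipidemia", "asthma", "ckd", "osa")


@dataclass
class ArmRun:
    """One arm's full run: inputs, audit trace, and summarised result."""

    result: ArmResult
    path: BMIPath
    trace: RunTrace
    space: StateSpace
    n_utility_clamped: int = 0


def _build_matrices(
    config: ModelConfig, space: StateSpace, path: BMIPath
) -> list[np.ndarray]:
    m = _risk.build_mortality_inputs(config.mortality)
    cohort = config.cohort
    cov_all = {"prediabetes": cohort.prediabetes_fraction, "smoker": cohort.smoker_fraction}
    grid = path.grid
    mats = []
    n_alive = space.n_states - 1
    for t in range(len(grid)):
        bmi = float(path.bmi[t])
        age = cohort.age + float(grid.mids[t])
        length = float(grid.lengths[t])
        inc = np.zeros(len(space.conditions))
        for j, rf in enumerate(config.risk_functions):
            cov = {k: v for k, v in cov_all.items() if k in rf.covariate_multipliers}
            annual = _risk.annual_incidence(rf, bmi, cov)
            inc[space.conditions.index(rf.condition)] = _risk.prob_for_cycle(annual, length)
        resid = _risk.residual_mortality(m, age, cohort.female_fraction, bmi)
        mort = np.empty(n_alive)
        for i, s in enumerate(space.states[:-1]):
            mort[i] = _risk.state_excess_mortality(resid, m, s, length)
        mats.append(build_matrix(space, inc, mort, config.joint_acquisition))
    return mats


def run_arm(config: ModelConfig, arm_name: str) -> ArmRun:
    """Run the cohort model for one treatment arm on the configured horizon."""
    if arm_name not in config.arms:
        raise KeyError(f"arm '{arm_name}' not in config (have {sorted(config.arms)})")
    space = enumerate_states(CONDITIONS, max_combo=3)
    path = build_cohort_bmi_path(config, config.cohort, config.arms[arm_name])
    mats = _build_matrices(config, space, path)
    rewards = build_rewards(config, space, path, arm_name)
    v0 = np.zeros(space.n_states)
    v0[0] = 1.0  # whole cohort enters complication-free
    trace, totals = run_cohort(
        path.grid.lengths,
        mats,
        rewards,
        v0,
        discount_rate_costs=config.discount_rate_costs,
        discount_rate_outcomes=config.discount_rate_outcomes,
        alive_mask=space.alive_mask(),
        discount_timing=config.discount_timing,
    )
    result = ArmResult(
        name=arm_name,
        treatment_cost=totals.costs.get("treatment", 0.0),
        monitoring_cost=totals.costs.get("monitoring", 0.0),
        state_cost=totals.costs.get("state", 0.0),
        event_cost=totals.costs.get("event", 0.0),
        qalys=totals.qalys,
        lys=totals.lys,
    )
    return ArmRun(
        result=result,
        path=path,
        trace=trace,
        space=space,
        n_utility_clamped=int(rewards.meta.get("n_utility_clamped", 0)),
    )


def run_comparison(
    config: ModelConfig,
    intervention: str = "semaglutide",
    comparator: str = "liraglutide",
) -> ComparisonResult:
    """Run both arms and return incremental decision metrics."""
    a = run_arm(config, intervention).result
    b = run_arm(config, comparator).result
    return compare(a, b, config.wtp_thresholds)


def run_scenarios(
    config: ModelConfig,
    scenarios: list[ScenarioSpec],
    intervention: str = "semaglutide",
    comparator: str = "liraglutide",
) -> pd.DataFrame:
    """Scenario battery: one full comparison per spec, plus the base case.

    The percent-change column is relative to the base-case ICER (NaN where
    either ICER is a dominance label).
    """
    base = run_comparison(config, intervention, comparator)
    base_icer = base.icer_per_qaly if isinstance(base.icer_per_qaly, float) else np.nan
    rows = [
        {
            "scenario": "Base case",
            "cost_intervention": base.intervention.total_cost,
            "cost_comparator": base.comparator.total_cost,
            "qalys_intervention": base.intervention.qalys,
            "qalys_comparator": base.comparator.qalys,
            "icer": base.icer_per_qaly,
            "pct_change_vs_base": 0.0,
        }
    ]
    for spec in scenarios:
        res = run_comparison(apply_scenario(config, spec), intervention, comparator)
        ic = res.icer_per_qaly
        pct = (
            100.0 * (ic / base_icer - 1.0)
            if isinstance(ic, float) and np.isfinite(base_icer)
            else np.nan
        )
        rows.append(
            {
                "scenario": spec.name,
                "cost_intervention": res.intervention.total_cost,
                "cost_comparator": res.comparator.total_cost,
                "qalys_intervention": res.intervention.qalys,
                "qalys_comparator": res.comparator.qalys,
                "icer": ic,
                "pct_change_vs_base": pct,
            }
        )
    return pd.DataFrame(rows)
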