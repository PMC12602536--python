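"""Utility and cost rewards.

Baseline (complication-free) utility comes from a published cubic-in-BMI
regression with demographic covariates.  Evaluated at the cohort's own
baseline means the regression does not reproduce the separately published
cohort utility of 0.78, so two modes are offered: ``regression`` evaluates
the polynomial directly, while ``anchored`` (default) pins model-entry
utility to the published 0.78 and uses the regression only for the per-cycle
*difference* as BMI and age evolve.  Comorbidity disutilities are additive
and persistent; acute-event disutilities are one-time decrements in the
cycle of occurrence.

Costs comprise drug acquisition (packs dispensed through the titration
calendar, payer share applied), consumables and monitoring, annual
health-state costs, and one-time acute-event costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CohortProfile, CostInputs, ModelConfig, UtilityInputs
from .markov import CycleRewards, EventRule, StateSpace
from .trajectory import WEEKS_PER_YEAR, BMIPath, CycleGrid

__all__ = [
    "DrugSchedule",
    "baseline_utility",
    "state_utility",
    "event_qaly_and_cost",
    "build_drug_schedule",
    "drug_cost_cycle",
    "state_cost_cycle",
    "acs_event_unit_cost",
    "build_rewards",
]


def baseline_utility(
    coeffs: dict[str, float],
    age: float,
    bmi: float,
    heart_circ: float = 0.0,
    hypertension: float = 0.0,
    smoke_current: float = 0.0,
    smoke_previous: float = 0.0,
    prediabetes: float = 0.0,
    clamp: bool = True,
) -> float:
    """Complication-free utility from the published regression.

    Covariate indicators may be cohort prevalence fractions.  The raw
    polynomial can stray outside [0, 1] at extreme inputs; by contract the
    returned utility is clamped (disable with ``clamp=False`` for diagnostic
    use).
    """
    if bmi <= 0:
        raise ValueError("bmi must be > 0")
    u = (
        coeffs["intercept"]
        + coeffs["age"] * age
        + coeffs["heart_circ"] * heart_circ
        + coeffs["hypertension"] * hypertension
        + coeffs["smoke_current"] * smoke_current
        + coeffs["smoke_previous"] * smoke_previous
        + coeffs["bmi"] * bmi
        + coeffs["bmi2"] * bmi**2
        + coeffs["bmi3"] * bmi**3
        + coeffs["prediabetes"] * prediabetes
    )
    return float(min(1.0, max(0.0, u))) if clamp else float(u)


def state_utility(
    base: float, conditions: tuple[str, ...] | frozenset[str], utility: UtilityInputs
) -> float:
    """Baseline utility plus additive condition disutilities, clamped to [0, 1]."""
    u = base
    for c in conditions:
        if c not in utility.state_disutilities:
            raise KeyError(f"unknown condition '{c}' in state-utility lookup")
        u += utility.state_disutilities[c].mean
    return float(min(1.0, max(0.0, u)))


def event_qaly_and_cost(
    events: dict[str, float],
    utility: UtilityInputs,
    event_costs: dict[str, tuple[float, float]],
    fatal_fractions: dict[str, float] | None = None,
) -> tuple[float, float]:
    """One-time QALY decrement and cost of a bundle of acute events.

    ``events`` maps event label -> expected count; ``event_costs`` maps
    label -> (fatal cost, non-fatal cost) and ``fatal_fractions`` gives the
    fatal share (default 0).  Discounting is the engine's job, not ours.
    """
    fatal_fractions = fatal_fractions or {}
    dq = 0.0
    cost = 0.0
    for name, count in events.items():
        if count < 0:
            raise ValueError(f"event count for '{name}' must be >= 0")
        if name not in utility.event_disutilities:
            raise KeyError(f"unknown event '{name}'")
        dq += count * utility.event_disutilities[name].mean
        cf, cnf = event_costs.get(name, (0.0, 0.0))
        f = fatal_fractions.get(name, 0.0)
        cost += count * (f * cf + (1.0 - f) * cnf)
    return dq, cost


# ---------------------------------------------------------------------------
# drug costs


@dataclass(frozen=True)
class DrugSchedule:
    """Per-cycle expected pack counts by dose label (cohort means)."""

    packs: list[dict[str, float]]          # one dict per cycle
    payer_share: float
    prices: dict[str, float]
    consumables_per_cycle: np.ndarray      # EUR per cycle, already exposure-weighted
    consumables_payer_share: float = 1.0


def _dose_intervals(
    titration: list[tuple[str, float | None]], t_max_weeks: float
) -> list[tuple[str, float, float]]:
    """Resolve the titration ladder into [start, end) week intervals."""
    out = []
    w = 0.0
    for label, dur in titration:
        end = t_max_weeks if dur is None else min(w + dur, t_max_weeks)
        if end > w:
            out.append((label, w, end))
        w = end
        if w >= t_max_weeks:
            break
    return out


def build_drug_schedule(config: ModelConfig, arm_name: str, path: BMIPath) -> DrugSchedule:
    """Expected packs dispensed per cycle given titration and exposure.

    Pack counts are continuous cohort means: days at each dose inside the
    cycle divided by the pack coverage days, weighted by the fraction of the
    cohort on treatment during that cycle.
    """
    arm = config.arms[arm_name]
    costs = config.costs
    grid = path.grid
    t_max_w = config.max_treatment_years * WEEKS_PER_YEAR
    intervals = _dose_intervals(arm.titration_schedule, t_max_w)
    packs: list[dict[str, float]] = []
    consum = np.zeros(len(grid))
    for t in range(len(grid)):
        w0, w1 = grid.starts[t] * WEEKS_PER_YEAR, grid.ends[t] * WEEKS_PER_YEAR
        on = float(path.on_treatment[t])
        cyc: dict[str, float] = {}
        if on > 0:
            for label, a, b in intervals:
                overlap_w = max(0.0, min(b, w1) - max(a, w0))
                if overlap_w > 0:
                    days = overlap_w * 7.0
                    cyc[label] = cyc.get(label, 0.0) + on * days / costs.pack_coverage_days
            treated_years = on * max(0.0, min(t_max_w, w1) - max(0.0, w0)) / WEEKS_PER_YEAR
            consum[t] = costs.consumables_annual * treated_years
        packs.append(cyc)
    share_consum = (
        config.payer_share if config.valuation.payer_share_applies_to_consumables else 1.0
    )
    return DrugSchedule(
        packs=packs,
        payer_share=config.payer_share,
        prices=dict(costs.drug_prices),
        consumables_per_cycle=consum,
        consumables_payer_share=share_consum,
    )


def drug_cost_cycle(schedule: DrugSchedule, cycle: int) -> float:
    """Payer drug + consumable cost of one cycle: sum packs x price x share."""
    total = 0.0
    for label, n in schedule.packs[cycle].items():
        if label not in schedule.prices:
            raise KeyError(f"no price for dose label '{label}'")
        total += n * schedule.prices[label] * schedule.payer_share
    total += float(schedule.consumables_per_cycle[cycle]) * schedule.consumables_payer_share
    return total


def state_cost_cycle(
    conditions: tuple[str, ...],
    cycle_len: float,
    costs: CostInputs,
    monitoring_additive: bool = True,
) -> float:
    """Cycle cost of occupying a health state.

    Under the (default) monitoring-additive convention every alive state
    accrues the annual monitoring cost, with condition costs added on top;
    otherwise the complication-free state cost applies only to the empty
    state.
    """
    annual = costs.monitoring_annual if monitoring_additive else (
        costs.state_costs_annual["none"] if not conditions else 0.0
    )
    for c in conditions:
        if c not in costs.state_costs_annual:
            raise KeyError(f"no state cost for condition '{c}'")
        annual += costs.state_costs_annual[c]
    return cycle_len * annual


def acs_event_unit_cost(config: ModelConfig) -> float:
    """Expected acute-care cost of one incident ACS event.

    Mixes myocardial infarction and unstable angina with their fatal /
    non-fatal DRG tariffs per the valuation settings.
    """
    ev = config.costs.event_costs
    v = config.valuation
    mi = v.acs_mi_fatal_fraction * ev["mi_fatal"] + (1 - v.acs_mi_fatal_fraction) * ev["mi_nonfatal"]
    ang = (
        v.acs_angina_fatal_fraction * ev["angina_fatal"]
        + (1 - v.acs_angina_fatal_fraction) * ev["angina_nonfatal"]
    )
    return v.acs_mi_fraction * mi + (1 - v.acs_mi_fraction) * ang


# ---------------------------------------------------------------------------
# reward assembly


def build_rewards(
    config: ModelConfig,
    space: StateSpace,
    path: BMIPath,
    arm_name: str,
) -> CycleRewards:
    """Assemble per-cycle, per-state reward rates for one arm.

    Utility: baseline utility at the cycle's cohort BMI and attained age
    (anchored or raw regression mode) plus state disutilities, clamped.
    Adverse-event disutilities and costs enter as rates scaled by the
    on-treatment fraction.  Incident-ACS acute costs and disutility attach
    as one-time event rewards on entry flux.
    """
    arm = config.arms[arm_name]
    cohort = config.cohort
    utility = config.utility
    costs = config.costs
    grid: CycleGrid = path.grid
    T, n = len(grid), space.n_states
    coeffs = utility.coefficients

    def reg(age: float, bmi: float) -> float:
        return baseline_utility(
            coeffs, age, bmi,
            heart_circ=cohort.cvd_history_fraction,
            hypertension=cohort.on_antihypertensive,
            smoke_current=cohort.smoker_fraction,
            smoke_previous=cohort.smoker_previous_fraction,
            prediabetes=cohort.prediabetes_fraction,
            clamp=False,
        )

    u0 = reg(cohort.age, cohort.bmi)
    anchor = utility.baseline_utility.mean

    base_u = np.empty(T)
    for t in range(T):
        age_t = cohort.age + grid.mids[t]
        u_t = reg(age_t, float(path.bmi[t]))
        if utility.mode == "anchored":
            base_u[t] = anchor + (u_t - u0)
        else:
            base_u[t] = u_t

    # AE rates fold into per-year rates on alive states, exposure-weighted
    ae_cost_rate = path.on_treatment * (
        arm.gi_event_rate * costs.ae_costs.get("major_gi", 0.0)
        + arm.hypo_rate * costs.ae_costs.get("minor_hypoglycemia", 0.0)
    )
    ae_dutil_rate = path.on_treatment * (
        arm.gi_event_rate * utility.event_disutilities["severe_gi"].mean
        + arm.hypo_rate * utility.event_disutilities["nonsevere_hypoglycemia"].mean
    )

    util_rate = np.zeros((T, n))
    state_rate = np.zeros((T, n))
    monitor_rate = np.zeros((T, n))
    treat_rate = np.zeros((T, n))
    event_rate = np.zeros((T, n))

    alive = space.alive_mask()
    state_annual = np.zeros(n)
    for i, s in enumerate(space.states[:-1]):
        state_annual[i] = state_cost_cycle(s, 1.0, costs, config.valuation.monitoring_additive)
    monitor_annual = np.where(alive, costs.monitoring_annual, 0.0)
    if config.valuation.monitoring_additive:
        state_only = state_annual - monitor_annual
    else:
        state_only = state_annual
        monitor_annual = np.zeros(n)

    dis = np.zeros(n)
    for i, s in enumerate(space.states[:-1]):
        dis[i] = sum(utility.state_disutilities[c].mean for c in s)

    schedule = build_drug_schedule(config, arm_name, path)
    n_clamped = 0
    for t in range(T):
        raw = base_u[t] + dis
        n_clamped += int(np.sum(((raw < 0.0) | (raw > 1.0)) & alive))
        util_rate[t, :] = np.where(alive, np.clip(raw, 0.0, 1.0), 0.0)
        util_rate[t, alive] += ae_dutil_rate[t]
        state_rate[t, :] = np.where(alive, state_only, 0.0)
        monitor_rate[t, :] = monitor_annual
        # per-cycle drug spend spread over the cycle as a rate on alive mass
        treat_rate[t, alive] = drug_cost_cycle(schedule, t) / grid.lengths[t]
        event_rate[t, alive] = ae_cost_rate[t]

    acs_mask = np.zeros((n, n), dtype=bool)
    has_acs = space.condition_mask("acs")
    acs_mask[np.ix_(~has_acs, has_acs)] = True
    acs_mask[space.death_index, :] = False
    events = [
        EventRule(
            name="acs",
            mask=acs_mask,
            cost_per_event=acs_event_unit_cost(config),
            qaly_per_event=utility.event_disutilities["acs"].mean,
            cost_component="event",
        )
    ]

    return CycleRewards(
        utility_rate=util_rate,
        cost_rates={
            "treatment": treat_rate,
            "monitoring": monitor_rate,
            "state": state_rate,
            "event": event_rate,
        },
        events=events,
        meta={"n_utility_clamped": n_clamped},
    )
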