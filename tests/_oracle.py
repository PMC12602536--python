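"""Independent reference implementations used only as test oracles.

Deliberately naive: explicit Python loops, no matrix algebra, no shared code
with the package under test.
"""

from __future__ import annotations


def naive_cohort_run(
    lengths,
    matrices,
    utility_rates,
    cost_rates,
    v0,
    rate_costs=0.0,
    rate_outcomes=0.0,
):
    """Loop-based cohort accumulation with half-cycle correction and
    mid-cycle discounting.

    ``matrices[t][i][j]``: transition probability; ``utility_rates[t][i]`` and
    ``cost_rates[t][i]``: per-year reward rates; last state is absorbing death
    (life-years counted for every state except the last).

    Returns (life_years, qalys, cost), all discounted.
    """
    n = len(v0)
    v = [float(x) for x in v0]
    t_start = 0.0
    ly = qaly = cost = 0.0
    for t, length in enumerate(lengths):
        length = float(length)
        v_end = [0.0] * n
        for i in range(n):
            for j in range(n):
                v_end[j] += v[i] * float(matrices[t][i][j])
        t_mid = t_start + length / 2.0
        df_c = (1.0 + rate_costs) ** (-t_mid)
        df_o = (1.0 + rate_outcomes) ** (-t_mid)
        for i in range(n):
            mid = 0.5 * (v[i] + v_end[i])
            if i < n - 1:
                ly += length * mid * df_o
            qaly += length * float(utility_rates[t][i]) * mid * df_o
            cost += length * float(cost_rates[t][i]) * mid * df_c
        v = v_end
        t_start += length
    return ly, qaly, cost


def polynomial_utility(coeffs, age, bmi, heart, hyp, smoke_c, smoke_p, prediab):
    """Term-by-term evaluation of the baseline-utility regression (unclamped
    clamp applied at the end), written independently of the package."""
    terms = [
        coeffs["intercept"],
        coeffs["age"] * age,
        coeffs["heart_circ"] * heart,
        coeffs["hypertension"] * hyp,
        coeffs["smoke_current"] * smoke_c,
        coeffs["smoke_previous"] * smoke_p,
        coeffs["bmi"] * bmi,
        coeffs["bmi2"] * bmi * bmi,
        coeffs["bmi3"] * bmi * bmi * bmi,
        coeffs["prediabetes"] * prediab,
    ]
    u = 0.0
    for x in terms:
        u += x
    return min(1.0, max(0.0, u))


def calendar_walk_drug_cost(
    titration, prices, payer_share, pack_days, exposure_by_cycle, cycle_bounds_weeks,
    t_max_weeks,
):
    """Day-by-day dispensing oracle: walk the treatment calendar one day at a
    time, attribute each treated day's pro-rated pack cost to its cycle."""
    # resolve dose per week-of-treatment
    ladder = []
    w = 0.0
    for label, dur in titration:
        end = t_max_weeks if dur is None else min(w + dur, t_max_weeks)
        if end > w:
            ladder.append((label, w, end))
        w = end
        if w >= t_max_weeks:
            break

    def dose_at(week):
        for label, a, b in ladder:
            if a <= week < b:
                return label
        return None

    total_by_cycle = []
    for (w0, w1), on in zip(cycle_bounds_weeks, exposure_by_cycle):
        cost = 0.0
        n_days = int(round((w1 - w0) * 7))
        for d in range(n_days):
            week = w0 + d / 7.0
            label = dose_at(week)
            if label is not None and on > 0:
                cost += on * prices[label] / pack_days * payer_share
        total_by_cycle.append(cost)
    return total_by_cycle
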