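"""BMI-driven incidence and mortality machinery.

Incidence of each complication is a calibrated log-linear function of BMI
around a reference point (a pluggable stand-in for full published risk
equations such as QDiabetes or QRisk3, which operate on many covariates but
enter this cohort model only through the BMI channel), optionally scaled by
prevalence-weighted covariate multipliers.

Background mortality starts from an age/sex life table, subtracts the share
of all-cause deaths attributable to the modelled diseases (so disease
mortality is not counted twice), applies a BMI-band hazard ratio for the
residual obesity-attributable risk, and finally adds disease mortality back
state-specifically through per-condition excess-hazard multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MortalityConfig, RiskFunctionConfig

__all__ = [
    "MortalityInputs",
    "annual_incidence",
    "prob_for_cycle",
    "build_life_table",
    "build_mortality_inputs",
    "bmi_hazard_ratio",
    "residual_mortality",
    "state_excess_mortality",
]


@dataclass(frozen=True)
class MortalityInputs:
    """Resolved mortality inputs: life table plus adjustment parameters."""

    ages: np.ndarray                       # integer ages covered
    q_female: np.ndarray                   # annual all-cause death probability
    q_male: np.ndarray
    cause_fraction_total: float            # sum over modelled diseases
    bmi_hr_bands: tuple[tuple[float, float, float], ...]
    bmi_hr_enabled: bool
    state_excess_multipliers: dict[str, float]


def annual_incidence(
    rf: RiskFunctionConfig, bmi: float, covariates: dict[str, float] | None = None
) -> float:
    """Annual probability of acquiring ``rf.condition`` at the given BMI.

    log-linear kind: ``base * exp(log_rr * (bmi - ref)) * prod(multipliers)``,
    capped at 1.  Covariate values may be cohort prevalence fractions ``f``;
    a multiplier ``m`` then contributes ``1 - f + f*m``.  Rate-table kind
    looks the BMI band up directly (keys ``"lo-hi"``).
    """
    if bmi <= 0:
        raise ValueError("bmi must be > 0")
    covariates = covariates or {}
    unknown = sorted(set(covariates) - set(rf.covariate_multipliers))
    if unknown:
        raise KeyError(f"risk '{rf.condition}': unknown covariate(s) {unknown}")
    if rf.kind == "rate-table":
        for key, rate in rf.rate_table.items():
            lo, hi = (float(x) for x in key.split("-"))
            if lo <= bmi < hi:
                return min(1.0, rate)
        raise KeyError(f"risk '{rf.condition}': no rate-table band covers BMI {bmi}")
    p = rf.base_annual_rate * float(np.exp(rf.log_rr_per_bmi_unit * (bmi - rf.reference_bmi)))
    for name, m in rf.covariate_multipliers.items():
        f = float(covariates.get(name, 0.0))
        p *= 1.0 - f + f * m
    return min(1.0, p)


def prob_for_cycle(annual_p: float, cycle_len: float) -> float:
    """Convert an annual probability to a cycle-length probability.

    Constant-hazard conversion ``1 - (1 - p)^len``; compounds exactly back to
    the annual probability over sub-annual cycles.
    """
    if not 0.0 <= annual_p <= 1.0:
        raise ValueError("annual probability must be in [0, 1]")
    if cycle_len <= 0:
        raise ValueError("cycle length must be > 0")
    return 1.0 - (1.0 - annual_p) ** cycle_len


def build_life_table(cfg: MortalityConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gompertz–Makeham annual death probabilities per integer age and sex."""
    p = cfg.gompertz_makeham
    ages = np.arange(cfg.age_min, cfg.age_max + 1)
    mu_f = p["a"] + p["b_female"] * np.exp(p["c"] * ages)
    mu_m = p["a"] + p["b_male"] * np.exp(p["c"] * ages)
    return ages, 1.0 - np.exp(-mu_f), 1.0 - np.exp(-mu_m)


def build_mortality_inputs(cfg: MortalityConfig) -> MortalityInputs:
    ages, qf, qm = build_life_table(cfg)
    return MortalityInputs(
        ages=ages,
        q_female=qf,
        q_male=qm,
        cause_fraction_total=float(sum(cfg.cause_fractions.values())),
        bmi_hr_bands=tuple(tuple(b) for b in cfg.bmi_hr_bands),
        bmi_hr_enabled=cfg.bmi_hr_enabled,
        state_excess_multipliers=dict(cfg.state_excess_multipliers),
    )


def bmi_hazard_ratio(m: MortalityInputs, bmi: float) -> float:
    if not m.bmi_hr_enabled:
        return 1.0
    for lo, hi, hr in m.bmi_hr_bands:
        if lo <= bmi < hi:
            return hr
    raise KeyError(f"no BMI hazard-ratio band covers BMI {bmi}")


def residual_mortality(
    m: MortalityInputs, age: float, female_fraction: float, bmi: float
) -> float:
    """Annual background death probability net of modelled-disease deaths.

    ``q_all(age, sex mix) * (1 - sum cause fractions) * HR(BMI band)``,
    capped at 1.  ``female_fraction`` may be 0/1 for a single-sex cohort or
    the cohort mix.  Ages outside the life table raise (no extrapolation).
    """
    idx = int(np.floor(age)) - int(m.ages[0])
    if idx < 0 or idx >= len(m.ages):
        raise ValueError(f"age {age} outside the life table range "
                         f"[{m.ages[0]}, {m.ages[-1]}]")
    q_all = female_fraction * m.q_female[idx] + (1.0 - female_fraction) * m.q_male[idx]
    q = q_all * (1.0 - m.cause_fraction_total) * bmi_hazard_ratio(m, bmi)
    return min(1.0, q)


def state_excess_mortality(
    residual_annual: float,
    m: MortalityInputs,
    conditions: tuple[str, ...] | frozenset[str],
    cycle_len: float,
) -> float:
    """Cycle death probability for a state carrying the given conditions.

    Per-condition excess-mortality multipliers compose on the hazard scale:
    ``1 - (1 - q_residual)^(prod(multipliers) * cycle_len)``.  The empty set
    returns residual mortality converted to cycle length.
    """
    mult = 1.0
    for c in conditions:
        mult *= m.state_excess_multipliers.get(c, 1.0)
    if residual_annual >= 1.0:
        return 1.0
    return 1.0 - (1.0 - residual_annual) ** (mult * cycle_len)
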