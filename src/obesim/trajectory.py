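"""Per-cycle BMI/weight trajectories for each treatment pathway.

The cohort BMI path is a mixture over pathways:

* **responders** (fraction ``1 - non_responder_rate``) follow the arm's
  percent-weight-change timeline while on treatment, stop at the maximum
  treatment duration (or earlier via an adverse-event discontinuation
  hazard), then *catch up* linearly toward the post-discontinuation
  counterfactual (the diet-and-exercise trajectory by default) over
  ``catch_up_years``;
* **non-responders** (those failing to lose >= 5% of baseline weight by the
  12-week assessment) switch to the diet-and-exercise timeline at the end of
  the cycle containing the assessment week, with no separate catch-up;
* once a pathway has rejoined the untreated trajectory it follows **natural
  progression**: weight gain at 0.47 kg/year applied to BMI via height^2.

All pathways therefore coincide with the no-treatment path in the long run;
treatment moves costs and risks only transiently, which is the engine of the
whole cost-effectiveness question.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import CohortProfile, ModelConfig, TreatmentArmConfig

__all__ = [
    "WEEKS_PER_YEAR",
    "CycleGrid",
    "BMIPath",
    "classify_response",
    "on_treatment_bmi",
    "catch_up_bmi",
    "natural_progression",
    "build_cohort_bmi_path",
]

WEEKS_PER_YEAR = 365.25 / 7.0


@dataclass(frozen=True)
class CycleGrid:
    """Cycle calendar derived from the config's cycle schedule (years)."""

    lengths: np.ndarray
    starts: np.ndarray
    mids: np.ndarray
    ends: np.ndarray

    @classmethod
    def from_schedule(cls, schedule: list[float]) -> "CycleGrid":
        lengths = np.asarray(schedule, dtype=float)
        ends = np.cumsum(lengths)
        starts = ends - lengths
        return cls(lengths=lengths, starts=starts, mids=starts + lengths / 2, ends=ends)

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class BMIPath:
    """Pathway-resolved cohort BMI trajectory sampled at cycle midpoints."""

    grid: CycleGrid
    bmi: np.ndarray                    # (T,) cohort-mean BMI, kg/m2
    weight: np.ndarray                 # (T,) cohort-mean weight, kg
    pathway_bmi: dict[str, np.ndarray]
    pathway_weights: dict[str, float]
    on_treatment: np.ndarray           # (T,) fraction of the cohort on drug

    def __post_init__(self):
        if np.any(self.bmi <= 10) or np.any(self.bmi >= 100):
            raise ValueError("BMI path left the plausible range (10, 100)")
        total = sum(self.pathway_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pathway weights sum to {total}, not 1")


def classify_response(weight_change_12w: float, threshold: float = 0.05) -> bool:
    """Responder iff weight loss at the assessment week is >= the threshold.

    ``weight_change_12w`` is a signed fraction of baseline weight (loss
    negative); exactly -5.0% counts as response.
    """
    return weight_change_12w <= -threshold


def _interp_timeline(
    timeline: list[tuple[float, float]], week: float | np.ndarray, scale: float = 1.0
) -> float | np.ndarray:
    if not timeline:
        raise ValueError("efficacy timeline is empty")
    weeks = np.asarray([w for w, _ in timeline], dtype=float)
    changes = np.asarray([c for _, c in timeline], dtype=float) * scale
    return np.interp(week, weeks, changes)  # plateau beyond last anchor


def on_treatment_bmi(
    arm: TreatmentArmConfig, baseline_bmi: float, week: float | np.ndarray
) -> float | np.ndarray:
    """BMI while on treatment: baseline x (1 + interpolated %-change).

    Linear interpolation between anchor weeks; plateau at the last anchor.
    """
    return baseline_bmi * (1.0 + _interp_timeline(arm.efficacy_timeline, week, arm.efficacy_scale))


def catch_up_bmi(
    bmi_at_stop: float,
    counterfactual_bmi: float,
    years_since_stop: float,
    catch_up_years: float,
) -> float:
    """Linear fade of the residual treatment effect after discontinuation.

    ``counterfactual_bmi`` is the value of the post-discontinuation reference
    trajectory at the evaluation time; after ``catch_up_years`` the returned
    value equals it exactly.
    """
    if years_since_stop < 0:
        raise ValueError("years_since_stop must be >= 0")
    if catch_up_years <= 0:
        raise ValueError("catch_up_years must be > 0")
    w = min(1.0, years_since_stop / catch_up_years)
    return bmi_at_stop + (counterfactual_bmi - bmi_at_stop) * w


def natural_progression(
    bmi: float | np.ndarray,
    years: float | np.ndarray,
    weight_gain_rate: float,
    height: float,
    units: str = "kg_per_year",
) -> float | np.ndarray:
    """Background drift of untreated BMI.

    ``units='kg_per_year'`` (default) interprets the rate as weight gain and
    converts through height^2; ``'bmi_per_year'`` applies it to BMI directly.
    """
    if height <= 0:
        raise ValueError("height must be > 0")
    if units == "kg_per_year":
        rate = weight_gain_rate / height**2
    elif units == "bmi_per_year":
        rate = weight_gain_rate
    else:
        raise ValueError(f"unknown weight-gain units: {units!r}")
    return bmi + rate * years


# ---------------------------------------------------------------------------
# pathway composition


def _stop_time_mixture(
    config: ModelConfig, arm: TreatmentArmConfig, grid: CycleGrid
) -> list[tuple[float, float]]:
    """(stop_time, weight) sub-cohorts of responders.

    Adverse-event discontinuation acts as an annual hazard during active
    treatment, resolved at cycle boundaries; survivors stop at the maximum
    treatment duration.
    """
    t_max = config.max_treatment_years
    r = arm.ae_discontinuation_rate
    if t_max <= 0:
        return [(0.0, 1.0)]
    if r <= 0:
        return [(t_max, 1.0)]
    boundaries = [float(e) for e in grid.ends if e < t_max - 1e-12]
    surv = lambda t: (1.0 - r) ** t
    cohorts: list[tuple[float, float]] = []
    prev = 0.0
    for b in boundaries:
        cohorts.append((b, surv(prev) - surv(b)))
        prev = b
    cohorts.append((t_max, surv(prev)))
    return [(t, w) for t, w in cohorts if w > 0]


def _assessment_time(config: ModelConfig, grid: CycleGrid) -> float:
    """End of the cycle containing the stopping-rule week.

    Aligns the 12-week response assessment with the quarterly cycle grid
    (week 12 -> end of cycle 1 at ~week 13).
    """
    t_rule = config.stopping_rule_week / WEEKS_PER_YEAR
    for e in grid.ends:
        if e >= t_rule - 1e-12:
            return float(e)
    return float(grid.ends[-1])


def build_cohort_bmi_path(
    config: ModelConfig,
    cohort: CohortProfile,
    arm: TreatmentArmConfig,
) -> BMIPath:
    """Compose the pathway-weighted per-cycle BMI path for one arm."""
    grid = CycleGrid.from_schedule(config.cycle_schedule)
    bmi0, height = cohort.bmi, cohort.height

    def natural_path(t: np.ndarray) -> np.ndarray:
        return natural_progression(
            bmi0, t, config.natural_weight_gain, height, config.weight_gain_units
        )

    de_arm = config.arms.get("diet_exercise")

    def untreated_path(a: TreatmentArmConfig, t: np.ndarray) -> np.ndarray:
        """Lifestyle-only trajectory: own timeline, then fade to natural drift."""
        t = np.asarray(t, dtype=float)
        t_end = a.efficacy_timeline[-1][0] / WEEKS_PER_YEAR
        on = on_treatment_bmi(a, bmi0, np.minimum(t, t_end) * WEEKS_PER_YEAR)
        val_end = float(on_treatment_bmi(a, bmi0, t_end * WEEKS_PER_YEAR))
        fade = np.clip((t - t_end) / config.catch_up_years, 0.0, 1.0)
        return np.where(t <= t_end, on, val_end + (natural_path(t) - val_end) * fade)

    def diet_exercise_path(t: np.ndarray) -> np.ndarray:
        if de_arm is None:
            return natural_path(t)
        return untreated_path(de_arm, t)

    reference_path: Callable[[np.ndarray], np.ndarray]
    if config.post_discontinuation == "natural":
        reference_path = natural_path
    else:
        reference_path = diet_exercise_path

    t = grid.mids
    if not arm.titration_schedule:
        # untreated comparator pathway: nothing to stop or catch up from
        bmi = untreated_path(arm, t)
        return BMIPath(
            grid=grid,
            bmi=bmi,
            weight=bmi * height**2,
            pathway_bmi={"responder": bmi, "non_responder": bmi},
            pathway_weights={"responder": 1.0, "non_responder": 0.0},
            on_treatment=np.zeros_like(t),
        )
    stop_cohorts = _stop_time_mixture(config, arm, grid)

    def on_path(t_arr, eff_frac: float = 1.0):
        return bmi0 * (
            1.0
            + eff_frac
            * _interp_timeline(arm.efficacy_timeline, np.asarray(t_arr) * WEEKS_PER_YEAR,
                               arm.efficacy_scale)
        )

    def stopped_path(t_arr: np.ndarray, t_stop: float, eff_frac: float = 1.0) -> np.ndarray:
        on = on_path(np.minimum(t_arr, t_stop), eff_frac)
        b_stop = float(on_path(t_stop, eff_frac))
        fade = np.clip((t_arr - t_stop) / config.catch_up_years, 0.0, 1.0)
        ref = reference_path(t_arr)
        return np.where(t_arr <= t_stop, on, b_stop + (ref - b_stop) * fade)

    responder = np.zeros_like(t)
    for t_stop, w in stop_cohorts:
        responder += w * stopped_path(t, t_stop)

    t_assess = _assessment_time(config, grid)
    rule_active = config.stopping_rule_enabled and arm.apply_stopping_rule
    nr_rate = arm.non_responder_rate
    f_nr = arm.non_responder_efficacy_fraction

    if rule_active:
        # sub-threshold effect until the assessment, then diet-and-exercise
        # (or a fade toward natural drift when that benefit is removed)
        if config.post_discontinuation == "natural":
            b12 = float(on_path(t_assess, f_nr))
            fade = np.clip((t - t_assess) / config.catch_up_years, 0.0, 1.0)
            non_responder = np.where(
                t <= t_assess, on_path(t, f_nr), b12 + (natural_path(t) - b12) * fade
            )
        else:
            non_responder = np.where(t <= t_assess, on_path(t, f_nr), diet_exercise_path(t))
    else:
        # non-responders stay on treatment to the maximum duration with their
        # sub-threshold effect, then catch up like responders
        non_responder = np.zeros_like(t)
        for t_stop, w in stop_cohorts:
            non_responder += w * stopped_path(t, t_stop, f_nr)

    weights = {"responder": 1.0 - nr_rate, "non_responder": nr_rate}
    cohort_bmi = weights["responder"] * responder + weights["non_responder"] * non_responder

    # fraction of the cohort exposed to drug at each cycle midpoint
    r = arm.ae_discontinuation_rate
    surv = (1.0 - r) ** np.minimum(t, config.max_treatment_years)
    resp_on = np.where(t < config.max_treatment_years, surv, 0.0)
    nr_on = np.where(t < t_assess, 1.0, 0.0) if rule_active else resp_on
    on_treatment = weights["responder"] * resp_on + weights["non_responder"] * nr_on

    return BMIPath(
        grid=grid,
        bmi=cohort_bmi,
        weight=cohort_bmi * height**2,
        pathway_bmi={"responder": responder, "non_responder": non_responder},
        pathway_weights=weights,
        on_treatment=on_treatment,
    )
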