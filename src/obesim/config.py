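"""Configuration layer: every number the model uses enters through here.

A model run is fully described by a :class:`ModelConfig`.  The packaged base
case (``data/base_case.yaml``) carries the published Greek-payer inputs —
cohort profile, 2025 EUR cost tables, the baseline-utility regression and the
disutility table — each with a provenance tag.  Sections that were only
published in unavailable supplementary material (arm efficacy timelines, risk
calibrations, mortality inputs) are filled in at load time from
:mod:`obesim.fixtures` and tagged ``[FIXTURE]``.

Scenario files override parameters by dotted path (``max_treatment_years``,
``arms.semaglutide.efficacy_scale``, ...) and never mutate the base config.
"""

from __future__ import annotations

import copy
import math
from importlib import resources
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import fixtures as _fixtures

__all__ = [
    "CohortProfile",
    "CostInputs",
    "ValueWithSE",
    "UtilityInputs",
    "TreatmentArmConfig",
    "RiskFunctionConfig",
    "MortalityConfig",
    "ValuationSettings",
    "ModelConfig",
    "ScenarioSpec",
    "ConfigError",
    "load_config",
    "base_case_path",
    "load_base_case",
    "load_packaged_scenarios",
    "apply_scenario",
    "apply_overrides",
    "inflate_cost",
    "to_yaml",
    "provenance_table",
]

CONDITIONS = _fixtures.CONDITIONS


class ConfigError(ValueError):
    """Raised for schema violations and unresolvable override paths."""


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CohortProfile(_Frozen):
    """Baseline cohort characteristics (means / prevalence fractions)."""

    age: float = 48.6
    bmi: float = 41.5
    height: float = 1.70
    female_fraction: float = 0.736
    sbp: float = 128.4
    tchol: float = 186.0
    hdl: float = 50.9
    trig: float = 128.2
    smoker_fraction: float = 0.452
    smoker_previous_fraction: float = 0.0
    prediabetes_fraction: float = 0.488
    t2d_fraction: float = 0.108
    normoglycemic_fraction: float = 0.404
    cvd_history_fraction: float = 0.05
    on_lipid_lowering: float = 0.314
    on_antihypertensive: float = 0.447
    hba1c_t2d: float = 0.075
    t2d_duration: float = 6.0

    @model_validator(mode="after")
    def _check(self) -> "CohortProfile":
        if self.bmi <= 0 or self.height <= 0:
            raise ConfigError("cohort bmi and height must be positive")
        total = self.normoglycemic_fraction + self.prediabetes_fraction + self.t2d_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"glycaemic-status fractions must sum to 1 (got {total:.6f})"
            )
        for name in (
            "female_fraction", "smoker_fraction", "smoker_previous_fraction",
            "prediabetes_fraction", "t2d_fraction", "normoglycemic_fraction",
            "cvd_history_fraction", "on_lipid_lowering", "on_antihypertensive",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"cohort.{name} must be in [0, 1], got {v}")
        return self


class CostInputs(_Frozen):
    """All unit costs, expressed in euros of ``cpi_reference_year``."""

    drug_prices: dict[str, float]
    pack_coverage_days: float = 7.0
    consumables_annual: float = 33.58
    monitoring_annual: float = 124.88
    state_costs_annual: dict[str, float]
    event_costs: dict[str, float]
    ae_costs: dict[str, float]
    cpi_reference_year: int = 2025

    @model_validator(mode="after")
    def _check(self) -> "CostInputs":
        for table in (self.drug_prices, self.state_costs_annual, self.event_costs, self.ae_costs):
            for k, v in table.items():
                if v < 0:
                    raise ConfigError(f"cost '{k}' must be >= 0, got {v}")
        for name in ("consumables_annual", "monitoring_annual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"cost '{name}' must be >= 0")
        missing = [c for c in CONDITIONS if c not in self.state_costs_annual]
        if missing:
            raise ConfigError(f"state_costs_annual missing conditions: {missing}")
        if self.pack_coverage_days <= 0:
            raise ConfigError("pack_coverage_days must be positive")
        return self


class ValueWithSE(_Frozen):
    mean: float
    se: float

    @model_validator(mode="after")
    def _check(self) -> "ValueWithSE":
        if self.se < 0:
            raise ConfigError("standard error must be >= 0")
        return self


class UtilityInputs(_Frozen):
    """Baseline-utility regression coefficients plus additive disutilities.

    ``mode='anchored'`` pins the baseline (complication-free, model-entry)
    utility to ``baseline_utility.mean`` and lets the regression drive only
    the per-cycle BMI/age *changes*; ``mode='regression'`` evaluates the
    polynomial directly.
    """

    coefficients: dict[str, float]
    baseline_utility: ValueWithSE = ValueWithSE(mean=0.78, se=0.023)
    mode: Literal["anchored", "regression"] = "anchored"
    state_disutilities: dict[str, ValueWithSE]
    event_disutilities: dict[str, ValueWithSE]

    @model_validator(mode="after")
    def _check(self) -> "UtilityInputs":
        required = {
            "intercept", "age", "heart_circ", "hypertension", "smoke_current",
            "smoke_previous", "bmi", "bmi2", "bmi3", "prediabetes",
        }
        missing = required - set(self.coefficients)
        if missing:
            raise ConfigError(f"utility coefficients missing: {sorted(missing)}")
        missing = set(CONDITIONS) - set(self.state_disutilities)
        if missing:
            raise ConfigError(f"state_disutilities missing conditions: {sorted(missing)}")
        for k, v in {**self.state_disutilities, **self.event_disutilities}.items():
            if v.mean > 0:
                raise ConfigError(f"disutility '{k}' must be <= 0, got {v.mean}")
        return self


class TreatmentArmConfig(_Frozen):
    """One pathway's efficacy/safety inputs.

    The efficacy timeline is a list of ``[week, fractional weight change]``
    anchors (loss negative, starting at ``[0, 0]``); ``efficacy_scale``
    multiplies every anchor and is the handle scenario and PSA machinery use
    to perturb effect size without changing the trajectory shape.
    """

    name: str
    efficacy_timeline: list[tuple[float, float]]
    non_responder_rate: float = 0.0
    ae_discontinuation_rate: float = 0.0
    gi_event_rate: float = 0.0
    hypo_rate: float = 0.0
    titration_schedule: list[tuple[str, float | None]] = Field(default_factory=list)
    efficacy_scale: float = 1.0
    #: the 12-week non-responder rule applies to this arm (scenario machinery
    #: can keep one arm's non-responders on treatment)
    apply_stopping_rule: bool = True
    #: fraction of the arm-mean percent-weight-change that non-responders
    #: achieve while on treatment (their loss is sub-threshold by definition)
    non_responder_efficacy_fraction: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "TreatmentArmConfig":
        tl = self.efficacy_timeline
        if not tl:
            raise ConfigError(f"arm '{self.name}': efficacy timeline is empty")
        weeks = [w for w, _ in tl]
        if weeks[0] != 0 or tl[0][1] != 0:
            raise ConfigError(f"arm '{self.name}': timeline must start at (0, 0)")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigError(f"arm '{self.name}': timeline weeks must be strictly increasing")
        for rname in ("non_responder_rate", "ae_discontinuation_rate"):
            v = getattr(self, rname)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"arm '{self.name}': {rname} must be in [0, 1]")
        if self.gi_event_rate < 0 or self.hypo_rate < 0:
            raise ConfigError(f"arm '{self.name}': event rates must be >= 0")
        if self.efficacy_scale < 0:
            raise ConfigError(f"arm '{self.name}': efficacy_scale must be >= 0")
        if not 0.0 <= self.non_responder_efficacy_fraction <= 1.0:
            raise ConfigError(
                f"arm '{self.name}': non_responder_efficacy_fraction must be in [0, 1]"
            )
        maint = [w for _, w in self.titration_schedule if w is None]
        if self.titration_schedule and len(maint) != 1:
            raise ConfigError(
                f"arm '{self.name}': exactly one maintenance (open-ended) titration step required"
            )
        return self


class RiskFunctionConfig(_Frozen):
    """Calibrated BMI -> annual incidence mapping for one complication."""

    condition: str
    kind: Literal["loglinear-BMI", "rate-table"] = "loglinear-BMI"
    base_annual_rate: float = 0.0
    reference_bmi: float = 41.5
    log_rr_per_bmi_unit: float = 0.0
    covariate_multipliers: dict[str, float] = Field(default_factory=dict)
    rate_table: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "RiskFunctionConfig":
        if not 0.0 <= self.base_annual_rate < 1.0:
            raise ConfigError(f"risk '{self.condition}': base_annual_rate must be in [0, 1)")
        if any(m <= 0 for m in self.covariate_multipliers.values()):
            raise ConfigError(f"risk '{self.condition}': multipliers must be > 0")
        return self


class MortalityConfig(_Frozen):
    gompertz_makeham: dict[str, float]
    age_min: int = 18
    age_max: int = 110
    cause_fractions: dict[str, float]
    bmi_hr_bands: list[tuple[float, float, float]]
    bmi_hr_enabled: bool = True
    state_excess_multipliers: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "MortalityConfig":
        if sum(self.cause_fractions.values()) >= 1.0:
            raise ConfigError("cause fractions must sum to < 1")
        if any(f < 0 for f in self.cause_fractions.values()):
            raise ConfigError("cause fractions must be >= 0")
        if any(hr <= 0 for _, _, hr in self.bmi_hr_bands):
            raise ConfigError("BMI hazard ratios must be > 0")
        if any(m <= 0 for m in self.state_excess_multipliers.values()):
            raise ConfigError("state excess-mortality multipliers must be > 0")
        return self


class ValuationSettings(_Frozen):
    """Conventions for mapping states/events to rewards."""

    #: monitoring cost added to every alive state (True) or only to the
    #: complication-free state (False).
    monitoring_additive: bool = True
    #: composition of an incident ACS event into MI vs unstable angina and
    #: the fatal/non-fatal cost split.
    acs_mi_fraction: float = 0.7
    acs_mi_fatal_fraction: float = 0.12
    acs_angina_fatal_fraction: float = 0.04
    #: co-payment applies to drug acquisition only; consumables/monitoring are
    #: reimbursed in full.
    payer_share_applies_to_consumables: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ValuationSettings":
        for f in ("acs_mi_fraction", "acs_mi_fatal_fraction", "acs_angina_fatal_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ConfigError(f"valuation.{f} must be in [0, 1]")
        return self


class ModelConfig(_Frozen):
    """Full parameter set for one model run."""

    horizon_years: float = 40.0
    cycle_schedule: list[float] = Field(default_factory=lambda: [0.25] * 4 + [1.0] * 39)
    discount_rate_costs: float = 0.035
    discount_rate_outcomes: float = 0.035
    wtp_thresholds: list[float] = Field(default_factory=lambda: [27117.0, 30000.0, 34000.0])
    max_treatment_years: float = 2.0
    stopping_rule_week: float = 12.0
    stopping_rule_threshold: float = 0.05
    stopping_rule_enabled: bool = True
    catch_up_years: float = 3.0
    natural_weight_gain: float = 0.47
    weight_gain_units: Literal["kg_per_year", "bmi_per_year"] = "kg_per_year"
    post_discontinuation: Literal["diet_exercise", "natural"] = "diet_exercise"
    payer_share: float = 0.75
    joint_acquisition: bool = False
    discount_timing: Literal["mid", "start"] = "mid"
    seed: int = 0

    cohort: CohortProfile = CohortProfile()
    costs: CostInputs | None = None
    utility: UtilityInputs | None = None
    valuation: ValuationSettings = ValuationSettings()
    arms: dict[str, TreatmentArmConfig] = Field(default_factory=dict)
    risk_functions: list[RiskFunctionConfig] = Field(default_factory=list)
    mortality: MortalityConfig | None = None

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if any(c <= 0 for c in self.cycle_schedule):
            raise ConfigError("cycle lengths must be > 0")
        total = sum(self.cycle_schedule)
        if abs(total - self.horizon_years) > 1e-9:
            raise ConfigError(
                f"cycle schedule sums to {total}, not horizon_years={self.horizon_years}"
            )
        for name in ("discount_rate_costs", "discount_rate_outcomes",
                     "stopping_rule_threshold", "payer_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if any(t <= 0 for t in self.wtp_thresholds):
            raise ConfigError("WTP thresholds must be > 0")
        if self.catch_up_years <= 0:
            raise ConfigError("catch_up_years must be > 0")
        if self.max_treatment_years < 0:
            raise ConfigError("max_treatment_years must be >= 0")
        return self


class ScenarioSpec(_Frozen):
    """Named set of dotted-path overrides applied on top of a base config."""

    name: str
    description: str = ""
    overrides: dict[str, Any] = Field(default_factory=dict)


# ---------------------------------------------------------------------------
# loading / serialisation


def _data_dir():
    return resources.files("obesim") / "data"


def base_case_path() -> Path:
    """Path of the packaged base-case configuration file."""
    return Path(str(_data_dir() / "base_case.yaml"))


def _merge_fixture_sections(raw: dict[str, Any], prov: dict[str, str]) -> None:
    fx = _fixtures.make_default_fixtures(seed=int(raw.get("seed", 0)))
    if "arms" not in raw or not raw["arms"]:
        raw["arms"] = fx.arms
    if "risk_functions" not in raw or not raw["risk_functions"]:
        raw["risk_functions"] = fx.risk_functions
    if "mortality" not in raw or raw["mortality"] is None:
        raw["mortality"] = fx.mortality
    for key, tag in fx.provenance.items():
        prov.setdefault(key, tag)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a configuration file.

    Missing optional sections take base-case defaults; the supplementary-only
    sections (arms, risk functions, mortality) are inflated from the synthetic
    fixture set when absent.  Raises :class:`ConfigError` naming the offending
    field on any schema violation.
    """
    cfg, _ = _load_with_provenance(Path(path))
    return cfg


def _load_with_provenance(path: Path) -> tuple[ModelConfig, dict[str, str]]:
    if not Path(path).exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    prov = raw.pop("provenance", {}) or {}
    _merge_fixture_sections(raw, prov)
    try:
        cfg = ModelConfig(**raw)
    except ConfigError:
        raise
    except Exception as exc:  # pydantic ValidationError -> uniform error type
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    _check_provenance_coverage(cfg, prov)
    return cfg, prov


def load_base_case() -> ModelConfig:
    """The packaged Greek-payer base case, fixture-completed and validated."""
    return load_config(base_case_path())


def load_packaged_scenarios() -> list[ScenarioSpec]:
    """The packaged scenario battery, in published row order."""
    sdir = _data_dir() / "scenarios"
    specs = []
    for f in sorted(sdir.iterdir()):
        if f.name.endswith(".yaml"):
            with resources.as_file(f) as p, open(p, "r", encoding="utf-8") as fh:
                specs.append(ScenarioSpec(**yaml.safe_load(fh)))
    return specs


def to_yaml(config: ModelConfig) -> str:
    """Serialise a resolved config; parses back to an equal config."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)


# ---------------------------------------------------------------------------
# overrides / scenarios


def _set_by_path(d: dict[str, Any], dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = d
    for p in parts[:-1]:
        if isinstance(node, list):
            try:
                node = node[int(p)]
            except (ValueError, IndexError):
                raise ConfigError(f"override path not found: '{dotted}' (at '{p}')")
            continue
        if not isinstance(node, dict) or p not in node:
            raise ConfigError(f"override path not found: '{dotted}' (at '{p}')")
        node = node[p]
    leaf = parts[-1]
    if isinstance(node, list):
        try:
            node[int(leaf)] = value
        except (ValueError, IndexError):
            raise ConfigError(f"override path not found: '{dotted}' (at '{leaf}')")
        return
    if not isinstance(node, dict) or leaf not in node:
        raise ConfigError(f"override path not found: '{dotted}' (at '{leaf}')")
    node[leaf] = value


def apply_overrides(config: ModelConfig, overrides: dict[str, Any]) -> ModelConfig:
    """Return a new config with dotted-path overrides applied; base untouched."""
    d = config.model_dump()
    for path, value in overrides.items():
        _set_by_path(d, path, copy.deepcopy(value))
    try:
        return ModelConfig(**d)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"overrides produced an invalid config: {exc}") from exc


def apply_scenario(config: ModelConfig, spec: ScenarioSpec) -> ModelConfig:
    return apply_overrides(config, spec.overrides)


# ---------------------------------------------------------------------------
# small utilities


def inflate_cost(cost: float, cpi_source: float, cpi_target: float) -> float:
    """CPI adjustment of a historical cost: ``cost * cpi_target / cpi_source``."""
    if cpi_source <= 0 or cpi_target <= 0:
        raise ConfigError("CPI indices must be > 0")
    return cost * cpi_target / cpi_source


# ---------------------------------------------------------------------------
# provenance


def _numeric_leaves(obj: Any, prefix: str = "") -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    if isinstance(obj, bool):
        return out
    if isinstance(obj, (int, float)):
        if not (isinstance(obj, float) and math.isnan(obj)):
            out.append((prefix, float(obj)))
        return out
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.extend(_numeric_leaves(v, f"{prefix}.{k}" if prefix else str(k)))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            out.extend(_numeric_leaves(v, f"{prefix}.{i}" if prefix else str(i)))
    return out


def _tag_for(path: str, prov: dict[str, str]) -> str | None:
    # longest-prefix match on dotted paths
    parts = path.split(".")
    for i in range(len(parts), 0, -1):
        key = ".".join(parts[:i])
        if key in prov:
            return prov[key]
    return prov.get("")  # optional catch-all tag


def _check_provenance_coverage(cfg: ModelConfig, prov: dict[str, str]) -> None:
    untagged = [p for p, _ in _numeric_leaves(cfg.model_dump()) if _tag_for(p, prov) is None]
    if untagged:
        raise ConfigError(
            "numeric fields without a provenance tag reached the engine: "
            + ", ".join(untagged[:10])
            + ("..." if len(untagged) > 10 else "")
        )


def provenance_table(path: str | Path | None = None) -> pd.DataFrame:
    """Resolved parameter set with a source tag per numeric field.

    Columns: ``path``, ``value``, ``source``.  Every row carries either a
    [PAPER] tag (value printed in the source analysis), a [FIXTURE] tag
    (synthetic stand-in), or a [DERIVED]/[ASSUMED] tag.
    """
    cfg, prov = _load_with_provenance(Path(path) if path else base_case_path())
    rows = [
        {"path": p, "value": v, "source": _tag_for(p, prov)}
        for p, v in _numeric_leaves(cfg.model_dump())
    ]
    return pd.DataFrame(rows, columns=["path", "value", "source"])
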