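"""Uncertainty machinery: one-way DSA with tornado ranking, the scenario
battery (see :mod:`obesim.config`), and probabilistic sensitivity analysis.

PSA follows the conventional distribution assignment — Gamma for costs, Beta
for probabilities and utilities (disutilities sampled as Beta on their
magnitude), Lognormal for relative treatment effects — with a default
standard error of 20% of the point estimate where no empirical SE is
published.  Parameters are drawn independently; 1,000 iterations by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .config import ModelConfig, apply_overrides
from .economics import ComparisonResult, quadrant
from .pipeline import run_comparison

__all__ = [
    "DSAItem",
    "PSAParameter",
    "PSASpec",
    "PSAResult",
    "make_default_dsa_items",
    "run_dsa",
    "mm_beta",
    "mm_gamma",
    "mm_lognormal",
    "default_psa_parameters",
    "run_psa",
    "ceac",
    "ceac_grid",
    "quadrant_shares",
]

_SE_EPS = 1e-12


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis


@dataclass
class DSAItem:
    """One tornado bar: a config path varied to low/high, all else at base."""

    path: str
    low: float
    high: float
    label: str | None = None

    @classmethod
    def pct_range(cls, config: ModelConfig, path: str, pct: float = 0.25) -> "DSAItem":
        """Symmetric +-pct range around the base-case value (default 25%)."""
        base = config.model_dump()
        node = base
        for p in path.split("."):
            node = node[int(p)] if isinstance(node, list) else node[p]
        return cls(path=path, low=node * (1 - pct), high=node * (1 + pct))


def make_default_dsa_items(config: ModelConfig) -> list[DSAItem]:
    """Default one-way battery: +-25% on the principal cost, utility, efficacy
    and structural inputs."""
    paths = [
        "costs.state_costs_annual.t2d",
        "costs.state_costs_annual.acs",
        "costs.state_costs_annual.osa",
        "costs.state_costs_annual.hypertension",
        "costs.state_costs_annual.dyslipidemia",
        "costs.state_costs_annual.ckd",
        "costs.monitoring_annual",
        "costs.drug_prices.semaglutide_2_4mg",
        "costs.drug_prices.liraglutide_3mg",
        "discount_rate_costs",
        "discount_rate_outcomes",
        "utility.baseline_utility.mean",
        "arms.semaglutide.efficacy_scale",
        "arms.semaglutide.non_responder_rate",
        "arms.liraglutide.non_responder_rate",
        "natural_weight_gain",
        "catch_up_years",
    ]
    return [DSAItem.pct_range(config, p) for p in paths]


def _icer_value(res: ComparisonResult) -> float:
    ic = res.icer_per_qaly
    if isinstance(ic, str):
        # dominance has no finite ratio; 0 keeps dominant results on the
        # cost-effective side of every span computation
        return 0.0 if ic == "dominant" else np.nan
    return float(ic)


def run_dsa(
    config: ModelConfig,
    items: list[DSAItem] | None = None,
    runner: Callable[[ModelConfig], ComparisonResult] = run_comparison,
    top: int | None = 11,
) -> pd.DataFrame:
    """Two full model runs per item; rows ranked by descending ICER span.

    ``top`` trims the table to the most influential parameters (the
    conventional tornado shows eleven); pass ``None`` for all.
    """
    items = items if items is not None else make_default_dsa_items(config)
    rows = []
    for it in items:
        res_lo = runner(apply_overrides(config, {it.path: it.low}))
        res_hi = runner(apply_overrides(config, {it.path: it.high}))
        icer_lo, icer_hi = _icer_value(res_lo), _icer_value(res_hi)
        rows.append(
            {
                "parameter": it.label or it.path,
                "low": it.low,
                "high": it.high,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "span": abs(icer_hi - icer_lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("span", ascending=False, ignore_index=True)
    return df.head(top) if top else df


# ---------------------------------------------------------------------------
# method-of-moments distribution fits


def mm_beta(mean: float, se: float, name: str = "parameter") -> tuple[float, float]:
    """Beta(alpha, beta) matching a mean/SE; degenerate guard at tiny SE."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"{name}: Beta mean must be in (0, 1), got {mean}")
    if se < _SE_EPS:
        return np.inf, np.inf  # point mass sentinel
    if se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"{name}: SE {se} too large for Beta with mean {mean} "
            f"(need se^2 < mean*(1-mean))"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def mm_gamma(mean: float, se: float, name: str = "parameter") -> tuple[float, float]:
    """Gamma(shape, scale) matching a mean/SE."""
    if mean <= 0 or se < 0:
        raise ValueError(f"{name}: Gamma needs mean > 0 and se >= 0")
    if se < _SE_EPS:
        return np.inf, 0.0  # point mass sentinel
    return (mean / se) ** 2, se * se / mean


def mm_lognormal(mean: float, se: float, name: str = "parameter") -> tuple[float, float]:
    """Lognormal (mu, sigma) with the given arithmetic mean/SE."""
    if mean <= 0 or se < 0:
        raise ValueError(f"{name}: Lognormal needs mean > 0 and se >= 0")
    if se < _SE_EPS:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (se / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAParameter:
    """One sampled input: config path, distribution family, moments.

    ``negate=True`` samples the magnitude and flips the sign (disutilities).
    """

    path: str
    dist: str                      # gamma | beta | lognormal | normal
    mean: float
    se: float
    negate: bool = False


@dataclass
class PSASpec:
    n_iterations: int = 1000
    seed: int = 0
    se_fraction_default: float = 0.2
    parameters: list[PSAParameter] | None = None

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def default_psa_parameters(
    config: ModelConfig, se_fraction: float = 0.2
) -> list[PSAParameter]:
    """Standard assignment over the model's uncertain inputs.

    Costs -> Gamma; probabilities and utilities -> Beta (published SEs used
    where available, else ``se_fraction`` of the point estimate);
    disutilities -> Beta on magnitude; arm-level relative treatment effect
    (the efficacy-scale multiplier) -> Lognormal.  Administered drug prices
    are tariffs, not estimates, and stay fixed.
    """
    ps: list[PSAParameter] = []
    c = config.costs
    for cond, v in sorted(c.state_costs_annual.items()):
        if v > 0:
            ps.append(PSAParameter(f"costs.state_costs_annual.{cond}", "gamma", v, se_fraction * v))
    ps.append(PSAParameter("costs.monitoring_annual", "gamma",
                           c.monitoring_annual, se_fraction * c.monitoring_annual))
    for ev, v in sorted(c.event_costs.items()):
        if v > 0:
            ps.append(PSAParameter(f"costs.event_costs.{ev}", "gamma", v, se_fraction * v))
    for ev, v in sorted(c.ae_costs.items()):
        if v > 0:
            ps.append(PSAParameter(f"costs.ae_costs.{ev}", "gamma", v, se_fraction * v))
    u = config.utility
    ps.append(PSAParameter("utility.baseline_utility.mean", "beta",
                           u.baseline_utility.mean, u.baseline_utility.se))
    for cond, vse in sorted(u.state_disutilities.items()):
        ps.append(PSAParameter(f"utility.state_disutilities.{cond}.mean", "beta",
                               abs(vse.mean), vse.se, negate=True))
    for ev, vse in sorted(u.event_disutilities.items()):
        ps.append(PSAParameter(f"utility.event_disutilities.{ev}.mean", "beta",
                               abs(vse.mean), vse.se, negate=True))
    for arm_name in ("semaglutide", "liraglutide"):
        if arm_name not in config.arms:
            continue
        arm = config.arms[arm_name]
        ps.append(PSAParameter(f"arms.{arm_name}.non_responder_rate", "beta",
                               arm.non_responder_rate, se_fraction * arm.non_responder_rate))
        ps.append(PSAParameter(f"arms.{arm_name}.efficacy_scale", "lognormal",
                               arm.efficacy_scale, se_fraction * arm.efficacy_scale))
    for i, rf in enumerate(config.risk_functions):
        if rf.base_annual_rate > 0:
            ps.append(PSAParameter(f"risk_functions.{i}.base_annual_rate", "beta",
                                   rf.base_annual_rate, se_fraction * rf.base_annual_rate))
    return ps


def _sample(param: PSAParameter, rng: np.random.Generator, n: int) -> np.ndarray:
    mean, se = param.mean, param.se
    if se < _SE_EPS:
        x = np.full(n, mean)
    elif param.dist == "gamma":
        shape, scale = mm_gamma(mean, se, param.path)
        x = rng.gamma(shape, scale, size=n)
    elif param.dist == "beta":
        a, b = mm_beta(mean, se, param.path)
        x = rng.beta(a, b, size=n)
    elif param.dist == "lognormal":
        mu, sigma = mm_lognormal(mean, se, param.path)
        x = rng.lognormal(mu, sigma, size=n)
    elif param.dist == "normal":
        x = rng.normal(mean, se, size=n)
    else:
        raise ValueError(f"unknown distribution '{param.dist}' for {param.path}")
    return -x if param.negate else x


@dataclass
class PSAResult:
    draws: pd.DataFrame             # one row per iteration
    summary: pd.DataFrame           # mean/SD/percentile CI/min/max
    n_clamped_runs: int             # iterations where any utility was clamped
    parameters: list[PSAParameter] = field(default_factory=list)


def run_psa(
    spec: PSASpec,
    config: ModelConfig,
    intervention: str = "semaglutide",
    comparator: str = "liraglutide",
) -> PSAResult:
    """Monte-Carlo over the parameter distributions, one full two-arm model
    run per draw; reproducible for a fixed seed."""
    from .pipeline import run_arm  # local import keeps module import cheap

    params = spec.parameters if spec.parameters is not None else \
        default_psa_parameters(config, spec.se_fraction_default)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_iterations
    samples = {p.path: _sample(p, rng, n) for p in params}

    records = []
    n_clamped_runs = 0
    for i in range(n):
        overrides = {path: float(vals[i]) for path, vals in samples.items()}
        cfg_i = apply_overrides(config, overrides)
        run_a = run_arm(cfg_i, intervention)
        run_b = run_arm(cfg_i, comparator)
        a, b = run_a.result, run_b.result
        if run_a.n_utility_clamped or run_b.n_utility_clamped:
            n_clamped_runs += 1
        records.append(
            {
                "iteration": i,
                "cost_intervention": a.total_cost,
                "qalys_intervention": a.qalys,
                "cost_comparator": b.total_cost,
                "qalys_comparator": b.qalys,
                "delta_cost": a.total_cost - b.total_cost,
                "delta_qalys": a.qalys - b.qalys,
                "delta_treatment_cost": a.treatment_cost - b.treatment_cost,
                "delta_monitoring_cost": a.monitoring_cost - b.monitoring_cost,
                "delta_state_cost": a.state_cost - b.state_cost,
                "delta_event_cost": a.event_cost - b.event_cost,
            }
        )
    draws = pd.DataFrame(records)

    cols = [c for c in draws.columns if c != "iteration"]
    summary = pd.DataFrame(
        {
            "mean": draws[cols].mean(),
            "sd": draws[cols].std(ddof=1) if n > 1 else 0.0,
            "lci95": draws[cols].quantile(0.025),
            "uci95": draws[cols].quantile(0.975),
            "min": draws[cols].min(),
            "max": draws[cols].max(),
        }
    )
    return PSAResult(draws=draws, summary=summary, n_clamped_runs=n_clamped_runs,
                     parameters=list(params))


# ---------------------------------------------------------------------------
# PSA post-processing


def ceac_grid(
    lo: float = 0.0,
    hi: float = 50000.0,
    step: float = 500.0,
    always_include: tuple[float, ...] = (9000.0, 27117.0, 30000.0, 34000.0),
) -> np.ndarray:
    grid = np.arange(lo, hi + step / 2, step)
    return np.unique(np.concatenate([grid, np.asarray(always_include)]))


def ceac(draws: pd.DataFrame, lambdas: np.ndarray | None = None) -> pd.DataFrame:
    """Probability of positive NMB per willingness-to-pay value."""
    if len(draws) == 0:
        raise ValueError("no PSA draws")
    lambdas = lambdas if lambdas is not None else ceac_grid()
    dc = draws["delta_cost"].to_numpy()
    dq = draws["delta_qalys"].to_numpy()
    prob = [(lam * dq - dc > 0).mean() for lam in lambdas]
    return pd.DataFrame({"wtp": lambdas, "probability": prob})


def quadrant_shares(draws: pd.DataFrame) -> dict[str, float]:
    """CE-plane quadrant occupancy fractions (sum to 1)."""
    if len(draws) == 0:
        raise ValueError("no PSA draws")
    labels = [
        quadrant(dc, dq)
        for dc, dq in zip(draws["delta_cost"], draws["delta_qalys"])
    ]
    return {q: labels.count(q) / len(labels) for q in ("NE", "SE", "NW", "SW")}
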