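"""Decision metrics: incremental costs/effects, ICER, NMB, CE-plane quadrant."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ArmResult",
    "ComparisonResult",
    "icer",
    "nmb",
    "quadrant",
    "compare",
    "comparison_table",
]


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime results of one strategy."""

    name: str
    treatment_cost: float
    monitoring_cost: float
    state_cost: float
    event_cost: float
    qalys: float
    lys: float

    @property
    def total_cost(self) -> float:
        return self.treatment_cost + self.monitoring_cost + self.state_cost + self.event_cost

    def __post_init__(self):
        if self.qalys > self.lys + 1e-9:
            raise ValueError(f"arm '{self.name}': QALYs ({self.qalys}) exceed LYs ({self.lys})")
        for f in ("treatment_cost", "monitoring_cost", "state_cost", "event_cost",
                  "qalys", "lys"):
            if getattr(self, f) < -1e-9:
                raise ValueError(f"arm '{self.name}': {f} must be >= 0")


def icer(delta_cost: float, delta_qalys: float) -> float | str:
    """ICER or a dominance label.

    Returns the ratio only in the north-east quadrant; ``"dominant"`` for
    more QALYs at no extra cost, ``"dominated"`` for fewer QALYs at no
    saving, ``"southwest"`` for the trade-off quadrant where a ratio would
    invert its meaning, ``"undefined"`` at exactly zero QALY difference.
    """
    if delta_qalys == 0:
        return "undefined"
    if delta_qalys > 0:
        return "dominant" if delta_cost <= 0 else delta_cost / delta_qalys
    return "dominated" if delta_cost >= 0 else "southwest"


def nmb(delta_cost: float, delta_qalys: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * dQ - dC`` at willingness-to-pay ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qalys - delta_cost


def quadrant(delta_cost: float, delta_qalys: float) -> str:
    """CE-plane quadrant with boundary conventions dC=0 -> SE, dQ=0 -> NW."""
    if delta_qalys > 0:
        return "SE" if delta_cost <= 0 else "NE"
    return "NW" if delta_cost >= 0 else "SW"


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental results of intervention vs comparator."""

    intervention: ArmResult
    comparator: ArmResult
    wtp_thresholds: tuple[float, ...]
    delta_cost: float = field(init=False)
    delta_qalys: float = field(init=False)
    delta_lys: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "delta_cost",
                           self.intervention.total_cost - self.comparator.total_cost)
        object.__setattr__(self, "delta_qalys",
                           self.intervention.qalys - self.comparator.qalys)
        object.__setattr__(self, "delta_lys",
                           self.intervention.lys - self.comparator.lys)

    @property
    def icer_per_qaly(self) -> float | str:
        return icer(self.delta_cost, self.delta_qalys)

    @property
    def icer_per_ly(self) -> float | str:
        return icer(self.delta_cost, self.delta_lys)

    @property
    def quadrant(self) -> str:
        return quadrant(self.delta_cost, self.delta_qalys)

    def nmb_at(self, wtp: float) -> float:
        return nmb(self.delta_cost, self.delta_qalys, wtp)

    @property
    def nmb(self) -> dict[float, float]:
        return {w: self.nmb_at(w) for w in self.wtp_thresholds}

    def component_deltas(self) -> dict[str, float]:
        return {
            k: getattr(self.intervention, k) - getattr(self.comparator, k)
            for k in ("treatment_cost", "monitoring_cost", "state_cost", "event_cost")
        }


def compare(
    intervention: ArmResult,
    comparator: ArmResult,
    wtp_thresholds: list[float] | tuple[float, ...] = (27117.0, 30000.0, 34000.0),
) -> ComparisonResult:
    return ComparisonResult(intervention, comparator, tuple(wtp_thresholds))


def comparison_table(result: ComparisonResult) -> pd.DataFrame:
    """Base-case results in the conventional published layout (rows: cost
    components, QALYs, LYs, ICERs, NMBs; columns per arm plus incremental)."""
    a, b = result.intervention, result.comparator
    rows = [
        ("Discounted total lifetime direct medical costs",
         a.total_cost, b.total_cost, result.delta_cost),
        ("Obesity treatment costs", a.treatment_cost, b.treatment_cost,
         a.treatment_cost - b.treatment_cost),
        ("Obesity monitoring costs", a.monitoring_cost, b.monitoring_cost,
         a.monitoring_cost - b.monitoring_cost),
        ("Obesity complications: state costs", a.state_cost, b.state_cost,
         a.state_cost - b.state_cost),
        ("Obesity complications: event costs", a.event_cost, b.event_cost,
         a.event_cost - b.event_cost),
        ("Discounted QALYs", a.qalys, b.qalys, result.delta_qalys),
        ("Discounted LYs", a.lys, b.lys, result.delta_lys),
        ("ICER (EUR per QALY gained)", None, None, result.icer_per_qaly),
        ("ICER (EUR per LY gained)", None, None, result.icer_per_ly),
    ]
    for w in result.wtp_thresholds:
        rows.append((f"NMB at WTP EUR {w:,.0f}/QALY", None, None, round(result.nmb_at(w))))
    return pd.DataFrame(rows, columns=["parameter", a.name, b.name, "incremental"])
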