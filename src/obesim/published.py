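"""Loader for the packaged published results of the source evaluation.

These printed numbers (base-case cost decomposition, scenario ICERs, PSA
summary) are *inputs* used for arithmetic cross-checks of the decision-metric
layer — component sums, NMB identities, percent changes.  They are never fed
into the simulation engine.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import yaml

from .economics import ArmResult

__all__ = ["load_reference_results", "reference_arm_results"]


def load_reference_results() -> dict[str, Any]:
    ref = resources.files("obesim") / "data" / "reference_results.yaml"
    with resources.as_file(ref) as p, open(p, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def reference_arm_results() -> tuple[ArmResult, ArmResult]:
    """Published per-arm base-case results as ArmResult objects."""
    ref = load_reference_results()["base_case"]
    out = []
    for name in ("semaglutide", "liraglutide"):
        r = ref[name]
        out.append(
            ArmResult(
                name=name,
                treatment_cost=r["treatment_cost"],
                monitoring_cost=r["monitoring_cost"],
                state_cost=r["state_cost"],
                event_cost=r["event_cost"],
                qalys=r["qalys"],
                lys=r["lys"],
            )
        )
    return out[0], out[1]
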