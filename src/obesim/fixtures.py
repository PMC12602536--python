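"""Synthetic default inputs for parameters that enter the model only through
configuration.

The published base-case arithmetic of the analysis this package re-implements
rests on inputs that were never printed: the percent-weight-change timelines of
the two treatment arms, the calibrated BMI->incidence risk functions for the
seven complications, the life table, the BMI hazard-ratio bands for residual
mortality, and per-state excess-mortality multipliers.  Everything in this
module is therefore a clearly labelled synthetic stand-in ([FIXTURE]): values
are chosen once to be clinically plausible for a cohort of adults with class
II-III obesity, they satisfy the structural constraints the model needs
(ordering of arm efficacy, monotone life table, HR = 1 in the healthy-weight
band), and no quantitative claim of the original analysis is keyed to them.

Printed inputs (cohort profile, costs, utilities, non-responder rates) live in
``data/base_case.yaml`` with [PAPER]-tagged provenance and are NOT generated
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["FixtureSet", "ToyModel", "make_default_fixtures", "make_toy_model"]

#: Condition labels, in canonical model order.
CONDITIONS = ("t2d", "acs", "hypertension", "dyslipidemia", "asthma", "ckd", "osa")

FIXTURE_TAG = "[FIXTURE] synthetic default (supplementary value not published)"


@dataclass
class FixtureSet:
    """Bundle of synthetic config sections, keyed like the config schema.

    ``arms``, ``risk_functions`` and ``mortality`` are plain dicts in the exact
    shape :func:`obesim.config.load_config` expects, so the set can be merged
    verbatim into a partial configuration file.
    """

    arms: dict[str, Any]
    risk_functions: list[dict[str, Any]]
    mortality: dict[str, Any]
    seed: int = 0
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass
class ToyModel:
    """Tiny random Markov instance used as substrate for oracle tests."""

    n_states: int
    n_cycles: int
    cycle_lengths: np.ndarray          # (T,)
    matrices: np.ndarray               # (T, n, n) row-stochastic, last state absorbing
    utility_rates: np.ndarray          # (T, n) QALY/year, 0 in the absorbing state
    cost_rates: np.ndarray             # (T, n) EUR/year, 0 in the absorbing state
    v0: np.ndarray                     # (n,) initial occupancy, sums to 1


def _timeline(weeks: list[float], changes: list[float]) -> list[list[float]]:
    return [[float(w), float(c)] for w, c in zip(weeks, changes, strict=True)]


def make_default_fixtures(seed: int = 0) -> FixtureSet:
    """Return the packaged synthetic defaults.

    The set is deterministic: the same values are returned for every ``seed``
    (the argument is kept so callers that thread a seed through every input
    source have a uniform interface).  Invariants guaranteed by construction:

    * semaglutide anchor losses >= liraglutide's >= diet-and-exercise's at
      every common week;
    * life-table death probability nondecreasing in age above 30;
    * BMI hazard ratio exactly 1 in the 18.5-25 reference band.
    """
    weeks = [0, 12, 20, 36, 52, 68, 104]
    arms = {
        "semaglutide": {
            "name": "semaglutide",
            "efficacy_timeline": _timeline(
                weeks, [0.0, -0.060, -0.093, -0.132, -0.150, -0.159, -0.159]
            ),
            "non_responder_rate": 0.246,   # [PAPER] printed in the source analysis
            "ae_discontinuation_rate": 0.04,
            "gi_event_rate": 0.12,
            "hypo_rate": 0.010,
            "titration_schedule": [
                ["semaglutide_0_25mg", 4],
                ["semaglutide_0_5mg", 4],
                ["semaglutide_1mg", 4],
                ["semaglutide_1_7mg", 4],
                ["semaglutide_2_4mg", None],
            ],
        },
        "liraglutide": {
            "name": "liraglutide",
            "efficacy_timeline": _timeline(
                weeks, [0.0, -0.045, -0.056, -0.062, -0.064, -0.064, -0.064]
            ),
            "non_responder_rate": 0.386,   # [PAPER]
            "ae_discontinuation_rate": 0.06,
            "gi_event_rate": 0.10,
            "hypo_rate": 0.012,
            "titration_schedule": [["liraglutide_3mg", None]],
        },
        "diet_exercise": {
            "name": "diet_exercise",
            "efficacy_timeline": _timeline(
                weeks, [0.0, -0.012, -0.016, -0.019, -0.019, -0.019, -0.019]
            ),
            "non_responder_rate": 0.0,
            "ae_discontinuation_rate": 0.0,
            "gi_event_rate": 0.0,
            "hypo_rate": 0.0,
            "titration_schedule": [],
        },
    }

    # Calibrated log-linear BMI risk functions. base_annual_rate is the annual
    # incidence at the cohort's baseline BMI (reference 41.5 kg/m2); the
    # log-RR per BMI unit encodes how incidence scales as the cohort loses
    # (or regains) weight.
    def rf(cond, base, rr, mult=None):
        return {
            "condition": cond,
            "kind": "loglinear-BMI",
            "base_annual_rate": base,
            "reference_bmi": 41.5,
            "log_rr_per_bmi_unit": float(np.log(rr)),
            "covariate_multipliers": mult or {},
        }

    risk_functions = [
        rf("t2d", 0.022, 1.09, {"prediabetes": 2.0}),
        rf("acs", 0.007, 1.04, {"smoker": 1.6}),
        rf("hypertension", 0.035, 1.05),
        rf("dyslipidemia", 0.030, 1.04),
        rf("asthma", 0.004, 1.025),
        rf("ckd", 0.006, 1.05),
        rf("osa", 0.012, 1.08),
    ]

    mortality = {
        # Gompertz-Makeham hazard mu(age) = a + b * exp(c * age); the life
        # table q(age) = 1 - exp(-mu) is built per integer age and sex.
        "gompertz_makeham": {
            "a": 0.0002,
            "b_female": 1.8e-05,
            "b_male": 3.2e-05,
            "c": 0.092,
        },
        "age_min": 18,
        "age_max": 110,
        # Fraction of all-cause deaths attributable to each modelled disease,
        # subtracted from the life table to obtain residual mortality.
        "cause_fractions": {
            "t2d": 0.030,
            "acs": 0.230,
            "hypertension": 0.0,
            "dyslipidemia": 0.0,
            "asthma": 0.004,
            "ckd": 0.016,
            "osa": 0.002,
        },
        # Residual-mortality hazard ratio by BMI band; 1.0 at healthy weight.
        "bmi_hr_bands": [
            [0.0, 18.5, 1.25],
            [18.5, 25.0, 1.00],
            [25.0, 30.0, 1.10],
            [30.0, 35.0, 1.25],
            [35.0, 40.0, 1.55],
            [40.0, 45.0, 1.95],
            [45.0, 200.0, 2.35],
        ],
        "bmi_hr_enabled": True,
        # Excess all-cause mortality hazard multipliers once a condition has
        # been acquired (applied multiplicatively on the hazard scale).
        "state_excess_multipliers": {
            "t2d": 1.60,
            "acs": 2.00,
            "hypertension": 1.15,
            "dyslipidemia": 1.10,
            "asthma": 1.10,
            "ckd": 1.85,
            "osa": 1.30,
        },
    }

    prov = {
        "arms": FIXTURE_TAG,
        "arms.semaglutide.non_responder_rate": "[PAPER] non-responder rate 24.6%",
        "arms.liraglutide.non_responder_rate": "[PAPER] non-responder rate 38.6%",
        "risk_functions": FIXTURE_TAG,
        "mortality": FIXTURE_TAG,
    }
    return FixtureSet(
        arms=arms,
        risk_functions=risk_functions,
        mortality=mortality,
        seed=seed,
        provenance=prov,
    )


def make_toy_model(seed: int, n_states: int, n_cycles: int | None = None) -> ToyModel:
    """Random small Markov instance with an absorbing final state.

    Used to cross-check the cohort engine against a naive loop-based
    reference; rewards are zero in the absorbing state so `utility_rates`
    doubles as an alive indicator when set to 1.
    """
    if not 2 <= n_states <= 5:
        raise ValueError("n_states must be in [2, 5]")
    rng = np.random.default_rng(seed)
    T = int(n_cycles) if n_cycles is not None else int(rng.integers(2, 11))
    if T > 10:
        raise ValueError("toy horizon must be <= 10 cycles")
    lengths = rng.choice([0.25, 0.5, 1.0], size=T)
    mats = rng.random((T, n_states, n_states))
    mats /= mats.sum(axis=2, keepdims=True)
    # absorbing death state (last index)
    mats[:, -1, :] = 0.0
    mats[:, -1, -1] = 1.0
    util = rng.random((T, n_states))
    cost = 1000.0 * rng.random((T, n_states))
    util[:, -1] = 0.0
    cost[:, -1] = 0.0
    v0 = rng.random(n_states)
    v0[-1] = 0.0
    v0 /= v0.sum()
    return ToyModel(
        n_states=n_states,
        n_cycles=T,
        cycle_lengths=lengths,
        matrices=mats,
        utility_rates=util,
        cost_rates=cost,
        v0=v0,
    )
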