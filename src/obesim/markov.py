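"""Cohort state-transition engine.

States are combinations of up to three of the seven modelled comorbidities
plus an absorbing death state (65 states in the full model).  Conditions are
never lost; per cycle a surviving cohort fraction may acquire one absent
condition (competing-risk-normalised), or — behind an off-by-default flag —
several jointly.

``run_cohort`` advances occupancy through per-cycle row-stochastic matrices,
applies the half-cycle correction (rewards accrue on the average of start-
and end-of-cycle occupancy) and mid-cycle discounting, and accumulates
life-years, QALYs and cost components.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "CycleRewards",
    "EventRule",
    "RunTotals",
    "RunTrace",
    "enumerate_states",
    "build_matrix",
    "discount_factor",
    "run_cohort",
]

DEATH = "death"


@dataclass(frozen=True)
class StateSpace:
    """Enumerated comorbidity-combination states; death last."""

    conditions: tuple[str, ...]
    states: tuple[tuple[str, ...], ...]        # condition tuples; death = ("death",)
    max_combo: int
    index: dict[tuple[str, ...], int] = field(default_factory=dict, repr=False)
    # (n_alive, n_cond) membership and acquisition-target tables
    membership: np.ndarray = field(default=None, repr=False)
    acq_target: np.ndarray = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def death_index(self) -> int:
        return len(self.states) - 1

    def state_conditions(self, i: int) -> tuple[str, ...]:
        return self.states[i]

    def alive_mask(self) -> np.ndarray:
        m = np.ones(self.n_states, dtype=bool)
        m[self.death_index] = False
        return m

    def condition_mask(self, condition: str) -> np.ndarray:
        """Boolean over states: state contains the condition (death False)."""
        return np.array(
            [condition in s and s != (DEATH,) for s in self.states], dtype=bool
        )


def enumerate_states(conditions: tuple[str, ...] | list[str], max_combo: int = 3) -> StateSpace:
    """Deterministic state enumeration: by combination size, then by the
    order conditions were given; death appended last."""
    conditions = tuple(conditions)
    if not 1 <= max_combo <= len(conditions):
        raise ValueError("max_combo must be in [1, n_conditions]")
    states: list[tuple[str, ...]] = [()]
    for k in range(1, max_combo + 1):
        states.extend(itertools.combinations(conditions, k))
    states.append((DEATH,))
    index = {s: i for i, s in enumerate(states)}
    n_alive = len(states) - 1
    n_cond = len(conditions)
    membership = np.zeros((n_alive, n_cond), dtype=bool)
    acq_target = np.full((n_alive, n_cond), -1, dtype=np.int64)
    for i, s in enumerate(states[:-1]):
        for j, c in enumerate(conditions):
            membership[i, j] = c in s
            if c not in s and len(s) < max_combo:
                target = tuple(cc for cc in conditions if cc in s or cc == c)
                acq_target[i, j] = index[target]
    return StateSpace(
        conditions=conditions,
        states=tuple(states),
        max_combo=max_combo,
        index=index,
        membership=membership,
        acq_target=acq_target,
    )


def build_matrix(
    space: StateSpace,
    incidences: dict[str, float] | np.ndarray,
    mortality: dict[tuple[str, ...], float] | np.ndarray,
    joint_acquisition: bool = False,
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix.

    From each alive state: mortality first, then survivors acquire absent
    conditions.  By default the joint-acquisition mass of the independent
    per-condition probabilities is redistributed proportionally over single
    acquisitions (factor ``(1 - prod(1-p)) / sum(p)``), so at most one
    condition is added per cycle; ``joint_acquisition=True`` instead
    allocates every subset of absent conditions its independent product mass
    (subsets above the combination cap are truncated to the cap in condition
    order).
    """
    n = space.n_states
    n_alive = n - 1
    n_cond = len(space.conditions)
    if isinstance(incidences, dict):
        p_cond = np.array([incidences.get(c, 0.0) for c in space.conditions])
    else:
        p_cond = np.asarray(incidences, dtype=float)
    if isinstance(mortality, dict):
        mort = np.array([mortality.get(s, 0.0) for s in space.states[:-1]])
    else:
        mort = np.asarray(mortality, dtype=float)
    if np.any((p_cond < 0) | (p_cond > 1)) or np.any((mort < 0) | (mort > 1)):
        raise ValueError("probabilities must be in [0, 1]")

    P = np.zeros((n, n))
    P[-1, -1] = 1.0
    can_acquire = space.acq_target >= 0                     # (n_alive, n_cond)
    p_abs = np.where(can_acquire, p_cond[None, :], 0.0)

    if not joint_acquisition:
        joint = 1.0 - np.prod(1.0 - p_abs, axis=1)          # any-acquisition prob
        tot = p_abs.sum(axis=1)
        factor = np.divide(joint, tot, out=np.zeros(n_alive), where=tot > 0)
        alloc = (1.0 - mort)[:, None] * p_abs * factor[:, None]
        stay = (1.0 - mort) * (1.0 - joint)
        rows = np.repeat(np.arange(n_alive), n_cond)[can_acquire.ravel()]
        cols = space.acq_target.ravel()[can_acquire.ravel()]
        np.add.at(P, (rows, cols), alloc.ravel()[can_acquire.ravel()])
        P[np.arange(n_alive), np.arange(n_alive)] += stay
        P[:-1, -1] = mort
    else:
        for i in range(n_alive):
            absent = [j for j in range(n_cond) if not space.membership[i, j]]
            cap = space.max_combo - int(space.membership[i].sum())
            surv = 1.0 - mort[i]
            P[i, -1] = mort[i]
            for r in range(0, len(absent) + 1):
                for sub in itertools.combinations(absent, r):
                    prob = surv
                    for j in absent:
                        prob *= p_cond[j] if j in sub else 1.0 - p_cond[j]
                    if prob == 0.0:
                        continue
                    take = sub[:cap]  # truncate beyond the combination cap
                    conds = tuple(
                        c for k, c in enumerate(space.conditions)
                        if space.membership[i, k] or k in take
                    )
                    P[i, space.index[conds]] += prob

    rowsums = P.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-9):
        raise ValueError("transition matrix rows do not sum to 1")
    return P


def discount_factor(t: float | np.ndarray, rate: float) -> float | np.ndarray:
    """Discrete-time discount factor ``(1 + rate)^(-t)``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-np.asarray(t, dtype=float))


@dataclass(frozen=True)
class EventRule:
    """One-time reward attached to transition flux through a mask.

    ``mask[i, j]`` marks transitions that trigger the event (e.g. entry into
    any state containing ACS from any state without it); the expected event
    count per cycle is ``v_start @ (P * mask)`` summed.
    """

    name: str
    mask: np.ndarray
    cost_per_event: float = 0.0
    qaly_per_event: float = 0.0
    cost_component: str = "event"


@dataclass
class CycleRewards:
    """Per-cycle, per-state reward rates (per person-year of occupancy)."""

    utility_rate: np.ndarray                 # (T, n)
    cost_rates: dict[str, np.ndarray]        # component -> (T, n)
    ly_rate: np.ndarray | None = None        # defaults to alive indicator
    events: list[EventRule] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


@dataclass
class RunTotals:
    lys: float
    qalys: float
    costs: dict[str, float]
    event_counts: dict[str, float]

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))


@dataclass
class RunTrace:
    """Audit trail of one cohort run."""

    starts: np.ndarray
    lengths: np.ndarray
    occupancy_start: np.ndarray              # (T, n)
    occupancy_end: np.ndarray                # (T, n)
    ly_inc: np.ndarray                       # discounted per-cycle increments
    qaly_inc: np.ndarray
    cost_inc: dict[str, np.ndarray]
    ly_inc_undisc: np.ndarray
    qaly_inc_undisc: np.ndarray

    def to_frame(self, space: StateSpace | None = None) -> pd.DataFrame:
        """Tidy per-cycle/state occupancy table for inspection."""
        T, n = self.occupancy_start.shape
        labels = (
            ["+".join(s) if s else "none" for s in space.states]
            if space is not None
            else [str(i) for i in range(n)]
        )
        recs = []
        for t in range(T):
            for j in range(n):
                recs.append(
                    {
                        "cycle": t,
                        "time": self.starts[t],
                        "length": self.lengths[t],
                        "state": labels[j],
                        "occupancy_start": self.occupancy_start[t, j],
                        "occupancy_end": self.occupancy_end[t, j],
                    }
                )
        return pd.DataFrame(recs)


def run_cohort(
    lengths: np.ndarray,
    matrices: np.ndarray | list[np.ndarray],
    rewards: CycleRewards,
    v0: np.ndarray,
    discount_rate_costs: float = 0.0,
    discount_rate_outcomes: float = 0.0,
    alive_mask: np.ndarray | None = None,
    discount_timing: str = "mid",
) -> tuple[RunTrace, RunTotals]:
    """Advance the cohort and accumulate half-cycle-corrected rewards.

    Per cycle ``reward = len * rate . (v_start + v_end)/2 * df`` with ``df``
    evaluated at the cycle midpoint (or start, per ``discount_timing``);
    event rewards attach to transition flux at the same discount point.
    """
    lengths = np.asarray(lengths, dtype=float)
    T = len(lengths)
    v = np.asarray(v0, dtype=float).copy()
    n = len(v)
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancy must sum to 1")
    if alive_mask is None:
        alive_mask = np.ones(n, dtype=bool)
        alive_mask[-1] = False
    ly_rate = rewards.ly_rate if rewards.ly_rate is not None else \
        np.tile(alive_mask.astype(float), (T, 1))

    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    t_disc = starts + lengths / 2 if discount_timing == "mid" else starts
    df_c = discount_factor(t_disc, discount_rate_costs)
    df_o = discount_factor(t_disc, discount_rate_outcomes)

    occ_s = np.zeros((T, n))
    occ_e = np.zeros((T, n))
    ly_inc = np.zeros(T)
    qaly_inc = np.zeros(T)
    ly_undisc = np.zeros(T)
    qaly_undisc = np.zeros(T)
    cost_inc = {k: np.zeros(T) for k in rewards.cost_rates}
    if rewards.events and "event" not in cost_inc:
        cost_inc["event"] = np.zeros(T)
    event_counts = {e.name: 0.0 for e in rewards.events}

    for t in range(T):
        P = matrices[t]
        if P.shape != (n, n):
            raise ValueError(f"matrix {t} has shape {P.shape}, expected {(n, n)}")
        v_end = v @ P
        mid = 0.5 * (v + v_end)
        occ_s[t], occ_e[t] = v, v_end
        ly_u = lengths[t] * float(ly_rate[t] @ mid)
        q_u = lengths[t] * float(rewards.utility_rate[t] @ mid)
        ly_undisc[t], qaly_undisc[t] = ly_u, q_u
        ly_inc[t] = ly_u * df_o[t]
        qaly_inc[t] = q_u * df_o[t]
        for k, rate in rewards.cost_rates.items():
            cost_inc[k][t] += lengths[t] * float(rate[t] @ mid) * df_c[t]
        for e in rewards.events:
            count = float(v @ (P * e.mask) @ np.ones(n))
            event_counts[e.name] += count
            cost_inc[e.cost_component][t] += count * e.cost_per_event * df_c[t]
            qaly_inc[t] += count * e.qaly_per_event * df_o[t]
            qaly_undisc[t] += count * e.qaly_per_event
        v = v_end

    trace = RunTrace(
        starts=starts,
        lengths=lengths,
        occupancy_start=occ_s,
        occupancy_end=occ_e,
        ly_inc=ly_inc,
        qaly_inc=qaly_inc,
        cost_inc=cost_inc,
        ly_inc_undisc=ly_undisc,
        qaly_inc_undisc=qaly_undisc,
    )
    totals = RunTotals(
        lys=float(ly_inc.sum()),
        qalys=float(qaly_inc.sum()),
        costs={k: float(vv.sum()) for k, vv in cost_inc.items()},
        event_counts=event_counts,
    )
    return trace, totals
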