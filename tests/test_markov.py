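import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obesim.fixtures import make_toy_model
from obesim.markov import (
    CycleRewards,
    build_matrix,
    discount_factor,
    enumerate_states,
    run_cohort,
)

from _oracle import naive_cohort_run

CONDS = ("t2d", "acs", "hypertension", "dyslipidemia", "asthma", "ckd", "osa")


class TestStateSpace:
    def test_full_model_has_65_states(self):
        space = enumerate_states(CONDS, max_combo=3)
        assert space.n_states == 65  # 1 + C(7,1) + C(7,2) + C(7,3) + death
        assert space.states[-1] == ("death",)
        assert len(set(space.states)) == 65

    def test_small_spaces(self):
        assert enumerate_states(("t2d",), max_combo=1).n_states == 3
        assert enumerate_states(("t2d", "acs"), max_combo=2).n_states == 5

    def test_ordering_by_size_then_condition_order(self):
        space = enumerate_states(("a", "b", "c"), max_combo=2)
        assert space.states == ((), ("a",), ("b",), ("c",), ("a", "b"),
                                ("a", "c"), ("b", "c"), ("death",))


class TestBuildMatrix:
    def test_no_risk_no_death_gives_identity(self):
        space = enumerate_states(CONDS, max_combo=3)
        P = build_matrix(space, {c: 0.0 for c in CONDS}, np.zeros(64))
        assert np.allclose(P, np.eye(65))

    def test_single_condition_hand_row(self):
        space = enumerate_states(("t2d",), max_combo=1)
        P = build_matrix(space, {"t2d": 0.2}, np.array([0.1, 0.1]))
        # from the empty state: stay 0.72, acquire 0.18 = 0.9*0.2, die 0.10
        assert P[0] == pytest.approx([0.72, 0.18, 0.10])

    def test_saturated_states_only_stay_or_die(self):
        space = enumerate_states(CONDS, max_combo=3)
        P = build_matrix(space, {c: 0.5 for c in CONDS}, np.full(64, 0.2))
        for i, s in enumerate(space.states[:-1]):
            if len(s) == 3:
                assert P[i, i] == pytest.approx(0.8)
                assert P[i, -1] == pytest.approx(0.2)
                assert P[i].sum() == pytest.approx(1.0)

    def test_competing_risk_redistribution_preserves_any_acquisition_mass(self):
        space = enumerate_states(("a", "b"), max_combo=2)
        pa, pb = 0.3, 0.2
        P = build_matrix(space, {"a": pa, "b": pb}, np.zeros(4))
        stay = P[0, space.index[()]]
        assert stay == pytest.approx((1 - pa) * (1 - pb))
        # single-acquisition allocations keep the p_a : p_b ratio
        out_a = P[0, space.index[("a",)]]
        out_b = P[0, space.index[("b",)]]
        assert out_a / out_b == pytest.approx(pa / pb)
        assert out_a + out_b == pytest.approx(1 - (1 - pa) * (1 - pb))

    def test_joint_acquisition_flag_allows_pairs(self):
        space = enumerate_states(("a", "b"), max_combo=2)
        P = build_matrix(space, {"a": 0.3, "b": 0.2}, np.zeros(4), joint_acquisition=True)
        assert P[0, space.index[("a", "b")]] == pytest.approx(0.06)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_invalid_probability_rejected(self):
        space = enumerate_states(("a",), max_combo=1)
        with pytest.raises(ValueError):
            build_matrix(space, {"a": 1.2}, np.zeros(2))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_rows_always_stochastic_and_conditions_never_lost(self, seed):
        rng = np.random.default_rng(seed)
        space = enumerate_states(CONDS[:4], max_combo=3)
        P = build_matrix(
            space,
            dict(zip(CONDS[:4], rng.uniform(0, 0.5, 4))),
            rng.uniform(0, 0.3, space.n_states - 1),
        )
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0) and np.all(P <= 1)
        for i, s in enumerate(space.states[:-1]):
            for j, sj in enumerate(space.states[:-1]):
                if P[i, j] > 0:
                    assert set(s) <= set(sj)  # no remission


class TestDiscounting:
    def test_discount_factor_values(self):
        assert discount_factor(0.0, 0.035) == 1.0
        assert discount_factor(10.0, 0.035) == pytest.approx(0.708919, abs=1e-6)
        assert discount_factor(123.0, 0.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1.0, -0.01)


def _toy_rewards(toy):
    return CycleRewards(
        utility_rate=toy.utility_rates,
        cost_rates={"state": toy.cost_rates},
    )


class TestRunCohort:
    def test_half_cycle_hand_case(self):
        """Two annual cycles, p(death)=0.5/cycle, undiscounted:
        LY = (1+0.5)/2 + (0.5+0.25)/2 = 1.125."""
        P = np.array([[0.5, 0.5], [0.0, 1.0]])
        rewards = CycleRewards(
            utility_rate=np.zeros((2, 2)), cost_rates={"state": np.zeros((2, 2))}
        )
        _, totals = run_cohort([1.0, 1.0], [P, P], rewards, np.array([1.0, 0.0]))
        assert totals.lys == pytest.approx(1.125, abs=1e-15)

    def test_conservation_without_mortality(self):
        P = np.eye(2)
        rewards = CycleRewards(
            utility_rate=np.ones((43, 2)), cost_rates={"state": np.zeros((43, 2))}
        )
        lengths = [0.25] * 4 + [1.0] * 39
        trace, totals = run_cohort(lengths, [P] * 43, rewards, np.array([1.0, 0.0]))
        assert totals.lys == pytest.approx(40.0)
        assert np.allclose(trace.occupancy_end.sum(axis=1), 1.0)

    def test_matches_naive_loop_oracle_exactly(self):
        toy = make_toy_model(seed=7, n_states=4)
        trace, totals = run_cohort(
            toy.cycle_lengths,
            toy.matrices,
            _toy_rewards(toy),
            toy.v0,
            discount_rate_costs=0.035,
            discount_rate_outcomes=0.015,
        )
        ly, qaly, cost = naive_cohort_run(
            toy.cycle_lengths, toy.matrices, toy.utility_rates, toy.cost_rates,
            toy.v0, 0.035, 0.015,
        )
        assert totals.lys == pytest.approx(ly, abs=1e-12)
        assert totals.qalys == pytest.approx(qaly, abs=1e-12)
        assert totals.costs["state"] == pytest.approx(cost, abs=1e-12)

    def test_discounted_increments_never_exceed_undiscounted(self):
        toy = make_toy_model(seed=3, n_states=5)
        trace, _ = run_cohort(
            toy.cycle_lengths, toy.matrices, _toy_rewards(toy), toy.v0,
            discount_rate_costs=0.05, discount_rate_outcomes=0.05,
        )
        assert np.all(trace.qaly_inc <= trace.qaly_inc_undisc + 1e-12)
        assert np.all(trace.ly_inc <= trace.ly_inc_undisc + 1e-12)

    def test_qalys_nonincreasing_in_discount_rate(self):
        toy = make_toy_model(seed=11, n_states=3)
        out = []
        for rate in (0.0, 0.02, 0.05, 0.10):
            _, totals = run_cohort(
                toy.cycle_lengths, toy.matrices, _toy_rewards(toy), toy.v0,
                discount_rate_outcomes=rate,
            )
            out.append(totals.qalys)
        assert np.all(np.diff(out) <= 1e-12)

    def test_death_occupancy_nondecreasing_and_mass_conserved(self):
        toy = make_toy_model(seed=5, n_states=5)
        trace, _ = run_cohort(toy.cycle_lengths, toy.matrices, _toy_rewards(toy), toy.v0)
        assert np.all(np.diff(trace.occupancy_end[:, -1]) >= -1e-12)
        assert np.allclose(trace.occupancy_start.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(trace.occupancy_end.sum(axis=1), 1.0, atol=1e-9)

    def test_half_cycle_ly_strictly_between_endpoint_sums(self):
        toy = make_toy_model(seed=13, n_states=4)
        trace, totals = run_cohort(
            toy.cycle_lengths, toy.matrices, _toy_rewards(toy), toy.v0
        )
        alive_start = float(
            (trace.occupancy_start[:, :-1].sum(axis=1) * trace.lengths).sum()
        )
        alive_end = float((trace.occupancy_end[:, :-1].sum(axis=1) * trace.lengths).sum())
        lo, hi = sorted([alive_start, alive_end])
        assert lo < totals.lys < hi

    def test_dimension_mismatch_raises(self):
        toy = make_toy_model(seed=1, n_states=3)
        bad = [m[:2, :2] for m in toy.matrices]
        with pytest.raises(ValueError, match="shape"):
            run_cohort(toy.cycle_lengths, bad, _toy_rewards(toy), toy.v0)

    def test_trace_export_is_tidy(self):
        toy = make_toy_model(seed=2, n_states=3, n_cycles=4)
        trace, _ = run_cohort(toy.cycle_lengths, toy.matrices, _toy_rewards(toy), toy.v0)
        df = trace.to_frame()
        assert set(df.columns) >= {"cycle", "time", "state", "occupancy_start"}
        assert len(df) == 4 * 3
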