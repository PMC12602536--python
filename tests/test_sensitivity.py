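import numpy as np
import pandas as pd
import pytest

from obesim.sensitivity import (
    DSAItem,
    PSASpec,
    ceac,
    ceac_grid,
    default_psa_parameters,
    mm_beta,
    mm_gamma,
    mm_lognormal,
    quadrant_shares,
    run_dsa,
    run_psa,
)


class TestMomentFits:
    def test_beta_hand_case(self):
        a, b = mm_beta(0.5, 0.1)
        assert (a, b) == (pytest.approx(12.0), pytest.approx(12.0))

    def test_beta_guards(self):
        with pytest.raises(ValueError, match="baseline"):
            mm_beta(0.5, 0.51, name="baseline utility")
        with pytest.raises(ValueError):
            mm_beta(1.2, 0.1)
        a, b = mm_beta(0.3, 0.0)  # point-mass sentinel
        assert np.isinf(a)

    def test_gamma_hand_case(self):
        shape, scale = mm_gamma(100.0, 20.0)
        assert (shape, scale) == (pytest.approx(25.0), pytest.approx(4.0))
        with pytest.raises(ValueError):
            mm_gamma(-1.0, 2.0)

    def test_lognormal_matches_arithmetic_moments(self):
        mu, sigma = mm_lognormal(1.0, 0.2)
        mean = np.exp(mu + sigma**2 / 2)
        sd = mean * np.sqrt(np.exp(sigma**2) - 1)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert sd == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize(
        "dist,mean,se",
        [("beta", 0.78, 0.023), ("beta", 0.246, 0.05), ("gamma", 1125.91, 225.0),
         ("lognormal", 1.0, 0.2)],
    )
    def test_samplers_recover_moments(self, dist, mean, se):
        """Method-of-moments parameterisations reproduce mean/SE within
        3 Monte-Carlo standard errors at n = 10,000."""
        rng = np.random.default_rng(2024)
        n = 10_000
        if dist == "beta":
            a, b = mm_beta(mean, se)
            x = rng.beta(a, b, n)
        elif dist == "gamma":
            a, b = mm_gamma(mean, se)
            x = rng.gamma(a, b, n)
        else:
            mu, sigma = mm_lognormal(mean, se)
            x = rng.lognormal(mu, sigma, n)
        assert abs(x.mean() - mean) < 3 * se / np.sqrt(n)
        assert abs(x.std(ddof=1) - se) < 4 * se / np.sqrt(n)


class TestDSA:
    def test_degenerate_item_has_zero_span(self, short_config):
        base_t2d = short_config.costs.state_costs_annual["t2d"]
        df = run_dsa(
            short_config,
            [DSAItem("costs.state_costs_annual.t2d", base_t2d, base_t2d)],
            top=None,
        )
        assert df.loc[0, "span"] == pytest.approx(0.0, abs=1e-9)

    def test_cost_outside_both_arms_has_zero_span(self, short_config):
        # stroke tariffs are carried in the cost table but no modelled state
        # generates stroke events, so the ICER cannot move
        item = DSAItem.pct_range(short_config, "costs.event_costs.stroke_nonfatal")
        df = run_dsa(short_config, [item], top=None)
        assert df.loc[0, "span"] == pytest.approx(0.0, abs=1e-9)

    def test_spans_match_single_run_oracle(self, short_config):
        from obesim import apply_overrides, run_comparison

        item = DSAItem.pct_range(short_config, "costs.state_costs_annual.t2d")
        df = run_dsa(short_config, [item], top=None)
        lo = run_comparison(apply_overrides(short_config, {item.path: item.low}))
        hi = run_comparison(apply_overrides(short_config, {item.path: item.high}))
        assert df.loc[0, "icer_low"] == pytest.approx(lo.icer_per_qaly)
        assert df.loc[0, "icer_high"] == pytest.approx(hi.icer_per_qaly)
        assert df.loc[0, "span"] == pytest.approx(abs(hi.icer_per_qaly - lo.icer_per_qaly))

    def test_default_battery_ranked_descending(self, short_config):
        df = run_dsa(short_config, top=11)
        assert len(df) == 11
        assert (df["span"].diff().dropna() <= 1e-9).all()


class TestPSA:
    def test_reproducible_under_fixed_seed(self, short_config):
        spec = PSASpec(n_iterations=8, seed=123)
        r1 = run_psa(spec, short_config)
        r2 = run_psa(spec, short_config)
        pd.testing.assert_frame_equal(r1.draws, r2.draws)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)

    def test_different_seeds_agree_within_mc_error(self, short_config):
        a = run_psa(PSASpec(n_iterations=60, seed=1), short_config)
        b = run_psa(PSASpec(n_iterations=60, seed=2), short_config)
        for col in ("delta_cost", "delta_qalys"):
            se = np.sqrt(
                a.summary.loc[col, "sd"] ** 2 / 60 + b.summary.loc[col, "sd"] ** 2 / 60
            )
            assert abs(a.summary.loc[col, "mean"] - b.summary.loc[col, "mean"]) < 3 * se

    def test_summary_interval_ordering(self, short_config):
        res = run_psa(PSASpec(n_iterations=40, seed=7), short_config)
        s = res.summary
        for col in s.index:
            assert s.loc[col, "min"] <= s.loc[col, "lci95"] <= s.loc[col, "mean"]
            assert s.loc[col, "mean"] <= s.loc[col, "uci95"] <= s.loc[col, "max"]
        assert s.loc["delta_qalys", "sd"] > 0

    def test_percentile_interval_covers_95pct_of_draws(self, short_config):
        res = run_psa(PSASpec(n_iterations=200, seed=11), short_config)
        lo = res.summary.loc["delta_cost", "lci95"]
        hi = res.summary.loc["delta_cost", "uci95"]
        inside = res.draws["delta_cost"].between(lo, hi).mean()
        assert 0.93 <= inside <= 0.97

    def test_default_parameter_assignment(self, base_config):
        params = default_psa_parameters(base_config)
        by_dist = {}
        for p in params:
            by_dist.setdefault(p.dist, []).append(p.path)
        assert any("state_costs" in p for p in by_dist["gamma"])
        assert any("baseline_utility" in p for p in by_dist["beta"])
        assert any("efficacy_scale" in p for p in by_dist["lognormal"])
        assert not any("drug_prices" in p.path for p in params)  # tariffs stay fixed
        # published SEs are used where available
        bu = [p for p in params if "baseline_utility" in p.path][0]
        assert bu.se == pytest.approx(0.023)


class TestCEACAndPlane:
    @pytest.fixture(scope="class")
    @staticmethod
    def draws(short_config):
        return run_psa(PSASpec(n_iterations=120, seed=5), short_config).draws

    def test_ceac_bounds_and_limits(self, draws):
        grid = ceac_grid()
        assert {9000.0, 27117.0, 30000.0, 34000.0} <= set(grid)
        curve = ceac(draws, grid)
        assert curve["probability"].between(0, 1).all()
        # lambda = 0: fraction of strictly cost-saving draws
        p0 = float(curve.loc[curve.wtp == 0.0, "probability"].iloc[0])
        assert p0 == pytest.approx((draws["delta_cost"] < 0).mean())
        # lambda -> infinity: fraction with positive QALY gain
        huge = ceac(draws, np.array([1e12]))["probability"].iloc[0]
        assert huge == pytest.approx((draws["delta_qalys"] > 0).mean())

    def test_quadrant_shares_sum_to_one(self, draws):
        shares = quadrant_shares(draws)
        assert sum(shares.values()) == pytest.approx(1.0)
        assert shares["SE"] + shares["NE"] == pytest.approx(
            (draws["delta_qalys"] > 0).mean()
        )

    def test_ceac_equals_se_share_plus_cheap_ne_share(self, draws):
        """At every threshold the CEAC decomposes into the dominant share plus
        the NE draws whose ICER clears the threshold."""
        dc = draws["delta_cost"].to_numpy()
        dq = draws["delta_qalys"].to_numpy()
        curve = ceac(draws)
        for lam, prob in zip(curve["wtp"], curve["probability"]):
            se_share = ((dq > 0) & (dc <= 0)).mean()
            ne_cheap = ((dq > 0) & (dc > 0) & (dc / dq < lam)).mean()
            sw_ok = ((dq <= 0) & (lam * dq - dc > 0)).mean()
            assert prob == pytest.approx(se_share + ne_cheap + sw_ok, abs=1e-12)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame(columns=["delta_cost", "delta_qalys"]))
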