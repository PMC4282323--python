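import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import truncnorm

from dtlshrink import (
    ALL_METHODS,
    MetaView,
    TrialDesign,
    estimate_all,
    estimate_cb,
    estimate_cr_proportional,
    estimate_cr_proportional_lt,
    estimate_cr_standard,
    estimate_direct,
    estimate_mle,
    estimate_umvcue,
    fixed_effect_mean,
    lindley_factor,
    profile_loglik_tau2,
    to_meta_view,
)
from tests.conftest import make_outcome


class TestUmvcue:
    def test_equals_mle_when_winner_is_clear(self, design_k6):
        out = make_outcome([100.0, 0, 0, 0, 0, 0], 99.0)
        mle = estimate_mle(out, design_k6).estimate
        umv = estimate_umvcue(out, design_k6).estimate
        assert umv == pytest.approx(mle, abs=1e-10)

    def test_correction_is_downward(self, design_k6):
        out = make_outcome([0.5, 0.4, 0, 0, 0, 0], 0.3)
        assert (
            estimate_umvcue(out, design_k6).estimate
            < estimate_mle(out, design_k6).estimate
        )

    def test_extreme_runner_up_no_overflow(self, design_k6):
        # Z far below X_r: Mills ratio must stay finite via log-space eval
        out = make_outcome([0.1, 0.0, 0, 0, 0, 0], -200.0)
        est = estimate_umvcue(out, design_k6).estimate
        assert np.isfinite(est)

    @pytest.mark.parametrize("s1,s2", [(1.0, 1.0), (2.0, 1.0), (0.7, 1.6)])
    def test_matches_rao_blackwell_conditional_oracle(self, s1, s2):
        # oracle: E[Y | Z, X >= x_r] by simulating the conditional law of
        # the stage-1 maximum given the combined estimate (truncated normal)
        design = TrialDesign(k=4, sigma1=s1, sigma2=s2)
        xr, z = 0.6, 0.9
        x = [z, xr, -1.0, -2.0]  # only x_r and Z matter for the estimator
        # back out a y_s giving combined estimate exactly z
        out = make_outcome(x, z)
        est = estimate_umvcue(out, design).estimate

        eta = s1**2 / np.sqrt(s1**2 + s2**2)
        a = (xr - z) / eta
        rng = np.random.default_rng(5)
        xs_draws = truncnorm.rvs(a, np.inf, loc=z, scale=eta,
                                 size=400_000, random_state=rng)
        w = s2**2 / (s1**2 + s2**2)  # weight of X in Z
        y_draws = (z - w * xs_draws) / (1 - w)
        se = y_draws.std(ddof=1) / np.sqrt(y_draws.size)
        assert est == pytest.approx(y_draws.mean(), abs=3 * se)

    def test_conditionally_unbiased_given_selection(self):
        # fixed unequal true means; condition on each selected arm
        design = TrialDesign(k=4, sigma1=1.3, sigma2=0.8)
        mu = np.array([0.4, 0.0, -0.2, 0.3])
        rng = np.random.default_rng(17)
        n = 200_000
        x = rng.normal(mu, design.sigma1, size=(n, 4))
        s = x.argmax(axis=1)
        idx = np.arange(n)
        masked = x.copy()
        masked[idx, s] = -np.inf
        r = masked.argmax(axis=1)
        ys = rng.normal(mu[s], design.sigma2)
        from dtlshrink.sim_study import _batch_estimates

        est = _batch_estimates(design, x, s, r, ys, ("umvcue",))["umvcue"]
        for arm in range(4):
            sel = s == arm
            err = est[sel] - mu[arm]
            se = err.std(ddof=1) / np.sqrt(sel.sum())
            assert abs(err.mean()) < 3 * se


class TestLindleyFactor:
    @pytest.mark.parametrize(
        "x, expected_c",
        [
            ([-1, -1, -1, 1, 1, 1], 0.5),  # sum of squares 6
            ([0, 0, 0, 0, 0, 3], 0.6),  # sum of squares 7.5
        ],
    )
    def test_hand_examples(self, x, expected_c):
        c, xbar = lindley_factor(np.array(x, float), sigma1=1.0)
        assert c == pytest.approx(expected_c)
        assert xbar == pytest.approx(np.mean(x))

    def test_sum_of_squares_nine(self):
        x = np.array([0, 0, 0, 0, 0, 3.0]) * np.sqrt(9 / 7.5)
        c, _ = lindley_factor(x, sigma1=1.0)
        assert c == pytest.approx(2 / 3)

    def test_plus_rule_full_shrinkage(self):
        c, xbar = lindley_factor(np.array([0, 0.1, 0, 0.1, 0, 0.1]), sigma1=1.0)
        assert c == 0.0

    def test_zero_dispersion(self):
        c, xbar = lindley_factor(np.full(6, 2.0), sigma1=1.0)
        assert c == 0.0 and xbar == 2.0


class TestCarrerasBrannath:
    def test_worked_example(self, design_k6):
        out = make_outcome([0, 0, 0, 0, 0, 3.0], 1.0)
        fit = estimate_cb(out, design_k6)
        assert fit.shrink_factor == pytest.approx(0.6)
        assert fit.grand_mean == pytest.approx(0.5)
        assert fit.estimate == pytest.approx(1.5)

    def test_reduces_to_mle_when_factor_zero(self, design_k6):
        # tiny stage-1 dispersion forces C+ = 0; the stage-1 component is
        # then Xbar, so CB equals the MLE built from Xbar instead of X_s;
        # with X_s == Xbar they agree exactly
        out = make_outcome(np.full(6, 1.2), 0.4)
        fit = estimate_cb(out, design_k6)
        assert fit.shrink_factor == 0.0
        assert fit.estimate == pytest.approx((1.2 + 0.4) / 2)

    def test_monotone_in_stage2_estimate(self, design_k6):
        x = [0.1, 0.9, -0.4, 0.2, 0.0, 0.5]
        lo = [f(make_outcome(x, 0.2), design_k6).estimate
              for f in (estimate_mle, estimate_umvcue, estimate_cb)]
        hi = [f(make_outcome(x, 0.9), design_k6).estimate
              for f in (estimate_mle, estimate_umvcue, estimate_cb)]
        assert all(h > l for l, h in zip(lo, hi))

    def test_k3_requires_fix(self):
        out = make_outcome([0.0, 1.0, 2.0], 1.5)
        with pytest.raises(ValueError):
            estimate_cb(out, TrialDesign(k=3, sigma1=1, sigma2=1))
        fit = estimate_cb(
            out, TrialDesign(k=3, sigma1=1, sigma2=1, small_k_fix=True)
        )
        assert np.isfinite(fit.estimate)


class TestDirect:
    def test_collapses_to_fixed_effects_mean_at_tau2_zero(self):
        xt = np.array([0.0, 0.05, -0.05, 0.02])
        w = np.ones(4)
        view = MetaView(xt=xt, w=w, s=1)
        fit = estimate_direct(view)
        assert fit.tau2 == 0.0
        assert fit.estimate == pytest.approx(fixed_effect_mean(xt, w))

    def test_approaches_own_estimate_at_huge_dispersion(self):
        view = MetaView(xt=[0.0, 1000.0, -500.0, 300.0], w=[1, 0.5, 1, 1], s=1)
        fit = estimate_direct(view)
        assert fit.shrink_factor > 0.999
        assert fit.estimate == pytest.approx(1000.0, rel=1e-2)

    def test_matches_grid_search_oracle(self):
        xt = np.array([0.0, 0.0, 4.0, 4.0])
        w = np.ones(4)
        view = MetaView(xt=xt, w=w, s=2)
        grid = np.linspace(0, 50, 100_001)
        lls = np.array([profile_loglik_tau2(t, xt, w) for t in grid])
        t_star = grid[int(np.argmax(lls))]
        v = w + t_star
        mu = np.sum(xt / v) / np.sum(1 / v)
        oracle = (t_star * xt[2] + w[2] * mu) / (w[2] + t_star)
        fit = estimate_direct(view)
        assert fit.estimate == pytest.approx(oracle, abs=1e-4)


class TestCarterRolphStandard:
    def test_equal_variance_reduction_to_lindley(self, design_stage1_only):
        # no stage-2 information: all W equal, PM tau2 > 0 here, so the
        # factor must equal Lindley's exactly and all three shrinkage
        # routes give the same estimate
        x = np.array([0.0, 0.4, 2.5, -1.0, 1.8, -0.6])
        out = make_outcome(x, 0.0)
        view = to_meta_view(out, design_stage1_only)
        c_lind, xbar = lindley_factor(x, sigma1=1.0)
        fit_std = estimate_cr_standard(view)
        fit_prop = estimate_cr_proportional(view)
        fit_cb = estimate_cb(out, design_stage1_only)
        lindley_est = xbar + c_lind * (x.max() - xbar)
        assert fit_std.shrink_factor == pytest.approx(c_lind, abs=1e-9)
        assert fit_std.estimate == pytest.approx(lindley_est, abs=1e-9)
        assert fit_prop.estimate == pytest.approx(lindley_est, abs=1e-9)
        assert fit_cb.estimate == pytest.approx(lindley_est, abs=1e-9)

    def test_factor_at_truncated_tau2(self, design_k6):
        # PM tau2 = 0 leaves a strictly positive factor 1 - (k-3)/(k-1)
        out = make_outcome([0.0, 0.01, -0.01, 0.02, 0.0, 0.01], 0.01)
        fit = estimate_cr_standard(to_meta_view(out, design_k6))
        assert fit.tau2 == 0.0
        k = 6
        expected = 1 - (k - 3) / (k - 1) * 0.5 / 0.5
        assert fit.shrink_factor == pytest.approx(expected)
        assert fit.shrink_factor > 0


class TestCarterRolphProportional:
    def test_full_shrinkage_when_q_small(self, design_k6):
        out = make_outcome([0.0, 0.1, -0.1, 0.05, 0.0, 0.08], 0.05)
        view = to_meta_view(out, design_k6)
        fit = estimate_cr_proportional(view)
        assert fit.shrink_factor == 0.0
        assert fit.estimate == pytest.approx(
            fixed_effect_mean(view.xt, view.w)
        )

    def test_factor_half_when_q_is_six(self):
        # symmetric configuration: mu_FE = 0, Q(0) = 6, C+ = 1 - 3/6
        view = MetaView(xt=[-1, -1, -1, 1, 1, 1], w=np.ones(6), s=3)
        fit = estimate_cr_proportional(view)
        assert fit.shrink_factor == pytest.approx(0.5)
        assert fit.estimate == pytest.approx(0.5)


class TestLimitedTranslation:
    def test_unchanged_inside_corridor(self):
        view = MetaView(xt=[-1, -1, -1, 1, 1, 1], w=np.ones(6), s=3)
        prop = estimate_cr_proportional(view).estimate
        lt = estimate_cr_proportional_lt(view).estimate
        assert abs(prop - 1.0) <= 1.0
        assert lt == pytest.approx(prop)

    def test_clips_to_corridor_edge(self):
        # Q(0) just above k-3 forces full shrinkage to the grand mean,
        # which sits more than one SE below the selected estimate
        view = MetaView(
            xt=[0.0, 0.0, 0.0, 0.0, 0.0, 1.6], w=np.ones(6), s=5
        )
        prop = estimate_cr_proportional(view).estimate
        lt = estimate_cr_proportional_lt(view).estimate
        assert prop < 1.6 - 1.0
        assert lt == pytest.approx(1.6 - 1.0)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        st.lists(st.floats(-5, 5), min_size=6, max_size=6),
        st.lists(st.floats(0.1, 2), min_size=6, max_size=6),
        st.integers(0, 5),
    )
    def test_corridor_and_contraction_property(self, xt, w, s):
        view = MetaView(xt=np.array(xt), w=np.array(w), s=s)
        prop = estimate_cr_proportional(view).estimate
        lt = estimate_cr_proportional_lt(view).estimate
        half = np.sqrt(view.w[s])
        assert abs(lt - view.xt[s]) <= half + 1e-12
        assert abs(lt - view.xt[s]) <= abs(prop - view.xt[s]) + 1e-12


class TestSharedProperties:
    def test_location_equivariance(self, design_k6, rng):
        x = rng.normal(size=6)
        y = float(rng.normal())
        shift = 3.7
        base = estimate_all(make_outcome(x, y), design_k6).set_index("method")
        moved = estimate_all(
            make_outcome(x + shift, y + shift), design_k6
        ).set_index("method")
        for m in ALL_METHODS:
            assert moved.loc[m, "estimate"] == pytest.approx(
                base.loc[m, "estimate"] + shift, abs=1e-7
            )

    def test_convex_combination_and_factor_range(self, design_k6, rng):
        for _ in range(30):
            out = make_outcome(rng.normal(0, 1.5, size=6), rng.normal())
            view = to_meta_view(out, design_k6)
            xt_s = view.xt[view.s]
            for fit in (
                estimate_cb(out, design_k6),
                estimate_direct(view),
                estimate_cr_standard(view),
                estimate_cr_proportional(view),
            ):
                assert 0.0 <= fit.shrink_factor <= 1.0
                lo, hi = sorted((fit.grand_mean, xt_s if fit.method != "cb"
                                 else estimate_mle(out, design_k6).estimate))
                # cb shrinks its stage-1 part toward Xbar then recombines
                if fit.method != "cb":
                    assert lo - 1e-9 <= fit.estimate <= hi + 1e-9

    def test_estimate_all_table_shape(self, design_k6):
        out = make_outcome([0, 0, 0, 0, 0, 3.0], 1.0)
        tab = estimate_all(out, design_k6)
        assert list(tab["method"]) == list(ALL_METHODS)
        assert set(tab.columns) == {
            "method", "estimate", "grand_mean", "tau2", "shrink_factor"
        }
        mle_row = tab.set_index("method").loc["mle", "estimate"]
        assert mle_row == pytest.approx(2.0)

    def test_unknown_method_rejected(self, design_k6):
        with pytest.raises(ValueError, match="unknown method"):
            estimate_all(make_outcome([0, 1], 0.5),
                         TrialDesign(k=2, sigma1=1, sigma2=1),
                         methods=("nope",))
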