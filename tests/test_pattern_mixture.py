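import numpy as np
import pytest

import lgmsens as L
from lgmsens.pattern_mixture import (
    DropoutGrouping,
    _multigroup_fit,
    _restriction_expr,
)

TIMES = np.array([0.0, 1.17, 2.17])


class TestAssignDropoutGroups:
    def test_pattern_fallback_three_groups(self):
        y = np.array([[1, 1, 1], [1, 1, np.nan], [1, np.nan, np.nan]], dtype=float)
        ds = L.WideDataset(y=y, wave_times=[0, 1, 2])
        g = L.assign_dropout_groups(ds, "last-observed-wave", k=3)
        assert g.labels.tolist() == [1, 2, 3]

    def test_all_complete_k2_errors_on_empty_group(self):
        ds = L.WideDataset(y=np.ones((5, 3)), wave_times=[0, 1, 2])
        with pytest.raises(ValueError, match="group 2 is empty"):
            L.assign_dropout_groups(ds, "last-observed-wave", k=2)

    def test_administrative_proportions_to_four_decimals(self):
        sizes = (395, 184, 493)
        labels = np.repeat([1, 2, 3], sizes)
        y = np.ones((labels.size, 3))
        ds = L.WideDataset(y=y, wave_times=[0, 1, 2], dropout_group=labels)
        g = L.assign_dropout_groups(ds, "administrative", k=3)
        np.testing.assert_allclose(g.proportions, np.array(sizes) / 1072, atol=1e-15)
        np.testing.assert_allclose(g.proportions, [0.3684, 0.1716, 0.4599], atol=1.01e-4)

    def test_returning_subjects_differ_between_sources(self):
        # wave non-response (o,m,o) is attrition group 1 by last-observed wave
        y = np.array([[1, np.nan, 1], [1, 1, 1], [1, 1, np.nan],
                      [1, np.nan, np.nan]], dtype=float)
        ds = L.WideDataset(y=y, wave_times=[0, 1, 2])
        g = L.assign_dropout_groups(ds, "last-observed-wave", k=3)
        assert g.labels.tolist() == [1, 1, 2, 3]

    def test_empty_derived_group_is_named_error(self):
        y = np.array([[1, np.nan, 1], [1, 1, 1], [1, np.nan, np.nan]], dtype=float)
        ds = L.WideDataset(y=y, wave_times=[0, 1, 2])
        with pytest.raises(ValueError, match="group 2 is empty"):
            L.assign_dropout_groups(ds, "last-observed-wave", k=3)


class TestPoolPatternMixture:
    def test_single_group_passthrough(self):
        pooled, se = L.pool_pattern_mixture([2.5], [0.04], [1.0], N=100)
        assert pooled == 2.5
        assert se == pytest.approx(0.2)

    def test_hand_expansion_multinomial_term(self):
        # theta = (1, 3), V = 0, pi = (.5, .5): var = theta' C theta = 1/N
        pooled, se = L.pool_pattern_mixture([1.0, 3.0], [0.0, 0.0], [0.5, 0.5], N=50)
        assert pooled == pytest.approx(2.0)
        assert se == pytest.approx(np.sqrt(1 / 50))

    def test_equal_estimates_kill_weight_term(self):
        pooled, se = L.pool_pattern_mixture([2.0, 2.0, 2.0], [0.01, 0.04, 0.09],
                                            [0.2, 0.3, 0.5], N=200)
        assert pooled == pytest.approx(2.0)
        assert se == pytest.approx(np.sqrt(0.04 * 0.01 + 0.09 * 0.04 + 0.25 * 0.09))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            L.pool_pattern_mixture([1.0, 2.0], [0.1, 0.1], [0.6, 0.5], N=10)

    def test_weighted_average_arithmetic(self):
        pooled, _ = L.pool_pattern_mixture([3.0, 3.5], [0.0, 0.0], [0.5, 0.5], N=10**9)
        assert pooled == pytest.approx(3.25)


class TestRestrictionExpressions:
    def test_available_case_weighted_average(self):
        expr = _restriction_expr("available-case")
        assert expr(np.array([-0.10, -0.20]), np.array([100, 100, 50])) == pytest.approx(-0.15)

    def test_complete_and_neighbouring(self):
        free = np.array([-0.10, -0.20])
        sizes = np.array([10, 30, 5])
        assert _restriction_expr("complete-case")(free, sizes) == -0.10
        assert _restriction_expr("neighbouring-case")(free, sizes) == -0.20


@pytest.fixture(scope="module")
def masked_medium(preset):
    params, scenario, _, times = preset
    ds, latent = L.simulate_growth(900, times, params, seed=70)
    masked, _ = L.impose_missingness(ds, scenario, latent=latent, seed=71)
    return masked


class TestTwoGroupModel:
    def test_null_difference_matches_single_group_fiml(self, masked_medium, spec):
        # both groups drawn from identical parameters: pooled means must sit
        # within sampling noise of the plain FIML fit
        g2 = L.assign_dropout_groups(masked_medium, "last-observed-wave", k=2)
        pm = L.fit_two_group_pm(masked_medium, g2, spec)
        ml = L.fit_lgm_fiml(masked_medium, spec)
        for k in ("mu_I", "mu_S"):
            assert abs(pm.params[k] - ml.params[k]) < 2 * ml.se[k]

    def test_pooled_mean_is_exact_weighted_average(self, masked_medium, spec):
        g2 = L.assign_dropout_groups(masked_medium, "last-observed-wave", k=2)
        pm = L.fit_two_group_pm(masked_medium, g2, spec)
        gm = pm.group_means
        np.testing.assert_allclose(
            pm.params["mu_I"], (gm["pi"] * gm["mu_I"]).sum(), atol=1e-12)
        np.testing.assert_allclose(
            pm.params["mu_S"], (gm["pi"] * gm["mu_S"]).sum(), atol=1e-12)

    def test_wrong_k_rejected(self, masked_medium, spec):
        g3 = L.assign_dropout_groups(masked_medium, "last-observed-wave", k=3)
        with pytest.raises(ValueError, match="k = 2"):
            L.fit_two_group_pm(masked_medium, g3, spec)

    def test_pooled_slope_moves_toward_incomplete_group(self, spec):
        # completers decline slowly, dropouts steeply; growing the dropout
        # share must pull the pooled slope toward the dropout slope
        p1 = L.GrowthParams(mu_I=3.2, mu_S=-0.05, psi_II=0.4, psi_SS=0.02, theta=0.25)
        p2 = L.GrowthParams(mu_I=3.2, mu_S=-0.30, psi_II=0.4, psi_SS=0.02, theta=0.25)
        d1, _ = L.simulate_growth(600, TIMES, p1, seed=80)
        pooled_slopes = []
        for n2 in (150, 450, 900):
            d2, _ = L.simulate_growth(n2, TIMES, p2, seed=81)
            y2 = d2.y.copy()
            y2[:, 2] = np.nan  # dropouts never reach wave 3
            y = np.vstack([d1.y, y2])
            ds = L.WideDataset(y=y, wave_times=TIMES)
            g2 = L.assign_dropout_groups(ds, "last-observed-wave", k=2)
            pm = L.fit_two_group_pm(ds, g2, spec)
            pooled_slopes.append(pm.params["mu_S"])
        assert pooled_slopes[0] > pooled_slopes[1] > pooled_slopes[2]


@pytest.fixture(scope="module")
def g3(masked_medium):
    return L.assign_dropout_groups(masked_medium, "last-observed-wave", k=3)


class TestRestrictionModels:
    def test_complete_case_needs_opt_in(self, masked_medium, g3, spec):
        with pytest.raises(ValueError, match="opt in"):
            L.fit_restriction_pm(masked_medium, g3, spec, "complete-case")

    @pytest.mark.parametrize("restriction", [
        "complete-case", "neighbouring-case", "available-case"])
    def test_constraint_holds_exactly_at_solution(self, masked_medium, g3, spec, restriction):
        pm = L.fit_restriction_pm(masked_medium, g3, spec, restriction,
                                  allow_complete_case=True)
        gm = pm.group_means.set_index("group")
        target = _restriction_expr(restriction)(
            gm.loc[[1, 2], "mu_S"].to_numpy(), g3.sizes)
        assert gm.loc[3, "mu_S"] == pytest.approx(target, abs=1e-10)

    def test_null_simulation_restrictions_agree(self, masked_medium, g3, spec):
        fits = {
            r: L.fit_restriction_pm(masked_medium, g3, spec, r, allow_complete_case=True)
            for r in ("complete-case", "neighbouring-case", "available-case")
        }
        slopes = {r: f.params["mu_S"] for r, f in fits.items()}
        ses = {r: f.se["mu_S"] for r, f in fits.items()}
        for a in slopes:
            for b in slopes:
                assert abs(slopes[a] - slopes[b]) < 2 * max(ses[a], ses[b])

    def test_pooled_means_exact_weighted_average(self, masked_medium, g3, spec):
        pm = L.fit_restriction_pm(masked_medium, g3, spec, "available-case")
        gm = pm.group_means
        np.testing.assert_allclose(
            pm.params["mu_S"], (gm["pi"] * gm["mu_S"]).sum(), atol=1e-12)

    def test_shared_variance_block_reported_with_se(self, masked_medium, g3, spec):
        pm = L.fit_restriction_pm(masked_medium, g3, spec, "neighbouring-case")
        for name in ("psi_II", "psi_SS", "theta1", "theta2", "theta3"):
            assert name in pm.params
            assert pm.se[name] > 0


class TestOneGroupReduction:
    def test_single_group_model_reproduces_fiml(self, masked_medium, spec):
        grouping = DropoutGrouping(labels=np.ones(masked_medium.n, dtype=int),
                                   k=1, mode="manual")
        est, shared = _multigroup_fit(masked_medium, grouping, spec, "PM1")
        ml = L.fit_lgm_fiml(masked_medium, spec)
        assert est.params["mu_I[1]"] == pytest.approx(ml.params["mu_I"], abs=1e-6)
        assert est.params["mu_S[1]"] == pytest.approx(ml.params["mu_S"], abs=1e-6)
        assert est.loglik == pytest.approx(ml.loglik, abs=1e-6)
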