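import numpy as np
import pytest
from scipy import stats

import lgmsens as L
from lgmsens.dataio import ConfigurationError
from lgmsens.growth import GrowthEstimates

TIMES = (0.0, 1.17, 2.17)


class TestGrowthSpec:
    def test_loadings_validated(self):
        with pytest.raises(ValueError):
            L.GrowthSpec(wave_times=(1.0, 2.0))
        with pytest.raises(ValueError):
            L.GrowthSpec(wave_times=(0.0, 2.0, 1.0))

    def test_param_names_respect_fixing(self):
        full = L.GrowthSpec(wave_times=TIMES)
        assert "psi_IS" in full.param_names()
        nocov = L.GrowthSpec(wave_times=TIMES, cov_IS_free=False)
        assert "psi_IS" not in nocov.param_names()
        noslope = L.GrowthSpec(wave_times=TIMES, slope_var_free=False)
        assert "psi_SS" not in noslope.param_names()


class TestImpliedMoments:
    def test_degenerate_mean_structure(self):
        spec = L.GrowthSpec(wave_times=TIMES)
        mean, cov = L.implied_moments(
            {"mu_I": 3, "mu_S": -0.1, "psi_II": 0, "psi_SS": 0, "psi_IS": 0,
             "theta1": 0, "theta2": 0, "theta3": 0}, spec)
        np.testing.assert_allclose(mean, [3, 2.883, 2.783])
        np.testing.assert_allclose(cov, 0, atol=1e-15)

    def test_intercept_variance_only(self):
        spec = L.GrowthSpec(wave_times=TIMES)
        _, cov = L.implied_moments(
            {"mu_I": 0, "mu_S": 0, "psi_II": 1.0, "psi_SS": 0, "psi_IS": 0,
             "theta1": 0, "theta2": 0, "theta3": 0}, spec)
        np.testing.assert_allclose(cov, np.ones((3, 3)))

    def test_full_parameterization_matches_matrix_expansion(self):
        params = {"mu_I": 3.1, "mu_S": -0.2, "psi_II": 0.5, "psi_SS": 0.07,
                  "psi_IS": -0.04, "theta1": 0.3, "theta2": 0.25, "theta3": 0.2}
        spec = L.GrowthSpec(wave_times=TIMES)
        mean, cov = L.implied_moments(params, spec)
        # independent expansion: Lambda eta-bar and Lambda Psi Lambda' + Theta
        lam = np.array(TIMES)
        Lam = np.column_stack([np.ones(3), lam])
        Psi = np.array([[0.5, -0.04], [-0.04, 0.07]])
        np.testing.assert_allclose(mean, Lam @ np.array([3.1, -0.2]), atol=1e-14)
        np.testing.assert_allclose(
            cov, Lam @ Psi @ Lam.T + np.diag([0.3, 0.25, 0.2]), atol=1e-14)


@pytest.fixture(scope="module")
def tiny_incomplete():
    """<= 20 subjects, all seven observable patterns represented."""
    rng = np.random.default_rng(21)
    y = rng.normal(3.0, 0.8, size=(18, 3))
    masks = [
        (1, 1, 1), (1, 1, 1), (1, 1, 1), (1, 1, 0), (1, 1, 0), (1, 0, 1),
        (0, 1, 1), (1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1),
        (1, 0, 1), (1, 1, 0), (1, 0, 0), (1, 1, 1), (0, 1, 1), (1, 1, 1),
    ]
    for i, m in enumerate(masks):
        y[i, ~np.array(m, dtype=bool)] = np.nan
    return L.WideDataset(y=y, wave_times=list(TIMES))


class TestFimlLoglik:
    def test_complete_data_equals_full_density_sum(self, small_complete):
        spec = L.GrowthSpec(wave_times=TIMES)
        params = {"mu_I": 3.0, "mu_S": -0.1, "psi_II": 0.4, "psi_SS": 0.03,
                  "psi_IS": 0.02, "theta1": 0.25, "theta2": 0.25, "theta3": 0.25}
        mean, cov = L.implied_moments(params, spec)
        ll = L.fiml_loglik(params, spec, small_complete)
        expected = stats.multivariate_normal(mean, cov).logpdf(small_complete.y).sum()
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_matches_brute_force_marginalization(self, tiny_incomplete):
        spec = L.GrowthSpec(wave_times=TIMES)
        params = {"mu_I": 3.2, "mu_S": -0.15, "psi_II": 0.5, "psi_SS": 0.06,
                  "psi_IS": -0.03, "theta1": 0.3, "theta2": 0.22, "theta3": 0.27}
        mean, cov = L.implied_moments(params, spec)
        # oracle: per-subject scipy logpdf on the observed sub-vector
        expected = 0.0
        for row in tiny_incomplete.y:
            obs = ~np.isnan(row)
            expected += stats.multivariate_normal(
                mean[obs], cov[np.ix_(obs, obs)]).logpdf(row[obs])
        assert L.fiml_loglik(params, spec, tiny_incomplete) == pytest.approx(
            expected, abs=1e-10)

    def test_single_subject_bivariate_marginal(self):
        spec = L.GrowthSpec(wave_times=TIMES)
        params = {"mu_I": 3.0, "mu_S": 0.1, "psi_II": 0.4, "psi_SS": 0.05,
                  "psi_IS": 0.0, "theta1": 0.2, "theta2": 0.2, "theta3": 0.2}
        mean, cov = L.implied_moments(params, spec)
        y = np.array([[2.5, np.nan, 3.5], [3.0, 3.0, 3.0]])
        ds = L.WideDataset(y=y, wave_times=list(TIMES))
        obs = [0, 2]
        expected = (
            stats.multivariate_normal(mean[obs], cov[np.ix_(obs, obs)]).logpdf(y[0, obs])
            + stats.multivariate_normal(mean, cov).logpdf(y[1])
        )
        assert L.fiml_loglik(params, spec, ds) == pytest.approx(expected, abs=1e-10)


class TestFitting:
    def test_listwise_equals_fiml_on_complete_data(self, small_complete, spec):
        ld = L.fit_lgm_listwise(small_complete, spec)
        ml = L.fit_lgm_fiml(small_complete, spec)
        for k in ld.params:
            assert ld.params[k] == pytest.approx(ml.params[k], abs=1e-6)
        assert ld.loglik == pytest.approx(ml.loglik, abs=1e-6)

    def test_listwise_equals_fiml_on_complete_subset(self, preset_dataset, spec):
        masked, _, _ = preset_dataset
        ld = L.fit_lgm_listwise(masked, spec)
        ml_cc = L.fit_lgm_fiml(masked.complete_cases(), spec)
        assert ld.n_used == masked.mask.all(axis=1).sum()
        for k in ld.params:
            assert ld.params[k] == pytest.approx(ml_cc.params[k], abs=1e-6)

    def test_zero_noise_recovers_means_exactly(self, spec):
        p = L.GrowthParams(mu_I=3.0, mu_S=-0.1, psi_II=0, psi_SS=0, theta=0)
        ds, _ = L.simulate_growth(40, np.array(TIMES), p, seed=2)
        est = L.fit_lgm_listwise(ds, spec)
        assert est.params["mu_I"] == pytest.approx(3.0, abs=1e-5)
        assert est.params["mu_S"] == pytest.approx(-0.1, abs=1e-5)
        for k, v in est.params.items():
            if k.startswith(("psi_II", "psi_SS", "theta")):
                assert v < 1e-6

    def test_se_shrinks_like_root_n(self, spec):
        p = L.GrowthParams(mu_I=3.2, mu_S=-0.06, psi_II=0.4, psi_SS=0.02, theta=0.27)
        ds1, _ = L.simulate_growth(400, np.array(TIMES), p, seed=31)
        ds2, _ = L.simulate_growth(1600, np.array(TIMES), p, seed=32)
        se1 = L.fit_lgm_fiml(ds1, spec).se["mu_I"]
        se2 = L.fit_lgm_fiml(ds2, spec).se["mu_I"]
        assert 1.6 < se1 / se2 < 2.5

    def test_fiml_handles_all_patterns(self, tiny_incomplete, spec):
        est = L.fit_lgm_fiml(tiny_incomplete, spec)
        assert est.converged
        assert est.n_used == 18


class TestAuxiliaryFiml:
    def test_constant_auxiliary_rejected(self, preset_dataset, spec):
        import pandas as pd
        masked, _, _ = preset_dataset
        ds = masked.subset(np.arange(200))
        ds.aux = pd.DataFrame({"c": np.ones(200)})
        with pytest.raises(ConfigurationError, match="zero variance"):
            L.fit_lgm_fiml_aux(ds, spec)

    def test_uninformative_auxiliary_leaves_estimates_close(self, preset_dataset, spec):
        masked, _, _ = preset_dataset
        import pandas as pd
        rng = np.random.default_rng(77)
        ds = masked.subset(np.arange(masked.n))
        ds.aux = pd.DataFrame({"noise": rng.standard_normal(ds.n)})
        ml = L.fit_lgm_fiml(ds, spec)
        mla = L.fit_lgm_fiml_aux(ds, spec)
        # an auxiliary independent of outcome and missingness carries no
        # information, so growth estimates should sit within sampling noise
        for k in ("mu_I", "mu_S"):
            assert abs(mla.params[k] - ml.params[k]) < 2 * ml.se[k]


class TestWaldSummary:
    def _est(self, value, se):
        return GrowthEstimates(
            technique="X", params={"mu_S": value}, se={"mu_S": se},
            loglik=0.0, n_used=10, converged=True,
        )

    def test_z_two_gives_one_star(self):
        tab = L.wald_summary(self._est(1.0, 0.5))
        row = tab.iloc[0]
        assert row["z"] == pytest.approx(2.0)
        assert row["p"] == pytest.approx(0.0455, abs=1e-4)
        assert row["stars"] == "*"

    def test_zero_estimate_no_stars(self):
        row = L.wald_summary(self._est(0.0, 0.5)).iloc[0]
        assert row["z"] == 0.0
        assert row["stars"] == ""

    @pytest.mark.parametrize("alpha,stars_below,stars_at", [
        (0.05, "*", ""), (0.01, "**", "*"), (0.001, "***", "**"),
    ])
    def test_thresholds_are_strict(self, alpha, stars_below, stars_at):
        # p just above the threshold falls to the weaker tier, just below
        # earns the star: the boundary convention is a strict inequality
        z_above_p = stats.norm.isf(alpha * 1.001 / 2)
        assert L.wald_summary(self._est(z_above_p, 1.0)).iloc[0]["stars"] == stars_at
        z_below_p = stats.norm.isf(alpha * 0.999 / 2)
        assert L.wald_summary(self._est(z_below_p, 1.0)).iloc[0]["stars"] == stars_below

    def test_ci_is_symmetric(self):
        row = L.wald_summary(self._est(1.0, 0.5)).iloc[0]
        assert row["ci_low"] == pytest.approx(1 - 1.959964 * 0.5, abs=1e-4)
        assert row["ci_high"] == pytest.approx(1 + 1.959964 * 0.5, abs=1e-4)
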