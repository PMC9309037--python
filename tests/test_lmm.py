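import numpy as np
import pytest
from scipy import stats

from conftest import anova_one_way, dense_criterion, make_balanced, make_orthogonal_oneway
from fewlevels import (
    LMMSpec,
    ScenarioConfig,
    fit_lmm,
    is_singular,
    profiled_criterion,
    satterthwaite_test,
    simulate_dataset,
)
from fewlevels.datasets import Dataset
from fewlevels.lmm import _COEF_INDEX


class TestProfiledCriterion:
    def test_theta_zero_equals_ols_restricted_likelihood(self, dataset_a):
        """At theta = 0 the criterion collapses to the closed-form OLS
        restricted Gaussian likelihood of height ~ temperature."""
        y, t = dataset_a.height, dataset_a.temperature
        X = np.column_stack([np.ones_like(t), t])
        n, p = len(y), 2
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = rss[0] / (n - p)
        expected = (np.linalg.slogdet(X.T @ X)[1]
                    + (n - p) * (1 + np.log(2 * np.pi * s2)))
        got = profiled_criterion(dataset_a, LMMSpec("M4"), [0.0])
        assert got == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("model_id,theta", [
        ("M4", [0.3]),
        ("M10", [0.2, 0.05]),
        ("M11", [0.25, -0.1, 0.15]),
    ])
    def test_matches_dense_matrix_evaluation(self, model_id, theta):
        """Woodbury-based criterion equals a brute-force dense n x n
        computation for every random-effect structure."""
        ds = make_balanced(4, 25, var_intercept=0.2, var_slope=0.1, seed=13)
        for estimator in ("REML", "ML"):
            spec = LMMSpec(model_id, estimator=estimator)
            assert profiled_criterion(ds, spec, theta) == pytest.approx(
                dense_criterion(ds, spec, theta), rel=1e-9)

    def test_row_permutation_invariance(self, dataset_b):
        perm = np.random.default_rng(0).permutation(dataset_b.n)
        shuffled = Dataset(
            height=dataset_b.height[perm],
            temperature=dataset_b.temperature[perm],
            mountain=dataset_b.mountain[perm],
            per_level_counts=dataset_b.per_level_counts,
        )
        spec = LMMSpec("M10")
        assert profiled_criterion(shuffled, spec, [0.1, 0.1]) == pytest.approx(
            profiled_criterion(dataset_b, spec, [0.1, 0.1]), rel=1e-10)

    def test_constant_covariate_raises_rank_error(self):
        ds = make_balanced(3, 10, seed=1)
        flat = Dataset(height=ds.height, temperature=np.zeros(ds.n),
                       mountain=ds.mountain, per_level_counts=ds.per_level_counts)
        with pytest.raises(ValueError, match="temperature"):
            profiled_criterion(flat, LMMSpec("M4"), [0.1])


class TestAgainstLme4:
    """Frozen reference values computed with lme4 1.1-37 / lmerTest 3.1-3
    on datasets regenerated deterministically by the simulator."""

    def test_reml_criterion_and_theta_scenario_a(self, dataset_a):
        fit = fit_lmm(dataset_a, LMMSpec("M4"))
        assert fit.criterion == pytest.approx(2886.8597701877, abs=1e-6)
        assert fit.varcomp.theta[0] == pytest.approx(0.24830630, abs=1e-5)
        assert fit.varcomp.sigma2_resid == pytest.approx(1.03154471, rel=1e-6)
        assert not fit.singular

    def test_satterthwaite_scenario_a(self, dataset_a):
        fit = fit_lmm(dataset_a, LMMSpec("M4"))
        tr = satterthwaite_test(dataset_a, fit, "intercept")
        assert tr.estimate == pytest.approx(0.5034659472, rel=1e-6)
        assert tr.se == pytest.approx(0.11854421674, rel=1e-4)
        assert tr.df == pytest.approx(4.215374952, rel=1e-3)
        assert tr.p == pytest.approx(1.178522846e-02, rel=1e-3)
        ts = satterthwaite_test(dataset_a, fit, "slope")
        assert ts.df == pytest.approx(994.438857384, rel=1e-3)
        assert ts.p == pytest.approx(1.650138590e-34, rel=1e-2)

    def test_reml_criterion_and_tests_scenario_b(self, dataset_b):
        fit = fit_lmm(dataset_b, LMMSpec("M10"))
        assert fit.criterion == pytest.approx(2215.5066830996, abs=1e-6)
        assert fit.varcomp.theta == pytest.approx([0.03625921, 0.11462237], abs=2e-5)
        tr = satterthwaite_test(dataset_b, fit, "slope")
        assert tr.df == pytest.approx(3.3100586, rel=1e-3)
        assert tr.p == pytest.approx(0.5430782276, rel=1e-3)
        ti = satterthwaite_test(dataset_b, fit, "intercept")
        assert ti.df == pytest.approx(2.468808175, rel=1e-3)
        assert ti.p == pytest.approx(0.1243555961, rel=1e-3)

    @pytest.mark.parametrize("seed,theta,p_slope", [
        (1000, (0.0, 0.090076), 0.90859),   # slope-only boundary, df ~ 1
        (1003, (0.0, 0.0), 0.00040),        # full collapse to pooled OLS, df = n - p
        (1006, (0.089461, 0.0), 0.02254),   # intercept-only boundary
    ])
    def test_boundary_fits_match_lmerTest(self, seed, theta, p_slope):
        """Singular (boundary) fits are the study's central edge case:
        theta and the Satterthwaite slope p must match the reference."""
        ds = simulate_dataset(ScenarioConfig(
            scenario="B", n_mountains=2, beta_intercept=0, beta_slope=0,
            var_intercept=0.01, var_slope=0.01, seed=seed))
        fit = fit_lmm(ds, LMMSpec("M10"))
        assert fit.singular
        assert fit.varcomp.theta == pytest.approx(theta, abs=2e-4)
        tr = satterthwaite_test(ds, fit, "slope")
        assert tr.p == pytest.approx(p_slope, rel=5e-3, abs=5e-5)


class TestFitLmm:
    def test_no_between_level_variance_collapses_to_boundary(self):
        """Levels sharing one intercept (MSB below MSW): the variance
        estimate hits zero and the fit is flagged singular."""
        found = 0
        for seed in range(30):
            ds = make_orthogonal_oneway(4, 30, var_intercept=0.0, resid_sd=0.01,
                                        seed=seed)
            sb, _ = anova_one_way(ds)
            if sb >= 0:
                continue
            fit = fit_lmm(ds, LMMSpec("M4"))
            assert fit.varcomp.sigma2_intercept < 1e-8
            assert fit.singular
            found += 1
            if found >= 3:
                break
        assert found >= 3

    def test_balanced_reml_equals_anova_closed_form(self):
        """On balanced random-intercept data with MSB > MSW, REML variance
        estimates equal the one-way ANOVA moment estimators."""
        checked = 0
        for seed in range(60):
            ds = make_orthogonal_oneway(5, 40, var_intercept=0.25, seed=seed)
            sb, se = anova_one_way(ds)
            if sb <= 0:
                continue
            fit = fit_lmm(ds, LMMSpec("M4"))
            assert fit.varcomp.sigma2_intercept == pytest.approx(sb, rel=1e-6)
            assert fit.varcomp.sigma2_resid == pytest.approx(se, rel=1e-6)
            checked += 1
            if checked >= 50:
                break
        assert checked >= 50

    def test_ml_residual_variance_below_reml(self):
        ds = make_balanced(4, 25, var_intercept=0.25, seed=8)
        reml = fit_lmm(ds, LMMSpec("M4", estimator="REML"))
        ml = fit_lmm(ds, LMMSpec("M4", estimator="ML"))
        assert ml.varcomp.sigma2_resid <= reml.varcomp.sigma2_resid + 1e-12

    def test_ml_reml_ratio_in_no_random_effect_limit(self):
        # with zero between-level variance both estimators hit theta = 0,
        # where sigma2_ML / sigma2_REML = (n - p) / n exactly (OLS forms)
        ds = make_balanced(4, 10, var_intercept=0.0, seed=21)
        reml = fit_lmm(ds, LMMSpec("M4", estimator="REML"))
        ml = fit_lmm(ds, LMMSpec("M4", estimator="ML"))
        assert reml.singular and ml.singular
        n, p = ds.n, 2
        ratio = ml.varcomp.sigma2_resid / reml.varcomp.sigma2_resid
        assert ratio == pytest.approx((n - p) / n, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self, dataset_b):
        """Independent implementation cross-check (different optimizer,
        different parameterization)."""
        smf = pytest.importorskip("statsmodels.formula.api")
        df = dataset_b.to_frame()
        res = smf.mixedlm("height ~ temperature", df, groups=df["mountain"],
                          re_formula="1", vc_formula={"t": "0 + temperature"},
                          ).fit(reml=True)
        fit = fit_lmm(dataset_b, LMMSpec("M10"))
        assert fit.beta == pytest.approx(np.asarray(res.fe_params), abs=1e-4)
        assert fit.varcomp.sigma2_resid == pytest.approx(res.scale, rel=1e-3)
        assert fit.varcomp.sigma2_intercept == pytest.approx(
            float(res.cov_re.iloc[0, 0]), abs=2e-4)

    def test_consistency_at_many_levels(self):
        """With 50 levels the median REML estimates recover the generating
        variances within 10%."""
        est_int, est_slope = [], []
        for seed in range(30):
            ds = simulate_dataset(ScenarioConfig(
                scenario="B", n_mountains=50, mean_plants_per_mountain=100,
                count_range=(20, 200), var_intercept=0.25, var_slope=0.25, seed=seed))
            fit = fit_lmm(ds, LMMSpec("M10"))
            est_int.append(fit.varcomp.sigma2_intercept)
            est_slope.append(fit.varcomp.sigma2_slope)
        assert np.median(est_int) == pytest.approx(0.25, rel=0.10)
        assert np.median(est_slope) == pytest.approx(0.25, rel=0.10)


class TestIsSingular:
    def _fit_with(self, model_id, theta, corr=None):
        ds = make_balanced(3, 10, seed=0)
        fit = fit_lmm(ds, LMMSpec(model_id))
        fit.varcomp.theta = np.asarray(theta, dtype=float)
        if corr is not None:
            fit.varcomp.correlation = corr
        return fit

    def test_zero_diagonal_is_singular(self):
        assert is_singular(self._fit_with("M10", [0.0, 0.3]))

    def test_near_unit_correlation_is_singular(self):
        fit = self._fit_with("M11", [0.5, 0.15, 0.3], corr=0.99999)
        assert is_singular(fit, tol=1e-4)

    def test_interior_estimate_is_not_singular(self):
        fit = self._fit_with("M11", [0.5, 0.06, 0.3], corr=0.2)
        assert not is_singular(fit)


class TestSatterthwaite:
    def test_balanced_intercept_df_is_m_minus_1(self):
        """Classical balanced one-way result: the population intercept is
        tested against the between-mountain variation."""
        ds = make_balanced(6, 50, var_intercept=1.0, seed=5)
        fit = fit_lmm(ds, LMMSpec("M4"))
        tr = satterthwaite_test(ds, fit, "intercept")
        assert tr.df == pytest.approx(5.0, rel=0.08)

    def test_collapsed_fit_recovers_ols_df(self):
        ds = make_balanced(4, 100, var_intercept=0.0, seed=17)
        fit = fit_lmm(ds, LMMSpec("M4"))
        assert fit.singular
        tr = satterthwaite_test(ds, fit, "slope")
        assert tr.df == pytest.approx(ds.n - 2, rel=0.05)

    def test_sign_symmetry(self, dataset_b):
        flipped = Dataset(height=-dataset_b.height, temperature=dataset_b.temperature,
                          mountain=dataset_b.mountain,
                          per_level_counts=dataset_b.per_level_counts)
        spec = LMMSpec("M10")
        t1 = satterthwaite_test(dataset_b, fit_lmm(dataset_b, spec), "slope")
        t2 = satterthwaite_test(flipped, fit_lmm(flipped, spec), "slope")
        assert t2.estimate == pytest.approx(-t1.estimate, rel=1e-6)
        assert abs(t2.t) == pytest.approx(abs(t1.t), rel=1e-6)
        assert t2.df == pytest.approx(t1.df, rel=1e-4)
        assert t2.p == pytest.approx(t1.p, rel=1e-4)

    def test_unknown_coefficient_raises(self, dataset_b):
        fit = fit_lmm(dataset_b, LMMSpec("M10"))
        with pytest.raises(ValueError):
            satterthwaite_test(dataset_b, fit, "altitude")

    def test_null_p_values_are_uniform(self):
        """The correctly specified model's slope p-values under the null
        are approximately uniform (KS statistic < 0.05 at 1000 reps)."""
        ps = []
        for seed in range(1000):
            ds = simulate_dataset(ScenarioConfig(
                scenario="A", n_mountains=4, mean_plants_per_mountain=50,
                count_range=(10, 150), beta_intercept=0, beta_slope=0,
                var_intercept=0.25, seed=seed))
            fit = fit_lmm(ds, LMMSpec("M4"))
            ps.append(satterthwaite_test(ds, fit, "slope").p)
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05
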