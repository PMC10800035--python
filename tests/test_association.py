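import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetassoc.association import (
    analysis_grid,
    association_test,
    cohort_summary,
    fit_logistic,
    pearson_corr,
    proportion_test,
    students_ttest,
)
from hetassoc.heterozygosity import compute_het_profiles, compute_strata
from hetassoc.simulate import SimulationConfig, generate_cohort

from conftest import make_samples
from oracles import logistic_grid_oracle


class TestFitLogistic:
    def test_matches_grid_search_oracle(self, rng):
        """MLE and log-likelihood agree with a nested grid search on small data."""
        for _ in range(3):
            x = rng.normal(size=12)
            y = (rng.random(12) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
            if y.min() == y.max():
                continue
            X = np.column_stack([np.ones(12), x])
            fit = fit_logistic(y, X)
            if not fit.converged:
                continue  # separated draw: covered by the dedicated test
            b0, b1, ll = logistic_grid_oracle(y, x)
            assert fit.beta[0] == pytest.approx(b0, abs=1e-3)
            assert fit.beta[1] == pytest.approx(b1, abs=1e-3)
            assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_agrees_with_statsmodels(self, rng):
        """Independent cross-check against a reference GLM implementation."""
        import statsmodels.api as sm

        x = rng.normal(size=(200, 2))
        eta = -0.5 + x @ [0.7, -0.3]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(200), x])
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_null_predictor_small_beta(self, rng):
        x = rng.standard_normal(500)
        y = (rng.random(500) < 0.5).astype(float)
        fit = fit_logistic(y, np.column_stack([np.ones(500), x]))
        assert fit.converged
        assert abs(fit.beta[1]) < 4 * fit.se[1] + 0.3

    def test_perfect_separation_flagged(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        fit = fit_logistic(y, np.column_stack([np.ones(6), x]))
        assert not fit.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(5), np.ones((5, 1)))


def _profiles_and_samples(n=400, n_snps=3000, beta_het=np.log(0.6), seed=0,
                          both_strata=False, **kw):
    cfg = SimulationConfig(
        n_samples=n, case_fraction=0.5, n_snps=n_snps, seed=seed,
        beta_het=beta_het, f_dist=("normal_truncated", 0.05, 0.05),
        n_x_snps=0, missing_rate=0.0, beta_age=0.0, beta_bmi=0.0,
        cov_f_age=0.0, cov_f_bmi=0.0, **kw,
    )
    g, s, truth = generate_cohort(cfg)
    prof = (compute_strata(g) if both_strata else compute_het_profiles(g, 0.01))
    return prof, s, truth


class TestAssociationTest:
    def test_protective_effect_recovered(self):
        prof, s, truth = _profiles_and_samples(n=800, n_snps=5000, seed=5)
        res = association_test(prof, s, "het_excess", "all_oa", [])
        assert res.or_per_sd < 1
        assert res.converged
        # truth is OR 0.6 per SD of the propensity; generous band at this n
        assert res.or_per_sd == pytest.approx(0.6, abs=0.15)

    def test_null_is_null(self):
        prof, s, _ = _profiles_and_samples(beta_het=0.0, seed=6)
        res = association_test(prof, s, "het_rate", "all_oa", [])
        assert res.ci_low < 1 < res.ci_high

    def test_same_n_across_metrics(self):
        prof, s, _ = _profiles_and_samples(seed=7)
        r1 = association_test(prof, s, "het_rate", "all_oa", ["age", "sex", "bmi"])
        r2 = association_test(prof, s, "het_excess", "all_oa", ["age", "sex", "bmi"])
        assert (r1.n_case, r1.n_control) == (r2.n_case, r2.n_control)

    def test_or_and_ci_consistency(self):
        prof, s, _ = _profiles_and_samples(seed=8)
        r = association_test(prof, s, "het_excess", "hip", ["age"])
        assert r.or_per_sd == pytest.approx(np.exp(r.beta))
        assert r.ci_low < r.or_per_sd < r.ci_high
        assert r.ci_low == pytest.approx(np.exp(r.beta - 1.96 * r.se))

    def test_unknown_covariate(self):
        prof, s, _ = _profiles_and_samples(seed=9, n=100, n_snps=500)
        with pytest.raises(ValueError, match="covariate"):
            association_test(prof, s, "het_rate", "all_oa", ["height"])

    def test_subgroup_keeps_all_controls(self):
        prof, s, _ = _profiles_and_samples(seed=10)
        full = association_test(prof, s, "het_rate", "all_oa", [])
        hip = association_test(prof, s, "het_rate", "hip", [])
        assert hip.n_control == full.n_control
        assert hip.n_case < full.n_case


class TestAnalysisGrid:
    def test_twelve_cells_all_protective(self):
        prof, s, _ = _profiles_and_samples(
            n=1000, n_snps=5000, beta_het=np.log(0.5), seed=11, both_strata=True,
        )
        grid = analysis_grid(prof, s, [])
        assert len(grid) == 12
        assert (grid.or_per_sd < 1).all()
        assert grid.groupby(["stratum", "metric"]).size().eq(3).all()

    def test_deterministic_order(self):
        prof, s, _ = _profiles_and_samples(seed=12, both_strata=True,
                                           n=200, n_snps=1000)
        grid = analysis_grid(prof, s, [])
        assert list(grid.stratum[:6]) == ["maf_gt_001"] * 6
        assert list(grid.subgroup[:3]) == ["all_oa", "hip", "knee"]


class TestDescriptives:
    def test_pearson_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_matches_direct_formula(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson_corr(x, y)
        want = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(want, abs=1e-12)

    def test_pearson_errors(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_ttest_hand_formula(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p = students_ttest(x, y)
        # pooled sd = 1, se = sqrt(2/3), t = -3/se
        assert t == pytest.approx(-3 / np.sqrt(2 / 3))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4))

    def test_ttest_symmetry_and_identity(self):
        x, y = [1.0, 2.0, 3.0], [1.5, 2.5, 3.1]
        t1, p1 = students_ttest(x, y)
        t2, p2 = students_ttest(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
        t0, p0 = students_ttest(x, x)
        assert t0 == 0 and p0 == pytest.approx(1.0)

    def test_proportion_test(self):
        assert proportion_test(10, 20, 10, 20) == pytest.approx(1.0)
        # 20/20 vs 0/20: chi2 = 40 on 1 df
        p = proportion_test(20, 20, 0, 20)
        assert p == pytest.approx(stats.chi2.sf(40, 1))
        assert p < 1e-6
        assert proportion_test(3, 10, 7, 12) == pytest.approx(
            proportion_test(7, 12, 3, 10)
        )

    def test_cohort_summary(self, toy_cohort):
        _, s = toy_cohort
        out = cohort_summary(s).set_index("group")
        case = s.df[s.df.status == "case"]
        assert out.loc["case", "n"] == 3
        assert out.loc["case", "mean_age"] == pytest.approx(case.age.mean())
        assert out.loc["case", "sd_bmi"] == pytest.approx(case.bmi.std(ddof=1))
        assert out.loc["case", "pct_female"] == pytest.approx(100 * 2 / 3)
        assert out.loc["hip", "n"] + out.loc["knee", "n"] == out.loc["case", "n"]

    def test_cohort_summary_identical_groups(self):
        rows = [("A%d" % i, "case", "knee", 60.0, "female", 30.0, "no") for i in range(3)]
        rows += [("B%d" % i, "control", "none", 60.0, "female", 30.0, "no") for i in range(3)]
        out = cohort_summary(make_samples(rows)).set_index("group")
        assert out.loc["case", "p_sex"] == pytest.approx(1.0)
        assert np.isnan(out.loc["case", "p_age"])  # zero variance -> no t-test


class TestCalibration:
    def test_type_one_error_fast_null(self, rng):
        """p-values of the score of a null logistic model are uniform enough:
        rejection rate at 0.05 is within Monte-Carlo error over 400 fits."""
        n, reps, hits = 120, 400, 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = (rng.random(n) < 0.5).astype(float)
            if y.min() == y.max():
                continue
            fit = fit_logistic(y, np.column_stack([np.ones(n), x]))
            z = fit.beta[1] / fit.se[1]
            if 2 * stats.norm.sf(abs(z)) < 0.05:
                hits += 1
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
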