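"""Chromatophore-index statistics, beta regression and comparison tests.

The in-package beta-regression MLE is cross-checked against the independent
statsmodels implementation; the nonparametric tests are cross-checked against
scipy and against exhaustive permutation/brute-force enumeration.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from picover.pigstats import (
    DARK_PIC_INTERCEPT,
    DARK_PIC_SLOPE,
    Link,
    compare_links_aic,
    compute_ci,
    fit_beta_regression,
    friedman_test,
    linear_concordance,
    predict_pic_from_ci,
    wilcoxon_signed_rank,
)


def simulate_log_link(n, seed, beta0=DARK_PIC_INTERCEPT, beta1=DARK_PIC_SLOPE, phi=200.0):
    rng = np.random.default_rng(seed)
    ci = rng.choice(np.arange(1, 5.01, 0.5), n)
    mu = np.exp(beta0 + beta1 * ci)
    pic = rng.beta(mu * phi, (1 - mu) * phi)
    return pic, ci


class TestComputeCi:
    def test_uniform_maximum_class(self):
        assert compute_ci([5, 5, 5, 5]).ci == 5.0

    def test_mean_of_classes(self):
        assert compute_ci([1, 2, 3, 4, 5]).ci == 3.0

    def test_overlap_rule_takes_maximum_index(self):
        rec = compute_ci([], overlap_flag=True)
        assert rec.ci == 5.0 and rec.overlap_flag

    def test_empty_without_overlap_errors(self):
        with pytest.raises(ValueError):
            compute_ci([], overlap_flag=False)

    def test_classes_outside_scale_rejected(self):
        with pytest.raises(ValueError):
            compute_ci([2, 6])


class TestPredictPicFromCi:
    @pytest.mark.parametrize(
        "ci,expected",
        [(5.0, np.exp(-0.067)), (1.0, np.exp(-2.703)), (3.0, np.exp(-1.385))],
    )
    def test_direct_evaluation_of_calibration(self, ci, expected):
        assert predict_pic_from_ci(ci) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("ci", [0.0, 0.99, 5.01, -1.0])
    def test_outside_validity_domain_errors(self, ci):
        with pytest.raises(ValueError, match="valid"):
            predict_pic_from_ci(ci)

    def test_strictly_increasing_on_domain(self):
        grid = np.linspace(1, 5, 201)
        preds = [predict_pic_from_ci(c) for c in grid]
        assert all(b > a for a, b in zip(preds, preds[1:]))


class TestFitBetaRegression:
    def test_parameter_recovery_large_n(self):
        # mean stays inside (0,1) over the CI grid: exp(-3+0.4*5) < 1
        pic, ci = simulate_log_link(2000, seed=42, beta0=-3.0, beta1=0.4, phi=50.0)
        fit = fit_beta_regression(pic, ci, Link.LOG)
        assert fit.intercept == pytest.approx(-3.0, abs=0.05)
        assert fit.slope == pytest.approx(0.4, abs=0.05)

    @pytest.mark.parametrize("link", list(Link))
    def test_matches_statsmodels_oracle(self, link):
        import statsmodels.api as sm
        from statsmodels.othermod.betareg import BetaModel

        sm_links = {
            Link.LOGIT: sm.families.links.Logit(),
            Link.LOG: sm.families.links.Log(),
            Link.LOGLOG: sm.families.links.LogLog(),
        }
        pic, ci = simulate_log_link(400, seed=7)
        fit = fit_beta_regression(pic, ci, link)
        res = BetaModel(
            pic, sm.add_constant(ci), link=sm_links[link]
        ).fit(disp=0)
        assert fit.intercept == pytest.approx(res.params[0], abs=1e-4)
        assert fit.slope == pytest.approx(res.params[1], abs=1e-4)
        assert fit.phi == pytest.approx(np.exp(res.params[2]), rel=1e-3)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * res.llf + 6, abs=1e-6)

    def test_refit_is_deterministic(self):
        pic, ci = simulate_log_link(100, seed=3)
        f1 = fit_beta_regression(pic, ci, Link.LOGIT)
        f2 = fit_beta_regression(pic, ci, Link.LOGIT)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert f1.beta == f2.beta

    def test_boundary_values_are_compressed_not_fatal(self):
        pic, ci = simulate_log_link(50, seed=5)
        pic[0], pic[1] = 0.0, 1.0
        fit = fit_beta_regression(pic, ci, Link.LOGIT)
        assert np.isfinite(fit.loglik)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_beta_regression([0.2, 0.3, 0.4, 0.5], [2, 2, 2, 2])

    def test_underdetermined_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_regression([0.2, 0.3, 0.4], [1, 2, 3])

    def test_pseudo_r2_high_for_tight_data(self):
        pic, ci = simulate_log_link(200, seed=11, phi=400.0)
        fit = fit_beta_regression(pic, ci, Link.LOG)
        assert fit.pseudo_r2 > 0.9


class TestCompareLinksAic:
    def test_log_truth_ranks_log_first(self):
        pic, ci = simulate_log_link(300, seed=21, phi=50.0)
        ranked = compare_links_aic(pic, ci)
        assert ranked[0][0].link is Link.LOG
        assert ranked[0][1] == 0.0
        assert all(d >= 0 for _, d in ranked)
        aics = [f.aic for f, _ in ranked]
        assert aics == sorted(aics)

    def test_underdetermined_errors(self):
        with pytest.raises(ValueError):
            compare_links_aic([0.1, 0.2, 0.3], [1, 2, 3])


class TestFriedman:
    def test_consistent_ranks_hand_value(self):
        # 4 blocks, 3 treatments, identical ordering everywhere:
        # chi2 = 12/(4*3*4) * (16+64+144) - 3*4*4 = 8
        table = np.array([[1, 2, 3]] * 4, dtype=float) * [1, 10, 100]
        chi2, df, p = friedman_test(np.tile([1.0, 2.0, 3.0], (4, 1)))
        assert chi2 == pytest.approx(8.0) and df == 2
        assert p == pytest.approx(stats.chi2.sf(8.0, 2))

    def test_identical_columns_give_zero_statistic(self):
        table = np.tile(np.arange(4, dtype=float)[:, None], (1, 3))
        chi2, df, p = friedman_test(table)
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(13)
        table = np.round(rng.random((10, 4)) * 5)  # coarse values force ties
        chi2, df, p = friedman_test(table)
        ref = stats.friedmanchisquare(*(table[:, j] for j in range(4)))
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_two_treatments_against_permutation_oracle(self):
        # k = 2 (scipy refuses this); exhaustive within-block permutations
        table = np.array(
            [[0.2, 0.5], [0.1, 0.4], [0.6, 0.3], [0.2, 0.9], [0.1, 0.7], [0.3, 0.8]]
        )
        chi2, df, p = friedman_test(table)
        n = table.shape[0]
        # closed form for k=2 without ties: chi2 = (sum of +-1 signs)^2 / n
        signs = np.sign(table[:, 1] - table[:, 0])
        assert chi2 == pytest.approx(signs.sum() ** 2 / n, abs=1e-12)
        stats_perm = []
        for flips in itertools.product([False, True], repeat=n):
            t = table.copy()
            for i, fl in enumerate(flips):
                if fl:
                    t[i] = t[i, ::-1]
            s = friedman_test(t)[0]
            stats_perm.append(s)
            fl_signs = np.sign(t[:, 1] - t[:, 0])
            assert s == pytest.approx(fl_signs.sum() ** 2 / n, abs=1e-12)
        p_perm = np.mean([s >= chi2 - 1e-12 for s in stats_perm])
        assert df == 1
        # the chi-square approximation at six blocks is coarse (the exact
        # null distribution has atoms of mass ~0.2); allow that resolution
        assert abs(p - p_perm) < 0.2

    def test_constant_table_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((4, 3)))

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))


class TestWilcoxon:
    def test_all_positive_differences_hand_value(self):
        # W = 15, mu = 7.5, sigma = sqrt(13.75) -> Z ~ +2.023
        a = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        b = a - np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z, p = wilcoxon_signed_rank(a, b)
        assert z == pytest.approx(7.5 / np.sqrt(13.75), abs=1e-9)
        assert z == pytest.approx(2.023, abs=5e-4)

    def test_antisymmetric_differences_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + np.array([0.5, -0.5, 1.5, -1.5])
        z, p = wilcoxon_signed_rank(a, b)
        assert z == 0.0 and p == 1.0

    def test_single_nonzero_difference_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 5.0])

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(17)
        a = rng.random(12)
        b = a + rng.normal(0.1, 0.2, 12)
        z, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, correction=False, method="approx")
        assert abs(z) == pytest.approx(abs(ref.zstatistic), abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_p_matches_enumeration_and_tracks_approx(self):
        a = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        b = a - np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z, p_exact = wilcoxon_signed_rank(a, b, method="exact")
        assert p_exact == pytest.approx(2 / 32)  # only W=0 and W=15 as extreme
        _, p_approx = wilcoxon_signed_rank(a, b)
        assert abs(p_exact - p_approx) < 0.08

    def test_zero_differences_are_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.0, 1.0, 2.0, 3.0, 4.0])  # first pair ties
        z, _ = wilcoxon_signed_rank(a, b)
        mu = 4 * 5 / 4
        s2 = 4 * 5 * 9 / 24 - (4**3 - 4) / 48  # all four |d| tied
        assert z == pytest.approx((10 - mu) / np.sqrt(s2))


class TestLinearConcordance:
    def test_perfect_identity(self):
        x = np.linspace(0, 1, 10)
        slope, intercept, r2 = linear_concordance(x, x)
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_line_recovered(self):
        x = np.linspace(0, 1, 10)
        slope, intercept, r2 = linear_concordance(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_noisy_identity_matches_closed_form_ols(self):
        rng = np.random.default_rng(23)
        x = rng.random(50)
        y = x + rng.normal(0, 0.01, 50)
        slope, intercept, r2 = linear_concordance(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
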