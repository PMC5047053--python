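"""Study statistics against independent references and brute-force oracles."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from osteowave import experiment_stats as es


class TestPooledT:
    def test_published_alkaline_phosphatase_example(self):
        # USG 86.38 +/- 18.94 (n=8) vs CG 82.86 +/- 10.03 (n=7)
        r = es.pooled_t_test(es.GroupSummary(86.38, 18.94, 8), es.GroupSummary(82.86, 10.03, 7))
        assert r.df == 13
        assert r.statistic == pytest.approx(0.440, abs=1e-3)
        assert r.ci_low == pytest.approx(-13.79, abs=0.02)
        assert r.ci_high == pytest.approx(20.82, abs=0.02)
        assert r.p == pytest.approx(0.67, abs=0.01)

    def test_equal_summaries_give_zero_t(self):
        g = es.GroupSummary(10.0, 2.0, 6)
        r = es.pooled_t_test(g, g)
        assert r.statistic == 0.0
        assert r.ci_low == pytest.approx(-r.ci_high)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = es.GroupSummary(rng.normal(0, 10), rng.uniform(0.5, 5), rng.integers(2, 30))
            b = es.GroupSummary(rng.normal(0, 10), rng.uniform(0.5, 5), rng.integers(2, 30))
            r = es.pooled_t_test(a, b)
            t_ref, p_ref = sps.ttest_ind_from_stats(
                a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
            )
            assert r.statistic == pytest.approx(t_ref, rel=1e-10)
            assert r.p == pytest.approx(p_ref, rel=1e-10)

    def test_antisymmetry(self):
        a = es.GroupSummary(5.0, 1.0, 8)
        b = es.GroupSummary(3.0, 2.0, 9)
        r1, r2 = es.pooled_t_test(a, b), es.pooled_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
        assert r1.ci_low == pytest.approx(-r2.ci_high, rel=1e-12)

    def test_zero_variance_cases(self):
        g = es.GroupSummary(4.0, 0.0, 5)
        assert es.pooled_t_test(g, g).statistic == 0.0
        with pytest.raises(ValueError):
            es.pooled_t_test(g, es.GroupSummary(5.0, 0.0, 5))


def brute_force_u(x, y):
    """min(U_x, U_y) by direct pair counting with half-credit ties."""
    ux = sum(1.0 if xi < yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y)
    return min(ux, len(x) * len(y) - ux)


class TestMannWhitney:
    def test_complete_separation(self):
        assert es.mann_whitney_u([1, 2, 3], [4, 5, 6]).statistic == 0.0

    def test_identical_multisets(self):
        x = [1, 2, 2, 3]
        assert es.mann_whitney_u(x, list(x)).statistic == pytest.approx(len(x) ** 2 / 2)

    def test_matches_pair_count_oracle_on_random_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            nx, ny = rng.integers(2, 9, size=2)
            x = rng.integers(0, 6, size=nx)  # heavy ties, ordinal-like
            y = rng.integers(0, 6, size=ny)
            r = es.mann_whitney_u(x, y)
            assert r.statistic == pytest.approx(brute_force_u(x, y), abs=1e-9)

    def test_symmetric_in_group_order(self):
        x, y = [0, 1, 1, 2, 3], [1, 2, 2, 2]
        assert es.mann_whitney_u(x, y).statistic == es.mann_whitney_u(y, x).statistic

    def test_scipy_cross_check_large_samples(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 9, size=15)
        y = rng.integers(0, 9, size=14)
        r = es.mann_whitney_u(x, y)
        u_scipy = sps.mannwhitneyu(x, y, alternative="two-sided")
        u_min = min(u_scipy.statistic, len(x) * len(y) - u_scipy.statistic)
        assert r.statistic == pytest.approx(u_min)
        assert r.p == pytest.approx(u_scipy.pvalue, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            es.mann_whitney_u([], [1, 2])


class TestKappa:
    def test_identical_raters_give_one(self):
        assert es.cohens_kappa([0, 1, 2, 0, 1], [0, 1, 2, 0, 1]) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(12)
        r1 = rng.integers(0, 4, size=10_000)
        r2 = rng.integers(0, 4, size=10_000)
        assert abs(es.cohens_kappa(r1, r2)) < 0.03

    def test_bounded_by_observed_agreement(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(5, 40)
            r1 = rng.integers(0, 3, size=n)
            r2 = rng.integers(0, 3, size=n)
            try:
                k = es.cohens_kappa(r1, r2)
            except ValueError:
                continue
            assert k <= np.mean(r1 == r2) + 1e-12

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        r1 = rng.integers(0, 3, size=60)
        r2 = rng.integers(0, 3, size=60)
        relabel = {0: 7, 1: 5, 2: 9}
        k1 = es.cohens_kappa(r1, r2)
        k2 = es.cohens_kappa([relabel[v] for v in r1], [relabel[v] for v in r2])
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(19)
        for _ in range(20):
            r1 = rng.integers(0, 4, size=30)
            r2 = np.where(rng.random(30) < 0.7, r1, rng.integers(0, 4, size=30))
            assert es.cohens_kappa(r1, r2) == pytest.approx(
                cohen_kappa_score(r1, r2), rel=1e-10
            )

    def test_constant_identical_raters_undefined(self):
        with pytest.raises(ValueError):
            es.cohens_kappa([2, 2, 2], [2, 2, 2])


class TestKsNormality:
    def test_large_normal_sample_not_rejected(self):
        x = np.random.default_rng(1).normal(0, 1, 5000)
        r = es.ks_normality(x, seed=2)
        assert r.p > 0.05
        assert 0.0 <= r.statistic <= 1.0

    def test_statistic_matches_brute_force_scan(self):
        x = np.random.default_rng(6).normal(3, 2, 40)
        r = es.ks_normality(x, n_sim=50, seed=0)
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        n = len(z)
        d = max(
            max(abs((i + 1) / n - sps.norm.cdf(v)), abs(i / n - sps.norm.cdf(v)))
            for i, v in enumerate(z)
        )
        assert r.statistic == pytest.approx(d, rel=1e-12)

    def test_statsmodels_lilliefors_cross_check(self):
        from statsmodels.stats.diagnostic import lilliefors

        x = np.random.default_rng(9).normal(0, 1, 100)
        d_ref, _ = lilliefors(x, dist="norm")
        assert es.ks_normality(x, n_sim=50, seed=0).statistic == pytest.approx(d_ref, rel=1e-9)

    def test_uniform_sample_rejected(self):
        x = np.random.default_rng(2).uniform(0, 1, 2000)
        assert es.ks_normality(x, seed=3).p < 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            es.ks_normality([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            es.ks_normality([1.0, 2.0])


class TestSampleSize:
    def test_published_design_effect_size(self):
        # d = 1.2, two-tailed alpha 0.05, power 0.8
        assert es.sample_size_cohens_d(1.2, 0.05, 0.8) == 12

    def test_classic_medium_effect(self):
        assert es.sample_size_cohens_d(0.5, 0.05, 0.8) == 64

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.4, 0.8, 1.2):
            n = es.sample_size_cohens_d(d, 0.05, 0.8)
            n_ref = TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.8)
            assert n == int(np.ceil(n_ref))

    @settings(derandomize=True, max_examples=30)
    @given(d=st.floats(0.2, 2.0), d2=st.floats(0.2, 2.0))
    def test_monotone_in_effect_size(self, d, d2):
        lo, hi = sorted([d, d2])
        assert es.sample_size_cohens_d(hi) <= es.sample_size_cohens_d(lo)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            es.sample_size_cohens_d(0.0)
        with pytest.raises(ValueError):
            es.sample_size_cohens_d(1.0, alpha=1.5)


class TestRadiographScore:
    def test_maximum_total_is_eight(self):
        assert es.score_radiograph(3, 3, 2).total == 8
        assert es.MAX_TOTAL_SCORE == 8

    @pytest.mark.parametrize(
        "p,u,r,total", [(0, 0, 0, 0), (2, 3, 1, 6), (1, 1, 2, 4)]
    )
    def test_totals(self, p, u, r, total):
        assert es.score_radiograph(p, u, r).total == total

    @pytest.mark.parametrize("bad", [(4, 0, 0), (0, 4, 0), (0, 0, 3), (-1, 0, 0)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            es.score_radiograph(*bad)
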