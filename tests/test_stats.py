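"""Statistical battery: tests against independent closed-form and exact oracles."""

import math
from math import comb

import numpy as np
import pytest

from peristim import (
    assumption_checks,
    cohens_d,
    one_way_anova,
    proportion_test,
    students_t,
    tukey_hsd,
)


# ---------------------------------------------------------------- oracles

def fisher_exact_oracle(k1, n1, k2, n2, mid_p=False):
    """Two-sided Fisher p by hypergeometric enumeration (independent oracle).

    ``mid_p=True`` gives the mid-p variant (half weight on the observed
    table), the standard comparator for asymptotic tests since the plain
    Fisher p is conservative at small counts.
    """
    K = k1 + k2
    denom = comb(n1 + n2, K)
    lo, hi = max(0, K - n2), min(n1, K)
    pmf = {k: comb(n1, k) * comb(n2, K - k) / denom for k in range(lo, hi + 1)}
    p_obs = pmf[k1]
    if mid_p:
        below = sum(p for p in pmf.values() if p < p_obs * (1 - 1e-9))
        ties = sum(p for p in pmf.values() if abs(p - p_obs) <= p_obs * 1e-9)
        return below + 0.5 * ties
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def pooled_t_oracle(x1, x2):
    """Equal-variance two-sample t statistic from the closed form."""
    a, b = np.asarray(x1, float), np.asarray(x2, float)
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / a.size + 1 / b.size))


# ---------------------------------------------------------------- proportions

class TestProportionTest:
    def test_equal_proportions_give_z0_p1(self):
        r = proportion_test(30, 100, 30, 100)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_reconstructed_counts_significant(self):
        # 20% of 105 vs 36% of 95 neurons
        r = proportion_test(21, 105, 34, 95)
        assert r.p_value < 0.05
        assert fisher_exact_oracle(21, 105, 34, 95) < 0.05

    def test_extreme_table_below_point_001_by_exact_oracle(self):
        r = proportion_test(0, 10, 10, 10)
        assert r.p_value < 0.001
        assert fisher_exact_oracle(0, 10, 10, 10) < 0.001

    def test_small_expected_cells_use_exact_fallback(self):
        r = proportion_test(0, 3, 3, 3)
        assert "exact_fallback" in r.flags
        assert r.p_value == pytest.approx(fisher_exact_oracle(0, 3, 3, 3), abs=1e-9)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(0, 0, 1, 2)

    def test_count_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(5, 3, 1, 10)

    def test_exhaustive_small_tables_agree_with_exact_oracle(self):
        # all 2x2 tables with n1, n2 <= 15: the exact fallback must match the
        # enumeration oracle to near machine precision; the z branch (which
        # only fires with all expected cells >= 5) must stay within
        # normal-approximation distance of the exact test — within 0.2 of the
        # mid-p value and 0.35 of the (conservative) plain Fisher p
        for n1 in range(1, 16):
            for n2 in range(1, 16):
                for k1 in range(n1 + 1):
                    for k2 in range(n2 + 1):
                        r = proportion_test(k1, n1, k2, n2)
                        p_oracle = fisher_exact_oracle(k1, n1, k2, n2)
                        if "exact_fallback" in r.flags:
                            assert r.p_value == pytest.approx(p_oracle, abs=1e-9)
                        else:
                            p_mid = fisher_exact_oracle(k1, n1, k2, n2, mid_p=True)
                            assert abs(r.p_value - p_mid) <= 0.2
                            assert abs(r.p_value - p_oracle) <= 0.35


# ---------------------------------------------------------------- t / d / anova

class TestStudentsT:
    def test_identical_samples_give_t0_p1(self):
        r = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_matches_closed_form_pooled_t(self):
        x1, x2 = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        r = students_t(x1, x2)
        assert r.statistic == pytest.approx(pooled_t_oracle(x1, x2), rel=1e-12)
        assert r.statistic == pytest.approx(-12.247, abs=1e-3)

    def test_constant_equal_samples_flagged(self):
        r = students_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0
        assert "degenerate_variance" in r.flags

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        t = students_t(x1, x2)
        f = one_way_anova([x1, x2])
        assert f.statistic == pytest.approx(t.statistic**2, abs=1e-9)
        assert f.p_value == pytest.approx(t.p_value, abs=1e-9)


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_large_sample_standardized_shift_recovers_population_d(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(0.0, 1.0, 100_000)
        x2 = rng.normal(0.9, 1.0, 100_000)
        assert cohens_d(x2, x1) == pytest.approx(0.90, abs=0.02)

    def test_antisymmetry(self):
        x1, x2 = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0]
        assert cohens_d(x1, x2) == -cohens_d(x2, x1)

    def test_zero_pooled_sd_is_nan(self):
        assert math.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestAnovaTukey:
    def test_constant_groups_flagged_undefined(self):
        r = one_way_anova([[1.0, 1.0], [1.0, 1.0, 1.0]])
        assert math.isnan(r.statistic)
        assert "degenerate_variance" in r.flags

    def test_two_group_tukey_reproduces_t_test_p(self):
        rng = np.random.default_rng(12)
        x1, x2 = rng.normal(0, 1, 15), rng.normal(0.8, 1, 18)
        p_tukey = tukey_hsd([x1, x2])[(0, 1)].p_value
        p_t = students_t(x1, x2).p_value
        assert p_tukey == pytest.approx(p_t, abs=1e-6)

    def test_tukey_flags_exactly_the_shifted_group_pairs(self):
        # three groups, one mean shifted by 1.5 SD: in nearly all seeded runs
        # the two pairs involving the shifted group are the significant ones
        rng = np.random.default_rng(15)
        hits = 0
        reps = 300
        for _ in range(reps):
            g = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(1.5, 1, 30)]
            res = tukey_hsd(g)
            sig = {pair for pair, r in res.items() if r.p_value < 0.05}
            hits += sig == {(0, 2), (1, 2)}
        assert hits / reps >= 0.85


class TestAssumptions:
    def test_null_normality_pvalues_are_uniform(self):
        # Shapiro-Wilk p over repeated normal samples should look U(0,1)
        from scipy import stats as sps

        rng = np.random.default_rng(19)
        ps = [
            assumption_checks([rng.normal(0, 1, 50)])["normality"][0].p_value
            for _ in range(500)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_outlier_contamination_detected(self):
        # 10% of points displaced by 6 SD: normality should fail nearly always
        rng = np.random.default_rng(23)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = np.r_[rng.normal(0, 1, 45), rng.normal(6, 0.3, 5)]
            hits += assumption_checks([x])["normality"][0].p_value < 0.05
        assert hits / reps >= 0.95

    def test_levene_type_i_error_near_alpha(self):
        rng = np.random.default_rng(27)
        rej = 0
        reps = 1000
        for _ in range(reps):
            g = [rng.normal(0, 1, 25) for _ in range(3)]
            rej += assumption_checks(g)["variance_homogeneity"].p_value < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_small_sample_skips_normality_with_flag(self):
        out = assumption_checks([[1.0, 2.0], [1.0, 2.0, 3.0, 2.5]])
        assert out["normality"][0] is None
        assert any("skipped" in f for f in out["flags"])
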