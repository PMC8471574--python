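"""Group-comparison statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ednaquant import (
    pairwise_wilcoxon,
    rank_sum_test,
    significance_stars,
    spearman_correlation,
    two_sample_ttest,
)
from ednaquant.compare import adjust_pvalues


def exact_wilcoxon_oracle(a, b):
    """Two-sided rank-sum p by enumerating every group assignment of the
    pooled ranks (no ties assumed)."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n]) - n * (n + 1) / 2)
    center = n * m / 2.0
    count = total = 0
    for subset in itertools.combinations(range(n + m), n):
        u = float(np.sum(ranks[list(subset)]) - n * (n + 1) / 2)
        count += abs(u - center) >= abs(u_obs - center) - 1e-12
        total += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        _, p = rank_sum_test([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2 / 70, rel=1e-9)

    def test_exact_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(10)
        for n in range(1, 10):
            for m in range(1, 11 - n):
                a = rng.normal(size=n)
                b = rng.normal(0.8, size=m)
                _, p = rank_sum_test(a, b)
                assert p == pytest.approx(exact_wilcoxon_oracle(a, b), rel=1e-9), (n, m)

    def test_rank_invariance_under_log_transform(self):
        rng = np.random.default_rng(11)
        a = rng.lognormal(6, 2, size=15)
        b = rng.lognormal(8, 2, size=12)
        _, p_raw_scale = rank_sum_test(a, b)
        _, p_log_scale = rank_sum_test(np.log10(a + 1), np.log10(b + 1))
        assert p_raw_scale == pytest.approx(p_log_scale, rel=1e-12)

    def test_tied_large_sample_path(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 5, size=25).astype(float)
        b = rng.integers(1, 6, size=30).astype(float)
        _, p = rank_sum_test(a, b)
        assert 0 <= p <= 1

    def test_pairwise_family(self):
        rng = np.random.default_rng(13)
        groups = {
            "a": rng.normal(0, 1, 12),
            "b": rng.normal(2, 1, 12),
            "c": rng.normal(0.1, 1, 12),
        }
        out = pairwise_wilcoxon(groups)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-15).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon({"a": [1.0], "b": []})


class TestAdjustment:
    def test_holm_preserves_order(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=20)
        adj = adjust_pvalues(p, "holm")
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_none_is_identity(self):
        p = [0.01, 0.5]
        assert adjust_pvalues(p, "none").tolist() == p

    def test_stars_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"
        assert significance_stars(0.06) == "ns"
        assert significance_stars(0.05) == "ns"  # strict inequality


class TestTTest:
    def test_identical_groups(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_welch_statistic(self):
        res = two_sample_ttest([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        assert res.statistic == pytest.approx(-12.247, abs=1e-3)

    def test_constant_equal_groups_convention(self):
        res = two_sample_ttest([1.0, 1.0], [1.0, 1.0])
        assert res.p_raw == 1.0

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(15)
        sims = 2000
        a = rng.normal(size=(sims, 30))
        b = rng.normal(size=(sims, 30))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        down = spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert up.statistic == 1.0 and down.statistic == -1.0

    def test_exact_p_small_n(self):
        res = spearman_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_raw == pytest.approx(2 / 6, rel=1e-12)

    def test_ties_match_average_rank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 7.0, 9.0, 8.0, 8.0])
        res = spearman_correlation(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.statistic == pytest.approx(oracle, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1 = spearman_correlation(x, y).statistic
        r2 = spearman_correlation(np.exp(x), y**3).statistic
        assert r1 == pytest.approx(r2, rel=1e-12)
        assert -1 <= r1 <= 1

    def test_constant_input_undefined(self):
        res = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.statistic)
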