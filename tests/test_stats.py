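"""Statistical primitives against independent oracles and their invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mirisk.stats import (
    UndefinedStatisticError,
    bh_fdr,
    clopper_pearson,
    midranks,
    rank_sum_test,
    roc_auc,
    roc_auc_rank_pvalue,
    spearman,
    wilcoxon_signed_rank,
)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3, 4], [2, 4, 6, 8]).rho == 1.0
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).rho == -1.0

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties
                x = np.round(x, 1)
            got = spearman(x, y).rho
            expect = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_exact_small_n_p_equals_full_enumeration(self, rng):
        # independent enumeration over all orderings of y's ranks
        for n in (5, 6, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res2 = spearman(x, y, "two")
            res1 = spearman(x, y, "negative-one-sided")
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            rhos = [
                np.corrcoef(rx, np.array(p))[0, 1]
                for p in itertools.permutations(ry)
            ]
            exp2 = np.mean([abs(r) >= abs(res2.rho) - 1e-12 for r in rhos])
            exp1 = np.mean([r <= res1.rho + 1e-12 for r in rhos])
            assert res2.p_value == pytest.approx(exp2, abs=1e-12)
            assert res1.p_value == pytest.approx(exp1, abs=1e-12)

    def test_t_approximation_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_one_sided_negative_orientation(self, rng):
        x = np.arange(12.0)
        y = -x + rng.normal(size=12) * 0.5
        neg = spearman(x, y, "negative-one-sided")
        two = spearman(x, y, "two")
        assert neg.p_value < two.p_value
        pos = spearman(x, -y, "negative-one-sided")
        assert pos.p_value > 0.5

    def test_pairwise_complete_and_degenerate_errors(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
        y = [2.0, 1.0, 3.0, np.nan, 4.0, 8.0, 5.0, 7.0, 6.0, 9.0, 10.0]
        res = spearman(x, y)
        assert res.n == 9  # two incomplete pairs dropped
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 2], [3, 4])
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_monotone_invariance(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=15)
        y = r.normal(size=15)
        a = spearman(x, y).rho
        assert spearman(y, x).rho == pytest.approx(a, abs=1e-12)
        # strictly increasing transforms leave ranks unchanged
        assert spearman(np.exp(x), 3 * y + 1).rho == pytest.approx(a, abs=1e-12)


class TestRankSum:
    def test_fully_separated_exact_example(self):
        u, p = rank_sum_test([10, 11, 12], [1, 2, 3], "a_greater")
        assert u == 9.0
        assert p == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_identical_groups_two_sided(self):
        _, p = rank_sum_test([5, 5, 5], [5, 5, 5], "two_sided")
        assert p == 1.0

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(2, 6)))
            b = rng.normal(size=int(rng.integers(2, 6)))
            ranks = sps.rankdata(np.concatenate([a, b]))
            na, n = a.size, a.size + b.size
            u_obs = ranks[:na].sum() - na * (na + 1) / 2
            us = [
                sum(ranks[list(c)]) - na * (na + 1) / 2
                for c in itertools.combinations(range(n), na)
            ]
            _, p = rank_sum_test(a, b, "a_greater")
            assert p == pytest.approx(np.mean([u >= u_obs - 1e-9 for u in us]))

    def test_ties_match_monte_carlo_permutation(self):
        rng = np.random.default_rng(7)
        a = np.round(rng.normal(size=10), 0)
        b = np.round(rng.normal(0.3, 1, size=10), 0)
        u_obs, p = rank_sum_test(a, b, "a_greater")
        pooled = np.concatenate([a, b])
        reps = 100_000
        count = 0
        for _ in range(reps):
            perm = rng.permutation(pooled)
            r = sps.rankdata(perm)
            u = r[:10].sum() - 55.0
            if u >= u_obs - 1e-9:
                count += 1
        p_mc = count / reps
        se = math.sqrt(p_mc * (1 - p_mc) / reps)
        assert abs(p - p_mc) < 3 * se + 0.01  # normal approx + MC error

    def test_exact_and_normal_branches_agree_at_n6(self):
        # exhaustive over every achievable U at 6+6 tie-free: the one-sided
        # exact P and the continuity-corrected normal P agree within 0.01
        # (two-sided doubles the discrepancy to ~0.0155 by construction)
        ranks = np.arange(1, 13)
        us = np.array([
            sum(ranks[list(c)]) - 21
            for c in itertools.combinations(range(12), 6)
        ])
        mu, sd = 18.0, math.sqrt(6 * 6 * 13 / 12)
        for u in range(0, 37):
            p_exact = np.mean(us >= u - 1e-9)
            p_norm = sps.norm.sf((u - mu - 0.5) / sd)
            assert abs(p_exact - p_norm) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            rank_sum_test([], [1.0], "two_sided")


class TestWilcoxonSignedRank:
    def test_matches_scipy_exact(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(0.5, 1, size=10)
        w, p = wilcoxon_signed_rank(b, a, "two_sided")
        ref = sps.wilcoxon(b, a, alternative="two-sided", mode="exact")
        # scipy reports min(W+, W-); p-values must agree
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_one_sided_orientation(self, rng):
        a = rng.normal(size=15)
        b = a + 1.0
        _, p_up = wilcoxon_signed_rank(b, a, "a_greater")
        _, p_dn = wilcoxon_signed_rank(b, a, "a_less")
        assert p_up < 0.01 < p_dn


class TestBH:
    def test_single_p_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_matches_direct_step_up_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # direct: q_(i) = min_{j>=i} p_(j) * m / j
        m = 4
        expect = [min(p[j] * m / (j + 1) for j in range(i, m)) for i in range(m)]
        assert np.allclose(bh_fdr(p), expect)

    def test_all_ones_boundary(self):
        assert np.all(bh_fdr(np.ones(7)) == 1.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.random(25)
        perm = rng.permutation(25)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_q_not_below_p(self, rng):
        p = rng.random(50)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def _auc_pair_counting(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_and_uninformative(self):
        labels = np.array([True, True, False, False])
        assert roc_auc([4, 3, 2, 1], labels).auc == 1.0
        assert roc_auc([1, 1, 1, 1], labels).auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = roc_auc(scores, labels)
            assert curve.auc == pytest.approx(
                _auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_curve_geometry_and_trapezoid_identity(self, rng):
        scores = np.round(rng.normal(size=30), 1)
        labels = rng.random(30) < 0.4
        c = roc_auc(scores, labels)
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)
        assert np.trapezoid(c.tpr, c.fpr) == pytest.approx(c.auc, abs=1e-12)

    def test_complement_symmetry_tie_free(self, rng):
        scores = rng.permutation(np.arange(20.0))
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_delong_ci_bounds_and_coverage_shape(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
        labels = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        c = roc_auc(scores, labels)
        lo, hi = c.ci95
        assert 0.0 <= lo < c.auc < hi <= 1.0

    def test_auc_rank_pvalue_consistent_with_separation(self, rng):
        labels = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        strong = np.concatenate([rng.normal(2, 1, 20), rng.normal(0, 1, 20)])
        null = rng.normal(size=40)
        assert roc_auc_rank_pvalue(strong, labels) < 0.001
        assert roc_auc_rank_pvalue(null, labels) > 0.01


class TestClopperPearson:
    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(0, 10), (3, 10), (10, 10), (45, 77)]:
            lo, hi = clopper_pearson(k, n)
            ref_lo, ref_hi = proportion_confint(k, n, method="beta")
            assert lo == pytest.approx(ref_lo, abs=1e-10)
            assert hi == pytest.approx(ref_hi, abs=1e-10)


def test_midranks_average_ties():
    assert np.allclose(midranks(np.array([3.0, 1.0, 3.0, 2.0])),
                       [3.5, 1.0, 3.5, 2.0])
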