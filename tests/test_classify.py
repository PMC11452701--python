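import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from uteroflow.classify import (EvalConfig, auc, cohens_d, delong_test,
                                kmeans_1d, normalize01, power_sample_size,
                                supervised_eval, threshold_select, ttest,
                                unsupervised_eval)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_pairwise_oracle(x, y):
    """Exhaustive enumeration over all (negative, positive) pairs."""
    pos = [v for v, l in zip(x, y) if l == 1]
    neg = [v for v, l in zip(x, y) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def kmeans_split_oracle(x):
    """Best contiguous split of the sorted values by direct WCSS evaluation."""
    xs = np.sort(np.asarray(x, dtype=float))
    best, best_k = math.inf, 1
    for k in range(1, xs.size):
        w = (np.sum((xs[:k] - xs[:k].mean()) ** 2)
             + np.sum((xs[k:] - xs[k:].mean()) ** 2))
        if w < best - 1e-15:
            best, best_k = w, k
    lo, hi = xs[:best_k].mean(), xs[best_k:].mean()
    return best, (lo, hi)


class TestTTest:
    def test_identical_groups(self):
        with pytest.warns(UserWarning):
            assert ttest([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_large_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = rng.normal(5, 1, 9)
        assert ttest(a, b) < 1e-3

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.2, 8)
        p = ttest(a, b)
        # permutation distribution of the Welch statistic (vectorised)
        def welch_t(g1, g2, axis=-1):
            m1, m2 = g1.mean(axis), g2.mean(axis)
            v1 = g1.var(axis, ddof=1) / g1.shape[axis]
            v2 = g2.var(axis, ddof=1) / g2.shape[axis]
            return (m1 - m2) / np.sqrt(v1 + v2)

        obs = abs(welch_t(a[None, :], b[None, :]))[0]
        pooled = np.concatenate([a, b])
        n_perm = 100_000
        order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[order]
        t = np.abs(welch_t(perm[:, :10], perm[:, 10:]))
        p_perm = np.mean(t >= obs)
        assert abs(p - p_perm) < 3.5 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            ttest([1.0], [2.0, 3.0])


class TestCohensD:
    def test_equal_means(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_one_pooled_sd(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 500_0)
        d = cohens_d(a, a + a.std(ddof=1))
        assert d == pytest.approx(1.0, rel=1e-9)

    def test_scale_invariance(self):
        a = [1.0, 2.0, 4.0, 3.0]
        b = [5.0, 6.0, 8.0]
        assert cohens_d([10 * v for v in a], [10 * v for v in b]) == \
            pytest.approx(cohens_d(a, b), rel=1e-12)

    def test_zero_pooled_sd(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_reversed(self):
        assert auc([10, 11, 1, 2, 3], [0, 0, 1, 1, 1]) == 0.0

    def test_independent_feature_near_half(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4000)
        y = rng.integers(0, 2, 4000)
        assert abs(auc(x, y) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2, 3], [1, 1, 1])

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(6, 31)
            # discrete support forces ties
            x = rng.integers(0, 6, n).astype(float)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, rng.integers(2, n - 1), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            assert auc(x, y) == pytest.approx(auc_pairwise_oracle(x, y),
                                              abs=1e-12)


class TestKMeans1D:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            x = rng.normal(size=n) * rng.uniform(0.5, 4.0)
            if rng.random() < 0.3:
                x = np.round(x)            # ties
            if np.unique(x).size < 2:
                continue
            assign, (lo, hi) = kmeans_1d(x)
            w_impl = (np.sum((x[assign == 0] - x[assign == 0].mean()) ** 2)
                      + np.sum((x[assign == 1] - x[assign == 1].mean()) ** 2))
            w_oracle, _ = kmeans_split_oracle(x)
            assert w_impl == pytest.approx(w_oracle, abs=1e-9)

    def test_two_tight_clusters(self):
        x = np.array([0.0, 0.01, 0.02, 1.0, 1.01])
        assign, (lo, hi) = kmeans_1d(x)
        np.testing.assert_array_equal(assign, [0, 0, 0, 1, 1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            kmeans_1d([2.0, 2.0, 2.0])


class TestThreshold:
    def test_midpoint(self):
        x = np.array([0.4, 0.5, 0.6, 0.8, 0.9, 1.0])
        thr = threshold_select(x)
        assert thr == pytest.approx(0.5 * (0.5 + 0.9))

    def test_affine_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        a, b = 3.7, -1.2
        assert threshold_select(a * x + b) == pytest.approx(
            a * threshold_select(x) + b, rel=1e-9)

    def test_threshold_reproduces_assignment(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(5, 30)))
            if np.unique(x).size < 2:
                continue
            assign, _ = kmeans_1d(x)
            thr = threshold_select(x)
            np.testing.assert_array_equal(assign, (x > thr).astype(int))


class TestUnsupervised:
    def test_clean_clusters(self):
        x = np.array([0.0, 0.05, 0.1, 1.0, 1.05, 1.1])
        y = np.array([0, 0, 0, 1, 1, 1])
        out = unsupervised_eval(x, y)
        assert out["ACC"] == 100.0
        assert out["SE"] == 100.0 and out["SP"] == 100.0

    def test_label_flip_swaps_se_sp(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 8)])
        y = np.array([0] * 10 + [1] * 8)
        a = unsupervised_eval(x, y)
        b = unsupervised_eval(x, 1 - y)
        assert a["SE"] == pytest.approx(b["SP"])
        assert a["SP"] == pytest.approx(b["SE"])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            unsupervised_eval([1.0] * 5, [0, 0, 1, 1, 1])


class TestSupervised:
    def test_confusion_arithmetic(self):
        # fixed confusion counts TP=8 FN=1 TN=10 FP=2
        from uteroflow.classify import _confusion
        y_true = np.array([1] * 9 + [0] * 12)
        y_pred = np.array([1] * 8 + [0] + [0] * 10 + [1] * 2)
        m = _confusion(y_true, y_pred)
        assert m["ACC"] == pytest.approx(100 * 18 / 21)
        assert m["SE"] == pytest.approx(100 * 8 / 9)
        assert m["SP"] == pytest.approx(100 * 10 / 12)

    def test_separable_feature(self):
        y = np.array([0] * 12 + [1] * 9)
        x = np.where(y == 1, 10.0, 0.0) + np.linspace(0, 0.1, 21)
        out = supervised_eval(x, y, EvalConfig(seed=0))
        assert out["ACC"] == 100.0
        assert out["SE"] == 100.0 and out["SP"] == 100.0

    def test_permutation_null_near_majority_rate(self):
        rng = np.random.default_rng(9)
        y = np.array([0] * 12 + [1] * 9)
        accs = []
        for k in range(30):
            x = rng.normal(size=21)
            out = supervised_eval(x, y, EvalConfig(seed=k))
            accs.append(out["ACC"])
        majority = 100 * 12 / 21
        assert abs(np.mean(accs) - majority) < 8.0

    def test_ci_is_wilson_halfwidth(self):
        from statsmodels.stats.proportion import proportion_confint
        from uteroflow.classify import _confusion
        y = np.array([1] * 9 + [0] * 12)
        m = _confusion(y, y)
        lo, hi = proportion_confint(21, 21, 0.05, method="wilson")
        assert m["CI"] == pytest.approx(100 * (hi - lo) / 2)


class TestDeLong:
    def test_identical_features(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=21)
        y = np.array([0] * 12 + [1] * 9)
        a1, a2, p = delong_test(x, x, y)
        assert a1 == a2
        assert p == 1.0

    def test_auc_matches_rank_auc(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(size=21)
        x2 = rng.normal(size=21)
        y = np.array([0] * 12 + [1] * 9)
        a1, a2, _ = delong_test(x1, x2, y)
        assert a1 == pytest.approx(auc(x1, y), abs=1e-12)
        assert a2 == pytest.approx(auc(x2, y), abs=1e-12)

    def test_agrees_with_paired_bootstrap(self):
        rng = np.random.default_rng(12)
        y = np.array([0] * 12 + [1] * 9)
        x1 = rng.normal(size=21) + 1.2 * y
        x2 = 0.6 * x1 + rng.normal(size=21) * 0.8
        a1, a2, p = delong_test(x1, x2, y)
        # paired bootstrap of the AUC difference
        n_boot = 10_000
        diffs = np.empty(n_boot)
        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        k = 0
        while k < n_boot:
            i = np.concatenate([rng.choice(idx0, idx0.size),
                                rng.choice(idx1, idx1.size)])
            diffs[k] = auc(x1[i], y[i]) - auc(x2[i], y[i])
            k += 1
        se_boot = diffs.std(ddof=1)
        z = (a1 - a2) / se_boot
        p_boot = 2 * sps.norm.sf(abs(z))
        assert abs(p - p_boot) < 0.12

    def test_variance_nonnegative_p_in_range(self):
        rng = np.random.default_rng(13)
        for k in range(20):
            y = rng.integers(0, 2, 15)
            if y.sum() in (0, 15):
                continue
            _, _, p = delong_test(rng.normal(size=15), rng.normal(size=15), y)
            assert 0.0 <= p <= 1.0


class TestPower:
    def test_reference_design(self):
        assert power_sample_size(alpha=0.1, power=0.80, effect_size_d=1.0,
                                 tails="one") == 10

    def test_huge_effect_floor(self):
        assert power_sample_size(0.1, 0.8, 10.0, "one") == 2

    def test_normal_approximation_within_one(self):
        for d, alpha, power in ((0.5, 0.05, 0.8), (1.0, 0.1, 0.8),
                                (0.8, 0.05, 0.9)):
            n = power_sample_size(alpha, power, d, "one")
            approx = 2 * (sps.norm.ppf(1 - alpha) + sps.norm.ppf(power)) ** 2 / d ** 2
            assert abs(n - math.ceil(approx)) <= 1

    def test_infeasible(self):
        with pytest.raises(ValueError):
            power_sample_size(0.5, 0.4, 1.0)


class TestNormalize:
    def test_reference(self):
        np.testing.assert_allclose(normalize01([2, 4, 6]), [0, 0.5, 1])

    def test_bounds_and_order(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=50)
        z = normalize01(x)
        assert z.min() == 0.0 and z.max() == 1.0
        np.testing.assert_array_equal(np.argsort(z), np.argsort(x))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize01([3.0, 3.0])


@given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                min_size=4, max_size=30))
@settings(max_examples=60, deadline=None)
def test_kmeans_property_bruteforce(xs):
    x = np.asarray(xs)
    if np.unique(x).size < 2:
        return
    assign, _ = kmeans_1d(x)
    w_impl = (np.sum((x[assign == 0] - x[assign == 0].mean()) ** 2)
              + np.sum((x[assign == 1] - x[assign == 1].mean()) ** 2))
    w_oracle, _ = kmeans_split_oracle(x)
    assert w_impl <= w_oracle + 1e-7 * (1 + abs(w_oracle))
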