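"""Statistical evaluation of candidate biomarkers.

Per feature: Welch t-test, Cohen's d, repeated holdout logistic-regression
evaluation (accuracy / Wilson CI / sensitivity / specificity), rank AUC,
exact 1-D two-means clustering with centroid-midpoint threshold, paired
DeLong comparison of correlated AUCs, and the noncentral-t power /
sample-size calculation.  PE (label 1) is the positive class throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EvalConfig",
    "ttest",
    "cohens_d",
    "auc",
    "supervised_eval",
    "unsupervised_eval",
    "kmeans_1d",
    "threshold_select",
    "delong_test",
    "power_sample_size",
    "normalize01",
    "evaluate_features",
]


@dataclass(frozen=True)
class EvalConfig:
    n_repeats: int = 5
    holdout_size: int = 2
    cv_folds: int = 2
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.holdout_size < n_samples:
            raise ValueError("holdout_size must be in (0, n_samples)")


def _two_groups(x_npe, x_pe):
    a = np.asarray(x_npe, dtype=float)
    b = np.asarray(x_pe, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    return a, b


def ttest(x_npe, x_pe) -> float:
    """Two-sided Welch t-test p-value; degenerate data (zero variance in
    both groups, equal means) yields p = 1 by convention."""
    a, b = _two_groups(x_npe, x_pe)
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            warnings.warn("degenerate t-test (identical constant groups): p=1")
            return 1.0
        return 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def cohens_d(x_npe, x_pe) -> float:
    """Absolute standardized mean difference with pooled SD."""
    a, b = _two_groups(x_npe, x_pe)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float(abs(np.mean(b) - np.mean(a)) / math.sqrt(sp2))


def auc(feature, labels) -> float:
    """Rank AUC: probability a positive value exceeds a negative one,
    ties counted 1/2 (Mann-Whitney U / n_pos*n_neg)."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    pos = x[y == 1]
    neg = x[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([neg, pos]))
    r_pos = np.sum(ranks[neg.size:])
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    n = tp + fn + tn + fp
    correct = tp + tn
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="wilson")
    return {
        "ACC": 100.0 * correct / n,
        "CI": 100.0 * (hi - lo) / 2.0,
        "SE": 100.0 * tp / (tp + fn) if tp + fn else math.nan,
        "SP": 100.0 * tn / (tn + fp) if tn + fp else math.nan,
    }


def supervised_eval(features, labels, config: EvalConfig | None = None) -> dict:
    """Repeated stratified-holdout logistic regression.

    Each repeat holds out ``holdout_size`` samples (one per class when the
    size is 2), fits on the rest with an internal ``cv_folds``-fold CV
    sanity accuracy, and scores the pooled train+test predictions; metrics
    are means over repeats, in percent."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    n = y.size
    config = config or EvalConfig()
    config.validate(n)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(config.seed)

    metrics = []
    cv_accs = []
    for _ in range(config.n_repeats):
        for _retry in range(100):
            test_idx = _stratified_holdout(y, config.holdout_size, rng)
            train = np.setdiff1d(np.arange(n), test_idx)
            if len(np.unique(y[train])) == 2:
                break
        else:
            raise ValueError("could not draw a training split with both classes")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(Xs[train], y[train])
        cv_accs.append(_cv_accuracy(Xs[train], y[train], config.cv_folds, rng))
        y_pred = clf.predict(Xs)
        metrics.append(_confusion(y, y_pred))

    out = {k: float(np.mean([m[k] for m in metrics])) for k in ("ACC", "CI", "SE", "SP")}
    out["cv_ACC"] = float(np.mean(cv_accs))
    return out


def _stratified_holdout(y: np.ndarray, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if size == 2:
        return np.array([rng.choice(idx0), rng.choice(idx1)])
    n1 = max(1, min(size - 1, round(size * idx1.size / y.size)))
    n0 = size - n1
    return np.concatenate([rng.choice(idx0, n0, replace=False),
                           rng.choice(idx1, n1, replace=False)])


def _cv_accuracy(X, y, folds, rng) -> float:
    n = y.size
    order = rng.permutation(n)
    accs = []
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(np.arange(n), test)
        if len(np.unique(y[train])) < 2:
            accs.append(np.mean(y[test] == np.bincount(y[train]).argmax()))
            continue
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X[train], y[train])
        accs.append(np.mean(clf.predict(X[test]) == y[test]))
    return 100.0 * float(np.mean(accs))


# ---------------------------------------------------------------------------
# 1-D two-means clustering (exact) and threshold
# ---------------------------------------------------------------------------

def kmeans_1d(feature) -> tuple[np.ndarray, tuple[float, float]]:
    """Exact 1-D 2-means: the within-cluster sum of squares is minimised by
    a contiguous split of the sorted values; all n-1 splits are scanned
    with prefix sums.  Returns (assignment in {0,1}, (lo_centroid, hi_centroid)),
    cluster 1 being the higher-mean cluster."""
    x = np.asarray(feature, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = x.size
    csum = np.cumsum(xs)
    csq = np.cumsum(xs ** 2)
    k = np.arange(1, n)           # size of the lower cluster
    s1 = csum[k - 1]
    s2 = csum[-1] - s1
    q1 = csq[k - 1]
    q2 = csq[-1] - q1
    wcss = (q1 - s1 ** 2 / k) + (q2 - s2 ** 2 / (n - k))
    kbest = int(k[np.argmin(wcss)])
    assign = np.zeros(n, dtype=int)
    assign[order[kbest:]] = 1
    lo = float(np.mean(xs[:kbest]))
    hi = float(np.mean(xs[kbest:]))
    return assign, (lo, hi)


def threshold_select(feature) -> float:
    """Unsupervised 1-D decision boundary: midpoint of the two centroids."""
    _, (lo, hi) = kmeans_1d(feature)
    return 0.5 * (lo + hi)


def unsupervised_eval(feature, labels) -> dict:
    """2-means on the standardized feature; clusters mapped to labels by
    majority vote (tie -> higher-mean cluster is PE)."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(x).size < 2:
        raise ValueError("feature has fewer than 2 distinct values")
    xs = (x - x.mean()) / x.std()
    assign, _ = kmeans_1d(xs)
    # majority-vote mapping of cluster -> label
    n1_in_hi = np.sum(y[assign == 1] == 1)
    n1_in_lo = np.sum(y[assign == 0] == 1)
    frac_hi = n1_in_hi / max(1, np.sum(assign == 1))
    frac_lo = n1_in_lo / max(1, np.sum(assign == 0))
    if frac_hi > frac_lo:
        y_pred = assign
    elif frac_hi < frac_lo:
        y_pred = 1 - assign
    else:
        y_pred = assign  # tie: higher-mean cluster = PE
    out = _confusion(y, y_pred)
    out["threshold"] = threshold_select(x)
    return out


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(x: np.ndarray, y: np.ndarray):
    pos = x[y == 1]
    neg = x[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    a = float((np.sum(all_r[:m]) - m * (m + 1) / 2.0) / (m * n))
    v10 = (all_r[:m] - r_pos) / n            # structural components, positives
    v01 = 1.0 - (all_r[m:] - r_neg) / m      # negatives
    return a, v10, v01


def delong_test(feature_1, feature_2, labels) -> tuple[float, float, float]:
    """Paired DeLong test: returns (auc_1, auc_2, two-sided p) for the
    equality of the two correlated AUCs on the same patients."""
    y = np.asarray(labels).astype(int)
    x1 = np.asarray(feature_1, dtype=float)
    x2 = np.asarray(feature_2, dtype=float)
    if x1.size != y.size or x2.size != y.size:
        raise ValueError("features and labels must be the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    a1, v10_1, v01_1 = _delong_components(x1, y)
    a2, v10_2, v01_2 = _delong_components(x2, y)
    m = v10_1.size
    n = v01_1.size
    v10 = np.vstack([v10_1, v10_2])
    v01 = np.vstack([v01_1, v01_2])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        if abs(a1 - a2) > 0:
            warnings.warn("DeLong variance estimate degenerate; p set to 1")
        return a1, a2, 1.0
    z = (a1 - a2) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return a1, a2, float(p)


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

def power_sample_size(alpha: float, power: float, effect_size_d: float,
                      tails: str = "one", n_max: int = 10 ** 6) -> int:
    """Smallest per-group n for a two-sample t-test (equal sizes) to reach
    the requested power, using the noncentral-t distribution
    (df = 2n - 2, noncentrality d*sqrt(n/2))."""
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if effect_size_d <= 0:
        raise ValueError("effect size must be > 0")
    if power <= alpha:
        raise ValueError("requested power must exceed alpha")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        nc = effect_size_d * math.sqrt(n / 2.0)
        if tails == "one":
            tcrit = sps.t.ppf(1.0 - alpha, df)
            pw = sps.nct.sf(tcrit, df, nc)
        else:
            tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
            pw = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
        if pw >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches the requested power")


def normalize01(feature) -> np.ndarray:
    """Min-max scaling to [0, 1]."""
    x = np.asarray(feature, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise ValueError("cannot normalise a constant feature")
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# full per-feature report
# ---------------------------------------------------------------------------

def evaluate_features(table: pd.DataFrame, feature_columns: list[str],
                      config: EvalConfig | None = None) -> dict[str, dict]:
    """Per-feature report mirroring the study's summary-table layout."""
    config = config or EvalConfig()
    y = (table["group"].to_numpy() == "PE").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both NPE and PE groups are required")
    report: dict[str, dict] = {}
    for i, col in enumerate(feature_columns):
        x = table[col].to_numpy(dtype=float)
        a = x[y == 0]
        b = x[y == 1]
        entry = {
            "t_test_p": ttest(a, b),
            "cohens_d": cohens_d(a, b),
            "AUC": auc(x, y),
            "supervised": supervised_eval(
                x, y, EvalConfig(config.n_repeats, config.holdout_size,
                                 config.cv_folds, config.seed + i)),
        }
        try:
            entry["unsupervised"] = unsupervised_eval(x, y)
        except ValueError as exc:
            entry["unsupervised"] = {"error": str(exc)}
        report[col] = entry
    return report
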