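"""Independent straight-line reimplementations used as test oracles.

Everything here is deliberately naive — explicit loops over features,
groups, and pairs — and shares no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np


def oracle_f_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F for a single feature, via group sums."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        sub = values[labels == g]
        m = sub.mean()
        ssb = ssb + len(sub) * (m - grand) ** 2
        ssw = ssw + ((sub - m) ** 2).sum()
    msb = ssb / (len(groups) - 1)
    msw = ssw / (n - len(groups))
    if msw == 0.0:
        return 0.0 if msb == 0.0 else 1e12
    return max(msb / msw, 0.0)


def oracle_euclidean_redundancy(X: np.ndarray) -> np.ndarray:
    """Mean pairwise Euclidean distance per feature (columns of X),
    by exhaustive enumeration of all pairs."""
    V = np.ascontiguousarray(np.asarray(X, dtype=float).T)
    m = V.shape[0]
    ed = np.empty(m)
    for i in range(m):
        dists = np.empty(m)
        for j in range(m):
            dists[j] = np.sqrt(((V[i] - V[j]) ** 2).sum())
        ed[i] = dists.sum() / (m - 1)
    return ed


def oracle_min_max(v: np.ndarray) -> np.ndarray:
    lo = min(v)
    hi = max(v)
    if hi == lo:
        return np.zeros(len(v))
    return np.array([(x - lo) / (hi - lo) for x in v])


def oracle_mfmd(X: np.ndarray, y: np.ndarray, feature_ids, w_s: float, w_d: float):
    """Full MFMD score table and ranking, brute force.

    Returns (F, ED, F_norm, ED_norm, mfmd, order) where order is a list
    of positions into feature_ids, best first.
    """
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    F = np.array([oracle_f_statistic(X[:, j], y) for j in range(n_feat)])
    ED = oracle_euclidean_redundancy(X)
    F_norm = oracle_min_max(F)
    ED_norm = oracle_min_max(ED)
    mfmd = np.array([w_s * F_norm[j] + w_d * ED_norm[j] for j in range(n_feat)])
    order = sorted(range(n_feat), key=lambda j: (-mfmd[j], -F_norm[j], str(feature_ids[j])))
    return F, ED, F_norm, ED_norm, mfmd, order


def oracle_pca_n_components(X: np.ndarray, target: float) -> int:
    """Component count by explicit covariance eigendecomposition and
    cumulative eigenvalue sums (smallest m with cumulative ratio > target)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    ratios = eig / eig.sum()
    cum = 0.0
    for m, r in enumerate(ratios, start=1):
        cum += r
        if cum > target:
            return m
    return len(ratios)


def oracle_knn_impute_cell(values: np.ndarray, feature_ids, i: int, s: int, k: int) -> float:
    """Impute cell (feature i, sample s) by exhaustive enumeration of
    donor distances over co-observed samples."""
    n_feat = values.shape[0]
    cand = []
    for j in range(n_feat):
        if j == i or np.isnan(values[j, s]):
            continue
        co = ~np.isnan(values[i]) & ~np.isnan(values[j])
        if not co.any():
            continue
        d = np.sqrt(((values[i, co] - values[j, co]) ** 2).sum())
        cand.append((d, str(feature_ids[j]), j))
    cand.sort()
    donors = [j for _, _, j in cand[:k]]
    if not donors:
        return float(np.nanmean(values[i]))
    return float(np.mean([values[j, s] for j in donors]))


def oracle_confusion_accuracy(y_true, y_pred) -> float:
    """Accuracy as confusion-matrix trace over grand total."""
    labels = sorted(set(list(y_true) + list(y_pred)))
    idx = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return float(np.trace(cm)) / cm.sum()
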