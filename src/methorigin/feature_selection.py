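"""Two-stage tissue-specific CpG selection.

Stage 1 — differential screen: for every feature and every class, a
two-sided Welch t-test of that class against all other classes pooled,
with Benjamini-Hochberg FDR adjustment per class across features; a
feature survives if it is significant (q below threshold) for at least
one class.

Stage 2 — MFMD ranking (Maximum-F-statistic-Maximum-Distance): each
candidate feature receives a relevance score, the one-way ANOVA
F-statistic of its values across classes, and a redundancy score, its
mean Euclidean distance to every other candidate's sample-vector (large
distance = less redundant). Both are min-max normalized to [0, 1] across
the candidates and combined as

    mfmd = w_s * F_norm + w_d * ED_norm,    0 < w_s, w_d <= 1,

and features are ranked by descending combined score. The quantities sit
on wildly different natural scales (F is unitless and unbounded, ED is
in matrix-value units), so the normalization is what makes the weights
meaningful.

The ranker is a scikit-learn transformer (:class:`MFMDRanker`), so it
slots into a ``Pipeline`` ahead of a classifier and is then fitted on
each training fold only — feature selection never sees test samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

#: F-statistic reported when within-group variance is exactly zero but
#: group means differ; keeps the min-max normalization finite.
F_CAP = 1e12


# ---------------------------------------------------------------------------
# stage 1: one-vs-rest Welch screen with BH adjustment per class
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-(feature, class) screen outcome: Welch t, p, BH q, selection."""

    t_statistic: pd.DataFrame      # features x classes
    p_value: pd.DataFrame
    q_value: pd.DataFrame
    threshold: float

    @property
    def selected(self) -> pd.DataFrame:
        return self.q_value < self.threshold

    def selected_features(self) -> list:
        """Union over classes of features significant for any class,
        in original feature order."""
        mask = self.selected.any(axis=1)
        return self.t_statistic.index[mask].tolist()


def differential_screen(dataset, fdr_threshold: float = 0.01) -> DifferentialResult:
    """One-vs-rest Welch t-test per (feature, class) with BH FDR control.

    Features constant across both groups get p = 1 (no evidence, never
    selected). Requires a complete matrix and >= 2 samples per class.
    """
    dataset.matrix.require_complete("differential_screen")
    X, y = dataset.to_xy()            # samples x features
    return _screen_xy(X, y, fdr_threshold)


def _screen_xy(X: pd.DataFrame, y: pd.Series, fdr_threshold: float) -> DifferentialResult:
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("differential screen needs >= 2 classes")
    counts = y.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with < 2 samples: {small}")
    arr = X.to_numpy(dtype=float)
    t_cols, p_cols, q_cols = {}, {}, {}
    for cls in classes:
        in_cls = (y == cls).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # constant features trigger a precision warning; they are
            # assigned p = 1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(arr[in_cls], arr[~in_cls], axis=0, equal_var=False)
        t = np.where(np.isnan(t), 0.0, t)
        p = np.where(np.isnan(p), 1.0, p)
        q = multipletests(p, method="fdr_bh")[1]
        t_cols[cls], p_cols[cls], q_cols[cls] = t, p, q
    idx = X.columns
    return DifferentialResult(
        t_statistic=pd.DataFrame(t_cols, index=idx),
        p_value=pd.DataFrame(p_cols, index=idx),
        q_value=pd.DataFrame(q_cols, index=idx),
        threshold=fdr_threshold,
    )


# ---------------------------------------------------------------------------
# stage 2: relevance, redundancy, and the combined criterion
# ---------------------------------------------------------------------------

def f_statistics(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per feature (columns of ``X``), vectorized.

    F = (between-group SS / (G-1)) / (within-group SS / (N-G)). A feature
    with zero within-group variance gets F = 0 if the group means also
    coincide, else the finite cap ``F_CAP``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    n, _ = X.shape
    if len(groups) < 2:
        raise ValueError("F-statistic needs >= 2 groups")
    if n <= len(groups):
        raise ValueError("F-statistic needs more samples than groups")
    # reductions run along the contiguous last axis so each feature's
    # sums accumulate exactly as they would for a single 1-D vector
    Xt = np.ascontiguousarray(X.T)            # features x samples
    grand = Xt.mean(axis=1)
    ssb = np.zeros(Xt.shape[0])
    ssw = np.zeros(Xt.shape[0])
    for g in groups:
        sub = np.ascontiguousarray(Xt[:, y == g])
        m = sub.mean(axis=1)
        ssb += sub.shape[1] * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    msb = ssb / (len(groups) - 1)
    msw = ssw / (n - len(groups))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw == 0.0, np.where(msb == 0.0, 0.0, F_CAP), f)
    return np.maximum(f, 0.0)


def f_statistic(values, labels) -> float:
    """One-way ANOVA F for a single per-sample vector."""
    return float(f_statistics(np.asarray(values, dtype=float)[:, None], np.asarray(labels))[0])


#: above this candidate count, mean distances switch from the direct
#: sum-of-squared-differences algorithm to the BLAS Gram formulation
#: (same quantity, different roundoff; cross-checked by a property test)
_GRAM_THRESHOLD = 512


def euclidean_redundancy(X: np.ndarray) -> np.ndarray:
    """Mean Euclidean distance from each candidate feature (column of
    ``X``, samples in rows) to every other candidate. Higher = less
    redundant. Needs >= 2 candidates."""
    V = np.ascontiguousarray(np.asarray(X, dtype=float).T)   # candidates x samples
    m = V.shape[0]
    if m < 2:
        raise ValueError("redundancy undefined for a single candidate")
    if m <= _GRAM_THRESHOLD:
        ed = np.empty(m)
        for i in range(m):
            d = np.sqrt(((V - V[i]) ** 2).sum(axis=1))
            ed[i] = d.sum() / (m - 1)
        return ed
    sq = (V * V).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2).sum(axis=1) / (m - 1)


def _min_max(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:            # degenerate: no spread, score carries no signal
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


class MFMDRanker(BaseEstimator, TransformerMixin):
    """Rank features by the combined relevance/redundancy criterion and
    select the top ``n_features``.

    Parameters
    ----------
    n_features : int or None
        How many top-ranked features ``transform`` keeps; ``None`` keeps
        every ranked candidate.
    w_s, w_d : float in (0, 1]
        Weights of the normalized F-statistic and Euclidean-distance
        scores.
    fdr_threshold : float or None
        If set, candidates are the differential screen's survivors at
        this FDR; if ``None`` every feature is a candidate.
    redundancy_sign : {+1, -1}
        +1 rewards large mean distance (the printed criterion); -1 flips
        the distance term for the minimum-redundancy reading.

    Attributes
    ----------
    scores_ : pandas.DataFrame
        The score table in rank order: columns F, ED, F_norm, ED_norm,
        mfmd, indexed by feature ID.
    ranking_ : list
        Feature IDs by descending combined score (ties: higher F_norm,
        then feature ID).
    screen_ : DifferentialResult or None
    """

    def __init__(self, n_features: int | None = None, w_s: float = 1.0, w_d: float = 1.0,
                 fdr_threshold: float | None = 0.01, redundancy_sign: int = 1):
        self.n_features = n_features
        self.w_s = w_s
        self.w_d = w_d
        self.fdr_threshold = fdr_threshold
        self.redundancy_sign = redundancy_sign

    def fit(self, X, y):
        if not (0 < self.w_s <= 1 and 0 < self.w_d <= 1):
            raise ValueError(f"weights must lie in (0,1], got w_s={self.w_s}, w_d={self.w_d}")
        if self.redundancy_sign not in (1, -1):
            raise ValueError("redundancy_sign must be +1 or -1")
        X = pd.DataFrame(X)
        if X.isna().to_numpy().any():
            raise ValueError("MFMDRanker requires a complete (imputed) matrix")
        y = pd.Series(np.asarray(y), index=X.index)
        self.feature_names_in_ = X.columns.to_numpy()
        self.n_features_in_ = X.shape[1]

        if self.fdr_threshold is not None:
            self.screen_ = _screen_xy(X, y, self.fdr_threshold)
            candidates = self.screen_.selected_features()
            if len(candidates) < 2:
                raise ValueError(
                    f"differential screen kept {len(candidates)} feature(s); "
                    "redundancy needs >= 2 candidates"
                )
        else:
            self.screen_ = None
            candidates = X.columns.tolist()
            if len(candidates) < 2:
                raise ValueError("MFMD ranking needs >= 2 candidate features")

        sub = X[candidates].to_numpy(dtype=float)
        F = f_statistics(sub, y.to_numpy())
        ED = euclidean_redundancy(sub)
        F_norm = _min_max(F)
        ED_norm = _min_max(ED)
        mfmd = self.w_s * F_norm + self.redundancy_sign * self.w_d * ED_norm
        table = pd.DataFrame(
            {"F": F, "ED": ED, "F_norm": F_norm, "ED_norm": ED_norm, "mfmd": mfmd},
            index=pd.Index(candidates, name="feature"),
        )
        order = sorted(
            range(len(candidates)),
            key=lambda i: (-mfmd[i], -F_norm[i], str(candidates[i])),
        )
        self.scores_ = table.iloc[order]
        self.ranking_ = self.scores_.index.tolist()
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        k = len(self.ranking_) if self.n_features is None else self.n_features
        keep = select_top_k(self.ranking_, min(k, len(self.ranking_)))
        X = pd.DataFrame(X)
        if not set(keep).issubset(X.columns):
            raise KeyError("transform input lacks ranked features")
        return X[keep]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "ranking_")
        k = len(self.ranking_) if self.n_features is None else self.n_features
        return np.asarray(self.ranking_[:k], dtype=object)


def mfmd_rank(dataset, candidates=None, w_s: float = 1.0, w_d: float = 1.0,
              fdr_threshold: float | None = 0.01, redundancy_sign: int = 1):
    """Functional wrapper: returns (score table, ranked feature list).

    ``candidates`` supplied explicitly bypasses the differential screen;
    otherwise the screen at ``fdr_threshold`` picks them.
    """
    ds = dataset if candidates is None else dataset.subset_features(candidates)
    ranker = MFMDRanker(
        w_s=w_s, w_d=w_d,
        fdr_threshold=None if candidates is not None else fdr_threshold,
        redundancy_sign=redundancy_sign,
    )
    X, y = ds.to_xy()
    ranker.fit(X, y)
    return ranker.scores_, ranker.ranking_


def select_top_k(ranked: list, k: int) -> list:
    """First ``k`` features of a ranked list."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must lie in [1, {len(ranked)}], got {k}")
    return list(ranked[:k])


def warn_if_masked(matrix) -> None:
    if not matrix.is_complete():
        warnings.warn("matrix has missing values; feature selection will reject it")
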