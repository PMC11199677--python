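"""PCA with the component count chosen by cumulative explained variance.

Samples are the observations; features are centered but not scaled to
unit variance (beta values already share the [0, 1] scale). The number
of retained components is the smallest m whose cumulative explained
variance ratio strictly exceeds the target (default 0.95), so dropping
the last kept component would fall below it. Loading signs follow a
deterministic convention: each component's largest-magnitude entry is
positive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted


class VarianceTargetPCA(BaseEstimator, TransformerMixin):
    """Centered PCA keeping the minimal component set that explains more
    than ``variance_target`` of the total variance.

    Attributes (after fit)
    ----------------------
    components_ : ndarray (n_components, n_features) — orthonormal loadings
    explained_variance_ratio_ : ndarray, nonincreasing
    n_components_ : int
    mean_ : ndarray (n_features,) — the centering vector
    """

    def __init__(self, variance_target: float = 0.95):
        self.variance_target = variance_target

    def fit(self, X, y=None):
        if not 0.0 < self.variance_target <= 1.0:
            raise ValueError(f"variance_target must lie in (0,1], got {self.variance_target}")
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("PCA needs >= 2 samples")
        if X.isna().to_numpy().any():
            raise ValueError("PCA requires a complete matrix")
        arr = X.to_numpy(dtype=float)
        if np.allclose(arr.var(axis=0), 0.0):
            raise ValueError("constant matrix: total variance is zero")
        self.feature_names_in_ = X.columns.to_numpy()
        self.n_features_in_ = X.shape[1]

        full = PCA(n_components=None, svd_solver="full").fit(arr)
        ratios = full.explained_variance_ratio_
        cum = np.cumsum(ratios)
        above = np.flatnonzero(cum > self.variance_target)
        # float roundoff can leave the full cumulative sum a hair under 1
        m = int(above[0]) + 1 if len(above) else len(ratios)

        comps = full.components_[:m].copy()
        flip = np.sign(comps[np.arange(m), np.argmax(np.abs(comps), axis=1)])
        comps *= flip[:, None]
        self.components_ = comps
        self.explained_variance_ratio_ = ratios[:m].copy()
        self.explained_variance_ = full.explained_variance_[:m].copy()
        self.n_components_ = m
        self.mean_ = full.mean_.copy()
        return self

    def _check_features(self, X: pd.DataFrame) -> None:
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: model fitted on {self.n_features_in_} features, got {X.shape[1]}"
            )
        got = [str(c) for c in X.columns]
        expected = [str(f) for f in self.feature_names_in_]
        if got != expected:
            raise ValueError("feature mismatch: column IDs differ from the fitted model's")

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = pd.DataFrame(X)
        self._check_features(X)
        return (X.to_numpy(dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, scores) -> np.ndarray:
        check_is_fitted(self, "components_")
        return np.asarray(scores) @ self.components_ + self.mean_

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "components_")
        return {
            "variance_target": self.variance_target,
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "explained_variance": self.explained_variance_.tolist(),
            "mean": self.mean_.tolist(),
            "feature_names": [str(f) for f in self.feature_names_in_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceTargetPCA":
        model = cls(variance_target=d["variance_target"])
        model.components_ = np.asarray(d["components"], dtype=float)
        model.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"], dtype=float)
        model.explained_variance_ = np.asarray(d["explained_variance"], dtype=float)
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
        model.n_features_in_ = len(model.mean_)
        model.n_components_ = model.components_.shape[0]
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "VarianceTargetPCA":
        return cls.from_dict(json.loads(Path(path).read_text()))


def pca_fit(matrix, variance_target: float = 0.95) -> VarianceTargetPCA:
    """Fit on an :class:`OmicsMatrix` (samples as observations)."""
    return VarianceTargetPCA(variance_target).fit(matrix.to_samples_by_features())


def pca_transform(model: VarianceTargetPCA, matrix) -> np.ndarray:
    return model.transform(matrix.to_samples_by_features())
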