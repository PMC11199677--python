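"""In-memory containers for omics matrices and labelled cohorts.

The pipeline's working unit is a feature-by-sample numeric matrix
(CpG sites or genes in rows, samples in columns) with missing entries
encoded as NaN, plus a value-domain tag distinguishing methylation beta
values (bounded in [0, 1]) from nonnegative expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_DOMAINS = ("beta", "expression")


@dataclass
class OmicsMatrix:
    """Feature-by-sample matrix with a missing-value mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by feature ID, columns by sample ID. Missing cells
        are ``NaN``; the mask is implicit in the NaN pattern.
    domain : {"beta", "expression"}
        Value domain. Beta values must lie in [0, 1]; expression values
        must be nonnegative. Validated on construction.
    """

    values: pd.DataFrame
    domain: str = "beta"

    def __post_init__(self) -> None:
        if self.domain not in VALID_DOMAINS:
            raise ValueError(f"domain must be one of {VALID_DOMAINS}, got {self.domain!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dup[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if self.domain == "beta":
            bad = (arr < 0.0) | (arr > 1.0)
        else:
            bad = arr < 0.0
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"{self.domain} value {arr[i, j]!r} out of domain at "
                f"feature {self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    def require_complete(self, who: str) -> None:
        if not self.is_complete():
            raise ValueError(f"{who} requires a complete matrix; found {self.n_missing} missing cells (impute first)")

    def to_samples_by_features(self) -> pd.DataFrame:
        """Transpose into the samples-as-rows layout estimators expect."""
        return self.values.T

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return OmicsMatrix(self.values.loc[list(feature_ids)], domain=self.domain)

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.values[list(sample_ids)], domain=self.domain)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), domain=self.domain)

    def equals(self, other: "OmicsMatrix") -> bool:
        return self.domain == other.domain and self.values.equals(other.values)


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort: which features were planted
    as class-specific markers and with what effect size."""

    markers: dict[str, list[str]]
    effect_size: float
    baseline_means: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cls, feats in self.markers.items():
            overlap = seen.intersection(feats)
            if overlap:
                raise ValueError(f"marker lists overlap across classes: {sorted(overlap)[:5]}")
            seen.update(feats)

    def all_markers(self) -> set[str]:
        return {f for feats in self.markers.values() for f in feats}


@dataclass
class LabelledDataset:
    """An :class:`OmicsMatrix` joined with one class label per sample."""

    matrix: OmicsMatrix
    labels: pd.Series
    truth: SyntheticTruth | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        unlabelled = self.matrix.sample_ids.difference(self.labels.index)
        if len(unlabelled):
            raise ValueError(f"samples without labels: {list(unlabelled[:5])}")
        # align label order to the matrix's sample order
        self.labels = self.labels.loc[self.matrix.sample_ids]

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique().tolist())

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def to_xy(self) -> tuple[pd.DataFrame, pd.Series]:
        """Return (X, y) with samples as rows, for estimator consumption."""
        return self.matrix.to_samples_by_features(), self.labels

    def subset_samples(self, sample_ids) -> "LabelledDataset":
        return LabelledDataset(
            self.matrix.subset_samples(sample_ids),
            self.labels.loc[list(sample_ids)],
            truth=self.truth,
        )

    def subset_features(self, feature_ids) -> "LabelledDataset":
        return LabelledDataset(
            self.matrix.subset_features(feature_ids), self.labels, truth=self.truth
        )
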