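"""Data-quality pipeline: class-size QC, high-missingness site removal,
and K-nearest-neighbor imputation of the remaining missing values.

Imputation is feature-wise, the convention of the canonical 450K KNN
impute: for a missing cell the donors are the K features nearest in
Euclidean distance computed over mutually observed samples, and the
imputed value is the mean of the donors' values at that sample. Ties in
distance break by feature-ID lexicographic order so the result is
deterministic; when fewer than K donors observe the needed sample all
available donors are used, and with none at all the feature's own
observed mean stands in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import LabelledDataset, OmicsMatrix


@dataclass
class PreprocessReport:
    n_features_in: int = 0
    n_features_removed_missing: int = 0
    n_samples_removed_qc: int = 0
    classes_dropped: list = field(default_factory=list)
    impute_k_used: int | None = None

    def __post_init__(self) -> None:
        if self.n_features_removed_missing > self.n_features_in:
            raise ValueError("more features removed than were present")


def qc_class_size(dataset: LabelledDataset, min_n: int = 100) -> tuple[LabelledDataset, PreprocessReport]:
    """Drop classes with ``min_n`` samples or fewer (the rule is strict:
    a class needs *more than* ``min_n`` samples to stay)."""
    counts = dataset.labels.value_counts()
    keep_classes = counts[counts > min_n].index
    dropped = sorted(counts.index.difference(keep_classes).tolist())
    if len(keep_classes) == 0:
        raise ValueError(f"no classes pass QC (all have <= {min_n} samples)")
    keep_samples = dataset.labels[dataset.labels.isin(keep_classes)].index
    report = PreprocessReport(
        n_features_in=dataset.matrix.n_features,
        n_samples_removed_qc=dataset.matrix.n_samples - len(keep_samples),
        classes_dropped=dropped,
    )
    if not dropped:
        return dataset, report
    return dataset.subset_samples(list(keep_samples)), report


def filter_missing_features(matrix: OmicsMatrix, max_frac: float = 0.30) -> tuple[OmicsMatrix, PreprocessReport]:
    """Remove features whose missing fraction strictly exceeds
    ``max_frac`` (a feature missing in exactly 30% of samples survives a
    0.30 cutoff). Feature order is preserved."""
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError(f"max_frac must lie in [0,1], got {max_frac}")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac[frac <= max_frac].index
    if len(keep) == 0:
        raise ValueError(f"all {matrix.n_features} features exceed {max_frac:.0%} missingness")
    report = PreprocessReport(
        n_features_in=matrix.n_features,
        n_features_removed_missing=matrix.n_features - len(keep),
    )
    if len(keep) == matrix.n_features:
        return matrix, report
    return OmicsMatrix(matrix.values.loc[keep], domain=matrix.domain), report


def _donor_order(values: np.ndarray, observed: np.ndarray, i: int, feature_ids) -> list[int]:
    """All features ordered by Euclidean distance to feature ``i`` over
    co-observed samples (then feature ID); features sharing no observed
    sample with ``i`` are excluded."""
    v0 = np.where(observed, values, 0.0)
    co = observed & observed[i]                     # co-observation mask per feature
    n_co = co.sum(axis=1)
    diff = np.where(co, v0 - v0[i], 0.0)
    dist = np.sqrt((diff * diff).sum(axis=1))
    order = sorted(
        (j for j in range(len(values)) if j != i and n_co[j] > 0),
        key=lambda j: (dist[j], feature_ids[j]),
    )
    return order


def knn_impute(matrix: OmicsMatrix, k: int = 5) -> OmicsMatrix:
    """Fill every missing cell from the K nearest features.

    Observed cells are never altered; each imputed value is a mean of
    donor values observed at the same sample, so it lies within the
    donors' range (and, for beta values, within [0, 1]).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if matrix.is_complete():
        return matrix
    values = matrix.values.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    feature_ids = matrix.feature_ids.astype(str).tolist()
    n_obs_per_feature = observed.sum(axis=1)
    if (n_obs_per_feature == 0).any():
        empty = [feature_ids[i] for i in np.flatnonzero(n_obs_per_feature == 0)]
        raise ValueError(
            f"features with zero observed values (filter before imputing): {empty[:5]}"
        )
    out = values.copy()
    for i in np.flatnonzero(~observed.all(axis=1)):
        order = _donor_order(values, observed, i, feature_ids)
        own_mean = values[i, observed[i]].mean()
        for s in np.flatnonzero(~observed[i]):
            donors = [j for j in order if observed[j, s]][:k]
            out[i, s] = np.mean([values[j, s] for j in donors]) if donors else own_mean
    frame = matrix.values.copy()
    frame.iloc[:, :] = out
    return OmicsMatrix(frame, domain=matrix.domain)


def preprocess(
    dataset: LabelledDataset,
    min_class_size: int = 100,
    missing_frac_max: float = 0.30,
    impute_k: int = 5,
) -> tuple[LabelledDataset, PreprocessReport]:
    """Full pass: class-size QC, missingness filter, KNN imputation.

    Idempotent: a second pass over the output is an identity.
    """
    dataset, qc_report = qc_class_size(dataset, min_n=min_class_size)
    filtered, f_report = filter_missing_features(dataset.matrix, max_frac=missing_frac_max)
    imputed = knn_impute(filtered, k=impute_k)
    report = PreprocessReport(
        n_features_in=qc_report.n_features_in,
        n_features_removed_missing=f_report.n_features_removed_missing,
        n_samples_removed_qc=qc_report.n_samples_removed_qc,
        classes_dropped=qc_report.classes_dropped,
        impute_k_used=impute_k,
    )
    return LabelledDataset(imputed, dataset.labels, truth=dataset.truth), report
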