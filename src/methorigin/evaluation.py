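"""Evaluation protocol: overall accuracy, per-class precision/recall,
stratified half-split and 5-fold cross-validation, and the two
experiment drivers — the profile-by-classifier comparison and the
accuracy-versus-marker-count curve.

Per class i, precision is the number of samples correctly classified as
class i over the number of samples classified as class i, and recall is
that same numerator over the number of true class-i samples. Overall
accuracy is correct predictions over total predictions, pooled across
CV folds (micro accounting), so the support-weighted mean of per-class
recalls reproduces it exactly.

The default whole-protocol driver mirrors the published design while
staying leakage-safe: the cohort is split in half (stratified), features
are ranked on the training half only, and the classifier is assessed by
stratified 5-fold CV on the held-out half restricted to the chosen
features. Whole-data CV is available as a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifiers import ClassifierSpec, predict, train
from .containers import LabelledDataset
from .feature_selection import mfmd_rank, select_top_k

# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def overall_accuracy(y_true, y_pred) -> float:
    """Correct predictions / total predictions, as an exact ratio."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise ValueError("empty prediction vectors")
    return float(np.sum(y_true == y_pred)) / len(y_true)


def precision_recall(y_true, y_pred) -> pd.DataFrame:
    """Per-class precision, recall, and support.

    A class present in the truth but never predicted gets precision 0
    with its ``never_predicted`` flag set; a label predicted but absent
    from the truth is excluded with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise ValueError("empty prediction vectors")
    classes = sorted(pd.unique(y_true).tolist())
    phantom = set(pd.unique(y_pred)) - set(classes)
    if phantom:
        warnings.warn(f"predicted labels absent from truth excluded: {sorted(phantom)}")
    rows = []
    for cls in classes:
        true_i = y_true == cls
        pred_i = y_pred == cls
        correct = int(np.sum(true_i & pred_i))
        n_pred = int(pred_i.sum())
        support = int(true_i.sum())
        if n_pred == 0:
            warnings.warn(f"class {cls!r} never predicted; precision set to 0")
        rows.append({
            "precision": correct / n_pred if n_pred else 0.0,
            "recall": correct / support,
            "support": support,
            "never_predicted": n_pred == 0,
        })
    return pd.DataFrame(rows, index=pd.Index(classes, name="class"))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    overall_accuracy: float
    per_class: pd.DataFrame
    fold_assignments: dict = field(default_factory=dict)   # sample -> fold index
    fold_accuracies: list = field(default_factory=list)
    predictions: dict = field(default_factory=dict)        # sample -> predicted label
    truths: dict = field(default_factory=dict)             # sample -> true label
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overall_accuracy <= 1.0:
            raise ValueError("overall accuracy outside [0,1]")
        if self.truths and int(self.per_class["support"].sum()) != len(self.truths):
            raise ValueError("per-class supports do not sum to the sample count")

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": {
                str(cls): {
                    "precision": float(row["precision"]),
                    "recall": float(row["recall"]),
                    "support": int(row["support"]),
                    "never_predicted": bool(row["never_predicted"]),
                }
                for cls, row in self.per_class.iterrows()
            },
            "fold_assignments": {str(k): int(v) for k, v in self.fold_assignments.items()},
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "predictions": {str(k): str(v) for k, v in self.predictions.items()},
            "truths": {str(k): str(v) for k, v in self.truths.items()},
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        per_class = pd.DataFrame.from_dict(d["per_class"], orient="index")
        per_class.index.name = "class"
        return cls(
            overall_accuracy=d["overall_accuracy"],
            per_class=per_class,
            fold_assignments=d.get("fold_assignments", {}),
            fold_accuracies=d.get("fold_accuracies", []),
            predictions=d.get("predictions", {}),
            truths=d.get("truths", {}),
            config=d.get("config", {}),
        )

    def render_table(self) -> str:
        """Plain-text per-class precision/recall table."""
        lines = [f"overall accuracy: {self.overall_accuracy:.4f}",
                 f"{'class':<12}{'precision':>10}{'recall':>10}{'support':>10}"]
        for cls, row in self.per_class.iterrows():
            lines.append(
                f"{str(cls):<12}{row['precision']:>10.4f}{row['recall']:>10.4f}{int(row['support']):>10d}"
            )
        return "\n".join(lines)


@dataclass
class MarkerCurve:
    """Accuracy as a function of the number of top-ranked markers."""

    points: list  # of (k, mean_accuracy, [per-fold accuracies])

    def __post_init__(self) -> None:
        ks = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("marker counts must be strictly increasing")
        for _, acc, folds in self.points:
            if not 0.0 <= acc <= 1.0 or any(not 0.0 <= a <= 1.0 for a in folds):
                raise ValueError("accuracies outside [0,1]")

    def k_values(self) -> list:
        return [p[0] for p in self.points]

    def accuracies(self) -> list:
        return [p[1] for p in self.points]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": [p[0] for p in self.points],
             "mean_accuracy": [p[1] for p in self.points],
             "fold_accuracies": [",".join(f"{a:.6f}" for a in p[2]) for p in self.points]}
        )


# ---------------------------------------------------------------------------
# splitting and cross-validation
# ---------------------------------------------------------------------------


def split_half(dataset: LabelledDataset, seed: int = 0) -> tuple[LabelledDataset, LabelledDataset]:
    """Stratified 50/50 split into training and testing cohorts; per-class
    sizes on the two sides differ by at most one."""
    counts = dataset.labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"classes of size 1 cannot be split: {counts[counts < 2].index.tolist()}")
    samples = dataset.matrix.sample_ids.to_numpy()
    tr, te = train_test_split(
        samples, test_size=0.5, stratify=dataset.labels.to_numpy(), random_state=seed
    )
    return dataset.subset_samples(list(tr)), dataset.subset_samples(list(te))


def cross_validate(
    dataset: LabelledDataset,
    spec: ClassifierSpec | str,
    n_folds: int = 5,
    seed: int = 0,
    feature_subset=None,
) -> EvaluationReport:
    """Stratified k-fold CV with pooled (micro) confusion accounting.

    Each sample is tested exactly once; the report keeps fold assignments
    and per-fold predictions so pooled numbers can be recomputed.
    ``feature_subset`` restricts the matrix to the given features first
    (rank them on independent data to stay leakage-safe).
    """
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    ds = dataset if feature_subset is None else dataset.subset_features(feature_subset)
    ds.matrix.require_complete("cross_validate")
    X, y = ds.to_xy()
    counts = y.value_counts()
    if (counts < n_folds).any():
        raise ValueError(
            f"classes smaller than n_folds={n_folds}: {counts[counts < n_folds].index.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    samples = X.index.to_numpy()
    fold_assignments: dict = {}
    predictions: dict = {}
    fold_accuracies = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = train(spec, X.iloc[tr], y.iloc[tr], seed=seed)
        labels, _ = predict(model, X.iloc[te])
        for s, lab in zip(samples[te], labels):
            fold_assignments[s] = fold
            predictions[s] = lab
        fold_accuracies.append(overall_accuracy(y.iloc[te].to_numpy(), labels))
    y_true = np.asarray([y.loc[s] for s in samples])
    y_pred = np.asarray([predictions[s] for s in samples])
    return EvaluationReport(
        overall_accuracy=overall_accuracy(y_true, y_pred),
        per_class=precision_recall(y_true, y_pred),
        fold_assignments=fold_assignments,
        fold_accuracies=fold_accuracies,
        predictions={s: predictions[s] for s in samples},
        truths={s: y.loc[s] for s in samples},
        config={"classifier": spec if isinstance(spec, str) else spec.name,
                "n_folds": n_folds, "seed": seed},
    )


def evaluate_protocol(
    dataset: LabelledDataset,
    spec: ClassifierSpec | str,
    n_top_features: int,
    n_folds: int = 5,
    seed: int = 0,
    w_s: float = 1.0,
    w_d: float = 1.0,
    fdr_threshold: float | None = 0.01,
    whole_data_cv: bool = False,
) -> tuple[EvaluationReport, list]:
    """Published protocol, leakage-safe: rank features on the training
    half, then run stratified CV on the held-out half restricted to the
    top-ranked features. ``whole_data_cv=True`` instead ranks and
    cross-validates on the full cohort (the original paper's reading is
    ambiguous between the two)."""
    if whole_data_cv:
        rank_on, cv_on = dataset, dataset
    else:
        rank_on, cv_on = split_half(dataset, seed=seed)
    _, ranking = mfmd_rank(rank_on, w_s=w_s, w_d=w_d, fdr_threshold=fdr_threshold)
    top = select_top_k(ranking, min(n_top_features, len(ranking)))
    report = cross_validate(cv_on, spec, n_folds=n_folds, seed=seed, feature_subset=top)
    return report, top


def marker_curve(
    dataset: LabelledDataset,
    ranked_features: list,
    k_grid=(10, 50, 100, 250, 500, 1000, 2000),
    spec: ClassifierSpec | str = "LASSO",
    n_folds: int = 5,
    seed: int = 0,
) -> MarkerCurve:
    """Cross-validated accuracy at each top-k prefix of a ranked feature
    list — the accuracy-versus-number-of-markers experiment."""
    k_grid = list(k_grid)
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be strictly increasing")
    if k_grid[-1] > len(ranked_features):
        raise ValueError(f"max k {k_grid[-1]} exceeds ranked list length {len(ranked_features)}")
    points = []
    for k in k_grid:
        report = cross_validate(
            dataset, spec, n_folds=n_folds, seed=seed,
            feature_subset=select_top_k(ranked_features, k),
        )
        points.append((k, report.overall_accuracy, report.fold_accuracies))
    return MarkerCurve(points)


def compare_profiles(
    datasets: dict,
    specs,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, EvaluationReport]:
    """Profile-by-classifier table of pooled CV accuracies over shared
    samples, plus the full per-class report of the best cell."""
    names = list(datasets)
    ref = datasets[names[0]].labels.sort_index()
    for name in names[1:]:
        other = datasets[name].labels.sort_index()
        if not ref.equals(other):
            raise ValueError(f"profile {name!r} has different samples or labels")
    spec_names = [s if isinstance(s, str) else s.name for s in specs]
    table = pd.DataFrame(index=names, columns=spec_names, dtype=float)
    best = (-1.0, None)
    for pname in names:
        for spec, sname in zip(specs, spec_names):
            report = cross_validate(datasets[pname], spec, n_folds=n_folds, seed=seed)
            table.loc[pname, sname] = report.overall_accuracy
            if report.overall_accuracy > best[0]:
                best = (report.overall_accuracy, report)
    return table, best[1]
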