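"""The eight classifier configurations behind one train/predict contract.

Model fitting is delegated to scikit-learn; the contribution here is the
faithful configuration of each model and a uniform contract: every
trained model exposes calibrated-or-pseudo class probabilities whose
rows sum to one, and rejects inputs whose feature signature differs from
training.

Configurations:

=====  ==================================================================
RF     random forest, 200 trees, soft voting (per-tree probability mean)
SVM    linear-kernel SVM, one-vs-rest; probabilities by softmax over the
       per-class decision values (a convention, not a calibration)
KNN    K-nearest neighbors, K = 5, Euclidean distance
DT     CART decision tree, Gini impurity, unpruned
LDA    linear discriminant analysis, one-vs-rest
LASSO  L1-regularized logistic regression (one-vs-rest), logistic-
       function class probabilities
NN     feed-forward neural network, one hidden layer of 128 ReLU units,
       trained by backpropagation (up to 500 epochs)
NBC    Gaussian naive Bayes (independence across features)
=====  ==================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .config import CLASSIFIER_NAMES, DEFAULT_CLASSIFIER_PARAMS


@dataclass
class ClassifierSpec:
    """One of the eight named model configurations plus hyperparameter
    overrides (missing entries fall back to the published settings)."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}")
        defaults = dict(DEFAULT_CLASSIFIER_PARAMS[self.name])
        unknown = set(self.params) - set(defaults) if defaults else set(self.params)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.name}: {sorted(unknown)}")
        defaults.update(self.params)
        self.params = defaults


class SoftmaxOvRSVC(BaseEstimator, ClassifierMixin):
    """Linear one-vs-rest SVM whose ``predict_proba`` is the softmax of
    the per-class decision values — a normalized pseudo-probability, not
    a calibrated one."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        self.ovr_ = OneVsRestClassifier(SVC(kernel="linear", C=self.C)).fit(X, y)
        self.classes_ = self.ovr_.classes_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "ovr_")
        return self.ovr_.decision_function(X)

    def predict_proba(self, X):
        scores = self.decision_function(X)
        if scores.ndim == 1:                      # binary: one margin column
            scores = np.column_stack([-scores, scores])
        return softmax(scores, axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_classifier(spec: ClassifierSpec | str, seed: int = 0):
    """Instantiate an unfitted scikit-learn estimator for a spec."""
    if isinstance(spec, str):
        spec = ClassifierSpec(spec)
    p = spec.params
    if spec.name == "RF":
        return RandomForestClassifier(n_estimators=p["n_trees"], random_state=seed)
    if spec.name == "SVM":
        return SoftmaxOvRSVC(C=p["C"])
    if spec.name == "KNN":
        return KNeighborsClassifier(n_neighbors=p["k"], metric="euclidean")
    if spec.name == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if spec.name == "LDA":
        return OneVsRestClassifier(LinearDiscriminantAnalysis())
    if spec.name == "LASSO":
        return OneVsRestClassifier(
            LogisticRegression(l1_ratio=1.0, solver="liblinear", C=p["C"], random_state=seed)
        )
    if spec.name == "NN":
        return MLPClassifier(
            hidden_layer_sizes=tuple(p["hidden"]), activation="relu",
            max_iter=p["max_epochs"], early_stopping=False, random_state=seed,
        )
    if spec.name == "NBC":
        return GaussianNB()
    raise AssertionError(spec.name)


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    estimator: object
    classes_: np.ndarray
    feature_signature: tuple

    def predict(self, X):
        return predict(self, X)


def _signature(X: pd.DataFrame) -> tuple:
    return tuple(str(c) for c in X.columns)


def train(spec: ClassifierSpec | str, X, y, seed: int = 0) -> TrainedClassifier:
    """Fit one configuration on (samples x features, labels).

    Rejects NaN inputs and singleton classes; training is deterministic
    given the seed.
    """
    if isinstance(spec, str):
        spec = ClassifierSpec(spec)
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y))
    if X.isna().to_numpy().any():
        raise ValueError("training matrix contains NaN (impute first)")
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("training needs >= 2 classes")
    if (counts < 2).any():
        raise ValueError(f"singleton classes: {counts[counts < 2].index.tolist()}")
    est = make_classifier(spec, seed=seed).fit(X.to_numpy(dtype=float), y.to_numpy())
    return TrainedClassifier(
        spec=spec, estimator=est, classes_=np.asarray(est.classes_),
        feature_signature=_signature(X),
    )


def predict(model: TrainedClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and a class-probability matrix (rows sum to 1); the
    predicted label is the argmax row-wise."""
    X = pd.DataFrame(X)
    if _signature(X) != model.feature_signature:
        raise ValueError("feature signature differs from the training matrix")
    proba = model.estimator.predict_proba(X.to_numpy(dtype=float))
    proba = proba / proba.sum(axis=1, keepdims=True)
    labels = model.classes_[np.argmax(proba, axis=1)]
    return labels, proba


def clone_classifier(spec: ClassifierSpec | str, seed: int = 0):
    return clone(make_classifier(spec, seed=seed))
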