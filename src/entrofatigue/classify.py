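"""The ten-classifier comparison harness.

The benchmark compares ten standard supervised learners on each
(channel, feature) cell: k-nearest neighbours (KNN), linear-kernel SVM (LS),
RBF-kernel SVM (RS), Gaussian process (GP), decision tree (DT), random forest
(RF), multilayer perceptron (MLP), AdaBoost (AB), Gaussian naive Bayes (GNB)
and quadratic discriminant analysis (QDA).  The algorithms themselves come
from scikit-learn; this module pins the benchmark configurations:

=====  =======================================================
KNN    k = 5
LS     linear kernel, C = 1
RS     RBF kernel, gamma = 2, C = 1
DT     max_depth = 10
RF     10 trees, max_depth = 10
MLP    one hidden layer of 100 units, max 500 iterations
GP/AB/GNB/QDA  library defaults
=====  =======================================================

Anything not pinned above is the scikit-learn default (recorded in the run
manifest for reproducibility).  Stochastic learners are seeded from
``ClassifierSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_NAMES = ("KNN", "LS", "RS", "GP", "DT", "RF", "MLP", "AB", "GNB", "QDA")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration: short name, overrides, seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}")


def _factories(seed: int) -> dict:
    return {
        "KNN": lambda kw: KNeighborsClassifier(**{"n_neighbors": 5, **kw}),
        "LS": lambda kw: SVC(**{"kernel": "linear", "C": 1.0, **kw}),
        "RS": lambda kw: SVC(**{"kernel": "rbf", "gamma": 2.0, "C": 1.0, **kw}),
        "GP": lambda kw: GaussianProcessClassifier(**{"random_state": seed, **kw}),
        "DT": lambda kw: DecisionTreeClassifier(**{"max_depth": 10, "random_state": seed, **kw}),
        "RF": lambda kw: RandomForestClassifier(
            **{"n_estimators": 10, "max_depth": 10, "random_state": seed, **kw}),
        "MLP": lambda kw: MLPClassifier(
            **{"hidden_layer_sizes": (100,), "max_iter": 500, "random_state": seed, **kw}),
        "AB": lambda kw: AdaBoostClassifier(**{"random_state": seed, **kw}),
        "GNB": lambda kw: GaussianNB(**kw),
        "QDA": lambda kw: QuadraticDiscriminantAnalysis(**kw),
    }


def build_classifier(spec: ClassifierSpec):
    """Instantiate a fresh, unfitted scikit-learn estimator for a spec."""
    try:
        return _factories(spec.seed)[spec.name](dict(spec.params))
    except TypeError as exc:
        raise ValueError(f"invalid hyperparameter for {spec.name}: {exc}") from exc


def score_samples(model, X: np.ndarray) -> np.ndarray:
    """Continuous fatigue score per instance (higher = more fatigue-like).

    Uses the class-1 probability where the estimator provides one, otherwise
    the decision-function margin (oriented toward the positive class by
    scikit-learn's convention for binary problems with classes [0, 1]).
    """
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        idx = int(np.where(model.classes_ == 1)[0][0])
        return proba[:, idx]
    margin = model.decision_function(X)
    if model.classes_[1] != 1:  # orient toward label 1
        margin = -margin
    return margin


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The ten benchmark configurations, in canonical order."""
    return [ClassifierSpec(name=n, seed=seed) for n in CLASSIFIER_NAMES]
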