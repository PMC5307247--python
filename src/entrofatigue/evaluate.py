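"""Leave-one-out evaluation of (subject, channel, feature, classifier) cells.

The evaluation unit is one subject's pooled normal + fatigue epochs of a
single channel and a single entropy feature.  Each epoch is predicted by a
model trained on all the subject's remaining epochs (leave-one-epoch-out);
confusion counts are accumulated over the folds, and the AUC is computed from
the held-out continuous scores.  Per-subject within-subject folds are what
make per-subject accuracies well defined; a leave-one-subject-out or
stratified k-fold mode is available as an extension (the k-fold mode is a
smoke-test shortcut, not part of the benchmark protocol).

Metrics (positive class = fatigue):

    Sn = TP / (TP + FN),   Sp = TN / (TN + FP),
    Acc = (TP + TN) / (TP + TN + FP + FN),

with ``NaN`` as the undefined marker when a denominator is zero.  AUC uses
the midrank (Mann-Whitney) convention for ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, build_classifier, score_samples
from .preprocess import minmax_apply, minmax_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts, positive class = fatigue (label 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))


def compute_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN marks undefined ratios."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return acc, sn, sp


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of fatigue scores; midrank tie handling (Mann-Whitney)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes in labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class EvaluationResult:
    """Metrics for one (subject, channel, feature, classifier) cell."""

    subject: int
    channel: str
    feature: str
    classifier: str
    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    auc: float


def loo_evaluate(values: np.ndarray, labels: np.ndarray, spec: ClassifierSpec,
                 fold_normalize: bool = False, cv: int | None = None) -> EvaluationResult:
    """Leave-one-epoch-out evaluation of one feature column.

    Parameters
    ----------
    values : array, shape (n,) or (n, k)
        Feature value(s) per epoch (typically a single entropy feature).
    labels : int array, shape (n,)
        Epoch states, normal=0 / fatigue=1; both classes must have >= 2
        epochs.
    spec : ClassifierSpec
        Classifier configuration; a fresh estimator is built (and identically
        seeded) for every fold, so results are deterministic.
    fold_normalize : bool
        If True, fit the [-1, 1] min-max map on each training fold only and
        clip the held-out value — the leakage-free variant.  The default
        (False) assumes values were already normalized per subject.
    cv : int, optional
        If given, use stratified ``cv``-fold cross-validation instead of
        leave-one-out.  A smoke-test shortcut, not the benchmark protocol.

    Returns
    -------
    EvaluationResult with subject/channel/feature left as placeholders
    (filled in by :func:`evaluate_grid`).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("values and labels length mismatch")
    counts_per_class = np.bincount(y, minlength=2)
    if counts_per_class[0] < 2 or counts_per_class[1] < 2:
        raise ValueError("need at least 2 epochs of each class for leave-one-out")

    n = len(y)
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)

    if cv is None:
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=spec.seed)
        folds = list(skf.split(X, y))

    with warnings.catch_warnings():
        # short 1-D training folds routinely trigger convergence/collinearity
        # warnings in MLP/QDA; they are expected at this problem size
        warnings.simplefilter("ignore")
        for train_idx, test_idx in folds:
            X_train, X_test = X[train_idx], X[test_idx]
            if fold_normalize:
                bounds = [minmax_fit(X_train[:, j]) for j in range(X.shape[1])]
                X_train = np.column_stack(
                    [minmax_apply(X_train[:, j], bounds[j]) for j in range(X.shape[1])])
                X_test = np.column_stack(
                    [minmax_apply(X_test[:, j], bounds[j]) for j in range(X.shape[1])])
            model = build_classifier(spec)
            model.fit(X_train, y[train_idx])
            preds[test_idx] = model.predict(X_test)
            scores[test_idx] = score_samples(model, X_test)

    counts = ConfusionCounts.from_predictions(y, preds)
    acc, sn, sp = compute_metrics(counts)
    auc = compute_auc(scores, y)
    return EvaluationResult(subject=-1, channel="", feature="", classifier=spec.name,
                            counts=counts, acc=acc, sn=sn, sp=sp, auc=auc)


RESULT_COLUMNS = ("subject", "channel", "feature", "classifier",
                  "tp", "fp", "tn", "fn", "acc", "sn", "sp", "auc")


def evaluate_grid(features: pd.DataFrame, specs: list[ClassifierSpec],
                  fold_normalize: bool = False, cv: int | None = None,
                  progress: bool = False) -> pd.DataFrame:
    """Evaluate every (subject, channel, feature) cell with every classifier.

    ``features`` is the tidy table of :func:`~entrofatigue.entropy.extract_features`
    (normally after per-subject normalization).  Returns one row per cell and
    classifier with confusion counts and Acc/Sn/Sp/AUC.
    """
    required = {"subject", "channel", "feature", "label", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")

    rows = []
    groups = list(features.groupby(["subject", "channel", "feature"], sort=True))
    for gi, ((subject, channel, feature), cell) in enumerate(groups):
        cell = cell.sort_values("epoch") if "epoch" in cell.columns else cell
        values = cell["value"].to_numpy()
        labels = cell["label"].to_numpy()
        for spec in specs:
            res = loo_evaluate(values, labels, spec,
                               fold_normalize=fold_normalize, cv=cv)
            res = replace(res, subject=int(subject), channel=str(channel),
                          feature=str(feature))
            rows.append((res.subject, res.channel, res.feature, res.classifier,
                         res.counts.tp, res.counts.fp, res.counts.tn, res.counts.fn,
                         res.acc, res.sn, res.sp, res.auc))
        if progress:
            logger.info("evaluated cell %d/%d (subject %s, %s, %s)",
                        gi + 1, len(groups), subject, channel, feature)
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
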