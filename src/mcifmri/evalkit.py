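"""Cross-validated classifier evaluation and confusion-matrix diagnostics.

Provides stratified k-fold assignment (tenfold by default), SVM and random
forest adapters, fold-pooled confusion matrices in the HC/MCI orientation,
and the derived performance metrics.

A note on sensitivity/specificity: the study's result tables score the
healthy-control class as "positive" — their printed sensitivity is
TN/(TN+FP) and specificity TP/(TP+FN) in the usual MCI-positive notation.
Both conventions are reported: ``sens_hc_pos``/``spec_hc_pos`` reproduce the
tables, ``sens_std``/``spec_std`` are the standard MCI-positive values; the
two are mirror images of each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger("mcifmri")

CLASSIFIERS = ("SVM", "RF")

__all__ = [
    "CLASSIFIERS",
    "FoldAssignment",
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "stratified_folds",
    "make_classifier",
    "cross_validate",
    "metrics_from_confusion",
    "mean_roc_auc",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified fold index per subject."""

    fold_index: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_index == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_index != fold)[0]


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold partition; k is reduced (with a warning) if a class
    has fewer members than k."""
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = np.asarray(labels, dtype=int)
    if k == labels.shape[0]:  # leave-one-out: every fold a singleton
        return FoldAssignment(fold_index=np.arange(k), k=k, seed=seed)
    min_class = int(np.bincount(labels).min())
    if min_class < k:
        logger.warning(
            "reducing k from %d to %d: smallest class has only %d members", k, min_class, min_class
        )
        k = min_class
        if k < 2:
            raise ValueError("smallest class has fewer than 2 members; cannot cross-validate")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test) in enumerate(splitter.split(np.zeros_like(labels), labels)):
        fold_index[test] = fold
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pooled counts in the reference-HC-row orientation: [[TN, FP], [FN, TP]]."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tn + other.tn, self.fp + other.fp, self.fn + other.fn, self.tp + other.tp
        )

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.as_array(),
            index=["reference_HC", "reference_MCI"],
            columns=["predicted_HC", "predicted_MCI"],
        ).to_csv(path)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sens_hc_pos: float  # TN / (TN + FP): HC scored as the positive class
    spec_hc_pos: float  # TP / (TP + FN)
    sens_std: float  # TP / (TP + FN): standard MCI-positive convention
    spec_std: float  # TN / (TN + FP)
    mean_auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sens_hc_pos": self.sens_hc_pos,
            "spec_hc_pos": self.spec_hc_pos,
            "sens_std": self.sens_std,
            "spec_std": self.spec_std,
            "mean_auc": self.mean_auc,
        }


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (empty class); reporting NaN", what)
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix, mean_auc: float | None = None) -> MetricsReport:
    """Accuracy and sensitivity/specificity (both conventions) from counts."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    hc_rate = _safe_ratio(cm.tn, cm.tn + cm.fp, "HC recall")
    mci_rate = _safe_ratio(cm.tp, cm.tp + cm.fn, "MCI recall")
    return MetricsReport(
        accuracy=acc,
        sens_hc_pos=hc_rate,
        spec_hc_pos=mci_rate,
        sens_std=mci_rate,
        spec_std=hc_rate,
        mean_auc=mean_auc,
    )


def make_classifier(name: str, seed: int = 0, params: dict | None = None):
    """SVM (linear, C=1) or random forest (500 trees, sqrt features)."""
    params = dict(params or {})
    if name == "SVM":
        params.setdefault("kernel", "linear")
        params.setdefault("C", 1.0)
        return SVC(**params)
    if name == "RF":
        params.setdefault("n_estimators", 500)
        params.setdefault("max_features", "sqrt")
        params.setdefault("random_state", seed)
        return RandomForestClassifier(**params)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass
class CVResult:
    folds: FoldAssignment
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # decision scores, aligned to subjects
    fold_accuracies: list[float]
    fold_aucs: list[float]
    confusion: ConfusionMatrix
    report: MetricsReport = field(init=False)

    def __post_init__(self) -> None:
        auc = float(np.mean(self.fold_aucs)) if self.fold_aucs else None
        self.report = metrics_from_confusion(self.confusion, mean_auc=auc)

    @property
    def pooled_accuracy(self) -> float:
        return self.report.accuracy

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    classifier: str = "SVM",
    k: int = 10,
    seed: int = 0,
    clf_params: dict | None = None,
) -> CVResult:
    """Stratified k-fold CV of one classifier on the masked feature columns.

    Features are z-scored with training-fold statistics only. The pooled
    confusion matrix sums the per-fold test predictions; per-fold ROC-AUC is
    computed from decision scores and folds with a single class are skipped
    with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty feature mask")
        x = x[:, mask]
    folds = stratified_folds(y, k=k, seed=seed)
    y_pred = np.empty_like(y)
    scores = np.empty(y.shape[0], dtype=float)
    fold_accuracies: list[float] = []
    fold_aucs: list[float] = []
    for fold in range(folds.k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"training split for fold {fold} lacks a class; use fewer folds"
            )
        scaler = StandardScaler()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns scale to 0
            xtr = scaler.fit_transform(x[tr])
            xte = scaler.transform(x[te])
        clf = make_classifier(classifier, seed=seed, params=clf_params)
        clf.fit(xtr, y[tr])
        pred = clf.predict(xte)
        if hasattr(clf, "decision_function"):
            sc = clf.decision_function(xte)
        else:
            sc = clf.predict_proba(xte)[:, 1]
        y_pred[te] = pred
        scores[te] = sc
        fold_accuracies.append(float(np.mean(pred == y[te])))
        if len(np.unique(y[te])) < 2:
            logger.warning("fold %d has a single class in the test split; AUC skipped", fold)
        else:
            fold_aucs.append(float(roc_auc_score(y[te], sc)))
    confusion = ConfusionMatrix.from_predictions(y, y_pred)
    return CVResult(
        folds=folds,
        y_true=y,
        y_pred=y_pred,
        scores=scores,
        fold_accuracies=fold_accuracies,
        fold_aucs=fold_aucs,
        confusion=confusion,
    )


def mean_roc_auc(cv: CVResult) -> float:
    """Mean of the per-fold ROC-AUCs."""
    if not cv.fold_aucs:
        raise ValueError("no fold had both classes in its test split; AUC unavailable")
    return float(np.mean(cv.fold_aucs))
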