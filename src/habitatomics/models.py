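"""Grade classifiers and their evaluation.

Four classifiers (random forest, logistic regression, decision tree, RBF
support vector machine) are trained per region on the candidate features
and scored with ROC/AUC plus accuracy, precision, recall and F1. The
positive class is high grade throughout. Hyperparameters are pinned,
documented defaults (no tuning): RF 500 trees; LR L2, C=1; DT gini,
unlimited depth; SVM RBF, C=1 with decision-function scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "EvaluationReport",
    "train_classifiers",
    "decision_scores",
    "evaluate",
    "split_cohort",
]

MODEL_NAMES = ("RF", "LR", "DT", "SVM")


@dataclass
class EvaluationReport:
    model: str
    region: str
    split: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "region": self.region,
            "split": self.split,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def _make_model(name: str, seed: int):
    if name == "RF":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if name == "LR":
        return LogisticRegression(C=1.0, max_iter=5000)
    if name == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    raise ValueError(f"unknown model {name!r}")


def train_classifiers(
    X_train: np.ndarray,
    y_train: np.ndarray,
    model_names=MODEL_NAMES,
    seed: int = 0,
) -> dict[str, object]:
    """Fit the configured classifiers; all randomness is seeded."""
    y_train = np.asarray(y_train)
    classes, counts = np.unique(y_train, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    Xa = np.asarray(X_train, dtype=float)
    const = Xa.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature column(s) in training data")
    return {name: _make_model(name, seed).fit(Xa, y_train) for name in model_names}


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous class scores for ROC: probabilities if available, else margins."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def evaluate(
    model,
    X: np.ndarray,
    y: np.ndarray,
    model_name: str = "",
    region: str = "",
    split: str = "",
    average: str = "binary",
) -> EvaluationReport:
    """Threshold metrics for the high-grade (positive) class plus ROC/AUC.

    AUC is trapezoidal over all score thresholds (equivalently the
    Mann-Whitney concordance probability). With single-class ``y`` the AUC
    is undefined and reported as NaN with a warning; the threshold metrics
    are still returned. ``average`` may be 'binary' (positive class,
    default) or 'weighted'.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pred = model.predict(X)
    scores = decision_scores(model, X)
    kw = {"average": average, "zero_division": 0}
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: AUC undefined (NaN)")
        auc = float("nan")
        roc = None
    else:
        auc = float(roc_auc_score(y, scores))
        fpr, tpr, thr = roc_curve(y, scores)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return EvaluationReport(
        model=model_name,
        region=region,
        split=split,
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, **kw)),
        recall=float(recall_score(y, pred, **kw)),
        f1=float(f1_score(y, pred, **kw)),
        auc=auc,
        roc=roc,
    )


def split_cohort(
    patient_ids,
    grades,
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train / internal-test split of the cohort.

    ``ratio`` is the training fraction (7:3 by default); the test set gets
    the ceiling of the complement (186 patients -> 130 train / 56 test),
    and grade proportions are preserved within one patient per stratum.
    """
    patient_ids = np.asarray(patient_ids)
    grades = np.asarray(grades)
    if len(patient_ids) < 10:
        raise ValueError("need at least 10 patients to split")
    _, counts = np.unique(grades, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every grade stratum must have at least 2 patients")
    train_ids, test_ids = train_test_split(
        patient_ids,
        train_size=ratio,
        stratify=grades,
        random_state=seed,
        shuffle=True,
    )
    return train_ids, test_ids
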