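"""Classifier training, leave-one-subject-out cross-validation, and
best-algorithm selection.

Five classifier families are supported: logistic regression, a linear
SVM (the family classically trained with sequential minimal optimisation),
adaptive boosting, random forest, and a pruned decision tree.
Hyperparameters are conventional defaults; features are standardized
inside each training fold (scale-sensitive learners, and no information
may flow from a held-out subject into training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionCounts, classification_metrics
from .io import LABELS, ValidationError

#: Fixed roster order — also the final tie-break in best-algorithm selection.
ALGORITHMS = (
    "logistic_regression",
    "svm_smo",
    "adaboost",
    "random_forest",
    "j48_tree",
)

POSITIVE_LABEL = "correct"


class TrainingError(ValueError):
    pass


@dataclass
class LabelledDataset:
    """Aligned features / labels / subject ids for one exercise."""

    X: np.ndarray
    y: np.ndarray          # label strings
    subjects: np.ndarray   # subject id strings
    exercise: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.subjects) == n):
            raise ValidationError("X, y and subjects must align row-wise")
        bad = set(self.y) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}")

    @property
    def n_reps(self) -> int:
        return self.X.shape[0]

    def subject_ids(self) -> list[str]:
        return sorted(set(self.subjects.tolist()))


@dataclass
class CvResult:
    """Pooled leave-one-subject-out result for one algorithm."""

    algorithm: str
    exercise: str
    predictions: dict[str, np.ndarray]  # subject -> predicted labels
    counts: ConfusionCounts
    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    skipped_subjects: list[str] = field(default_factory=list)


def make_estimator(algorithm: str, seed: int = 0) -> Pipeline:
    """A standardize-then-classify pipeline for one algorithm family."""
    if algorithm == "logistic_regression":
        clf = LogisticRegression(max_iter=2000)
    elif algorithm == "svm_smo":
        clf = SVC(kernel="linear", C=1.0)
    elif algorithm == "adaboost":
        clf = AdaBoostClassifier(n_estimators=100, random_state=seed)
    elif algorithm == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif algorithm == "j48_tree":
        clf = DecisionTreeClassifier(min_samples_leaf=2, random_state=seed)
    else:
        raise TrainingError(f"unknown algorithm {algorithm!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(data: LabelledDataset, algorithm: str, seed: int = 0) -> Pipeline:
    """Fit one algorithm on a full dataset (both classes required)."""
    if len(set(data.y.tolist())) < 2:
        raise TrainingError("training data must contain both classes")
    est = make_estimator(algorithm, seed)
    est.fit(data.X, data.y)
    return est


def _pool_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos = POSITIVE_LABEL
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def losocv(data: LabelledDataset, algorithm: str, seed: int = 0) -> CvResult:
    """Leave-one-subject-out cross-validation with pooled confusion counts.

    Each fold trains on all other subjects and predicts the held-out
    subject's repetitions.  Folds whose training split lacks a class are
    skipped with a warning and recorded on the result.
    """
    subjects = data.subject_ids()
    if len(subjects) < 2:
        raise ValidationError("LOSOCV needs at least 2 subjects")
    predictions: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    for subject in subjects:
        test_mask = data.subjects == subject
        train_mask = ~test_mask
        y_train = data.y[train_mask]
        if len(set(y_train.tolist())) < 2:
            warnings.warn(
                f"LOSOCV fold for subject {subject!r} skipped: training split "
                "lacks a class",
                stacklevel=2,
            )
            skipped.append(subject)
            continue
        est = make_estimator(algorithm, seed)
        est.fit(data.X[train_mask], y_train)
        pred = est.predict(data.X[test_mask])
        predictions[subject] = pred
        y_true_all.append(data.y[test_mask])
        y_pred_all.append(pred)
    if not y_pred_all:
        raise TrainingError("every LOSOCV fold was skipped")
    counts = _pool_counts(np.concatenate(y_true_all), np.concatenate(y_pred_all))
    accuracy, sensitivity, specificity = classification_metrics(counts)
    return CvResult(
        algorithm=algorithm,
        exercise=data.exercise,
        predictions=predictions,
        counts=counts,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        skipped_subjects=skipped,
    )


def select_best_algorithm(results: Sequence[CvResult]) -> str:
    """Highest accuracy; ties broken by sensitivity, then roster order."""
    if not results:
        raise ValidationError("cannot select from an empty result list")

    def key(r: CvResult):
        sens = r.sensitivity if r.sensitivity is not None else -1.0
        return (-r.accuracy, -sens, ALGORITHMS.index(r.algorithm))

    return min(results, key=key).algorithm
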