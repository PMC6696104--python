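"""Confusion-matrix evaluation and classical baselines (LDA, SVM, MLP).

The headline metric is the average recognition rate: the unweighted mean of
per-class recalls.  With balanced test classes this equals overall accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datatypes import CLASS_INDEX, CLASS_ORDER, PatternClass, WindowSample
from .model import TrainedModel, predict, standardize_windows

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "report",
    "run_baseline",
    "evaluate_model",
    "BASELINES",
]

#: baseline hyperparameters, recorded verbatim in every report
BASELINES = {
    "LDA": "LinearDiscriminantAnalysis(solver='svd')",
    "SVM": "SVC(kernel='rbf', C=1.0, gamma='scale')",
    "MLP": "MLPClassifier(hidden_layer_sizes=(256,), max_iter=500)",
}


@dataclass
class ConfusionMatrix:
    """5x5 count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_order: tuple[PatternClass, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [c.value for c in self.class_order]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class EvalReport:
    """Per-class recalls and their unweighted mean for one method."""

    per_class_rate: dict[PatternClass, float]
    average_rate: float
    matrix: ConfusionMatrix
    method_name: str
    details: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": c.value, "recognition_rate": r}
                for c, r in self.per_class_rate.items()]
        rows.append({"class": "average", "recognition_rate": self.average_rate})
        return pd.DataFrame(rows)


def _as_indices(labels: Sequence[PatternClass]) -> np.ndarray:
    try:
        return np.array([CLASS_INDEX[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown class label: {exc.args[0]}") from exc


def confusion(true_labels: Sequence[PatternClass],
              predicted_labels: Sequence[PatternClass]) -> ConfusionMatrix:
    """Tally counts[i][j] = #(true=i, predicted=j) over the fixed class order."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    if len(true_labels) == 0:
        raise ValueError("empty label sequences")
    yt = _as_indices(true_labels)
    yp = _as_indices(predicted_labels)
    counts = _sk_confusion(yt, yp, labels=list(range(len(CLASS_ORDER))))
    return ConfusionMatrix(counts=counts)


def report(matrix: ConfusionMatrix, method_name: str = "",
           details: str = "") -> EvalReport:
    """Per-class recall (diagonal over row sum) and the average rate.

    A class absent from the test set (empty row) is excluded from the average
    with a warning.
    """
    rates: dict[PatternClass, float] = {}
    for i, cls in enumerate(matrix.class_order):
        row = matrix.counts[i].sum()
        if row == 0:
            warnings.warn(f"class {cls.value} has no test samples; "
                          "excluded from the average", stacklevel=2)
            continue
        rates[cls] = float(matrix.counts[i, i] / row)
    if not rates:
        raise ValueError("every class row is empty")
    return EvalReport(per_class_rate=rates,
                      average_rate=float(np.mean(list(rates.values()))),
                      matrix=matrix, method_name=method_name, details=details)


def _make_baseline(name: str, seed: int):
    key = name.upper()
    if key == "LDA":
        return LinearDiscriminantAnalysis()
    if key == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if key == "MLP":
        return MLPClassifier(hidden_layer_sizes=(256,), max_iter=500,
                             random_state=seed)
    raise ValueError(f"unknown baseline {name!r}; expected LDA, SVM, or MLP")


def run_baseline(name: str, train_samples: Sequence[WindowSample],
                 test_samples: Sequence[WindowSample], seed: int = 0) -> EvalReport:
    """Fit one classical classifier on flattened standardized windows.

    The baselines see exactly the same per-window standardization as the CNN.
    """
    if len(train_samples) == 0 or len(test_samples) == 0:
        raise ValueError("train and test sets must be non-empty")
    y_train = _as_indices([s.label for s in train_samples])
    if np.unique(y_train).size < 2:
        raise ValueError("training set is degenerate: a single class")
    Xtr = standardize_windows(train_samples).astype(np.float64)
    Xte = standardize_windows(test_samples).astype(np.float64)
    clf = _make_baseline(name, seed)
    clf.fit(Xtr, y_train)
    pred_idx = clf.predict(Xte)
    pred = [CLASS_ORDER[int(i)] for i in pred_idx]
    mat = confusion([s.label for s in test_samples], pred)
    return report(mat, method_name=name.upper(),
                  details=BASELINES[name.upper()])


def evaluate_model(model: TrainedModel, test_samples: Sequence[WindowSample],
                   method_name: str = "1D CNN") -> EvalReport:
    """Confusion-matrix report of a trained CNN on a test set."""
    _, pred = predict(model, test_samples)
    mat = confusion([s.label for s in test_samples], pred)
    return report(mat, method_name=method_name)
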