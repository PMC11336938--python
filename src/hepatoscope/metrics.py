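"""Classifier evaluation: ROC/AUC, confusion matrix, report serialisation.

The AUC is computed from the ranking definition — the probability that a
randomly chosen positive subject outscores a randomly chosen negative
one, ties counting one half — which equals the trapezoidal area under
the ROC curve; the suite cross-checks the two routes against each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["roc_auc", "confusion_and_accuracy", "EvalReport", "evaluate_scores"]


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC and ROC points for binary ``labels`` scored by ``scores``.

    Returns ``(auc, roc)`` where ``roc`` is an (n, 2) array of
    (false-positive rate, true-positive rate) points running from (0, 0)
    to (1, 1).  The AUC is the Mann-Whitney ranking statistic
    ``P(score+ > score-) + P(tie)/2``.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC")
    ranks = rankdata(scores)  # midranks handle ties -> the 1/2 convention
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return float(auc), np.column_stack([fpr, tpr])


def confusion_and_accuracy(
    scores, labels, threshold: float = 0.5
) -> tuple[np.ndarray, float, np.ndarray]:
    """Threshold scores and tabulate (truth x prediction) counts.

    Returns the 2x2 confusion matrix (rows = truth 0/1, columns =
    prediction 0/1), overall accuracy, and per-class misclassification
    rates (off-diagonal over row sum).
    """
    scores, labels = _validate(scores, labels)
    preds = (scores >= threshold).astype(int)
    cm = _sk_confusion(labels, preds, labels=[0, 1])
    accuracy = float(np.trace(cm) / cm.sum())
    row_sums = cm.sum(axis=1)
    misclass = np.divide(
        np.array([cm[0, 1], cm[1, 0]], dtype=float),
        row_sums,
        out=np.zeros(2),
        where=row_sums > 0,
    )
    return cm, accuracy, misclass


@dataclass
class EvalReport:
    """Evaluation of one model on one partition."""

    model_name: str
    partition: str
    accuracy: float
    auc: float
    roc: np.ndarray
    confusion: np.ndarray
    misclassification: np.ndarray
    n_subjects: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "partition": self.partition,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc": self.roc.tolist(),
            "confusion": self.confusion.tolist(),
            "misclassification": self.misclassification.tolist(),
            "n_subjects": self.n_subjects,
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        d = json.loads(Path(path).read_text())
        d["roc"] = np.asarray(d["roc"], dtype=float)
        d["confusion"] = np.asarray(d["confusion"], dtype=int)
        d["misclassification"] = np.asarray(d["misclassification"], dtype=float)
        return cls(**d)

    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc, columns=["fpr", "tpr"])


def evaluate_scores(
    scores,
    labels,
    *,
    model_name: str = "model",
    partition: str = "test",
    threshold: float = 0.5,
    config: dict | None = None,
) -> EvalReport:
    """Bundle AUC, accuracy and confusion counts into an :class:`EvalReport`."""
    auc, roc = roc_auc(scores, labels)
    cm, accuracy, misclass = confusion_and_accuracy(scores, labels, threshold)
    return EvalReport(
        model_name=model_name,
        partition=partition,
        accuracy=accuracy,
        auc=auc,
        roc=roc,
        confusion=cm,
        misclassification=misclass,
        n_subjects=int(np.asarray(labels).size),
        config=config or {},
    )
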