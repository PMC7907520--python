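"""Classifier evaluation: ROC/AUC, threshold metrics, and per-feature
class-comparison t-tests.

The positive class is EGFR(+) throughout. AUC is computed in its
Mann–Whitney form — the probability that a random positive scores
above a random negative, counting ties as ½ — which is invariant under
any strictly monotone rescaling of the scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, LabelVector

__all__ = ["EvalReport", "auc", "threshold_metrics", "two_sample_t", "make_report", "roc_points"]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score⁺ > score⁻) + ½ P(score⁺ = score⁻)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties as ½
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs over all score thresholds, ascending FPR."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist()))


@dataclass
class ThresholdMetrics:
    accuracy: float
    recall: float
    precision: float
    f_score: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    threshold: float
    precision_undefined: bool = False


def threshold_metrics(scores, labels, threshold: float = 0.5) -> ThresholdMetrics:
    """Hard-label metrics at a score threshold (default 0.5).

    When no positives are predicted, precision is reported as 0 with a
    warning flag rather than NaN so reports stay comparable.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty score vector")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    accuracy = (tp + tn) / len(labels)
    recall = tp / (tp + fn) if tp + fn else 0.0
    undefined = (tp + fp) == 0
    if undefined:
        warnings.warn("no positive predictions: precision reported as 0", stacklevel=2)
    precision = 0.0 if undefined else tp / (tp + fp)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ThresholdMetrics(
        accuracy=accuracy, recall=recall, precision=precision, f_score=f,
        confusion=np.array([[tn, fp], [fn, tp]]), threshold=threshold,
        precision_undefined=undefined,
    )


def two_sample_t(
    table: FeatureTable, labels: LabelVector, equal_var: bool = True
) -> pd.DataFrame:
    """Independent two-sample t-test per feature, EGFR(+) vs EGFR(−).

    Classical pooled-variance (Student) form by default; set
    ``equal_var=False`` for Welch. Returns a frame with columns
    (feature_name, t, p, sig_05, sig_001); t > 0 means the feature is
    higher in the mutated group.
    """
    if table.patient_ids != labels.patient_ids:
        raise ValueError("table and labels must be aligned")
    y = labels.labels
    a, b = table.values[y == 1], table.values[y == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per class")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    return pd.DataFrame(
        {
            "feature_name": table.feature_names,
            "t": t,
            "p": p,
            "sig_05": p < 0.05,
            "sig_001": p < 0.001,
        }
    )


@dataclass
class EvalReport:
    """One model on one cohort split: ranking and threshold metrics."""

    model_id: str
    cohort_id: str
    n: int
    accuracy: float
    auc: float
    recall: float
    precision: float
    f_score: float
    threshold: float
    confusion: np.ndarray
    roc: list[tuple[float, float]] = field(default_factory=list)
    precision_undefined: bool = False

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.shape != (2, 2) or self.confusion.sum() != self.n:
            raise ValueError("confusion matrix must be 2×2 and sum to n")

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "cohort_id": self.cohort_id,
            "n": self.n,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "recall": self.recall,
            "precision": self.precision,
            "f_score": self.f_score,
            "threshold": self.threshold,
            "confusion": self.confusion.tolist(),
            "precision_undefined": self.precision_undefined,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def make_report(
    model_id: str,
    cohort_id: str,
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Assemble the full evaluation report from scores and labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    tm = threshold_metrics(scores, labels, threshold)
    return EvalReport(
        model_id=model_id,
        cohort_id=cohort_id,
        n=len(labels),
        accuracy=tm.accuracy,
        auc=auc(scores, labels),
        recall=tm.recall,
        precision=tm.precision,
        f_score=tm.f_score,
        threshold=threshold,
        confusion=tm.confusion,
        roc=roc_points(scores, labels),
        precision_undefined=tm.precision_undefined,
    )


def plot_roc(reports: list[EvalReport], path) -> None:
    """Write a ROC overlay for a set of reports (optional artifact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        xs, ys = zip(*rep.roc) if rep.roc else ((0, 1), (0, 1))
        ax.plot(xs, ys, label=f"{rep.model_id} (AUC={rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
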