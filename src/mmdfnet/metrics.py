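"""Risk-stratification evaluation metrics.

AUC is the Mann-Whitney rank statistic with tie-halving (delegated to
scikit-learn's ``roc_auc_score``); sensitivity, specificity, precision,
recall and F1 come from the confusion matrix at an explicit score threshold.
Sensitivity and specificity are reported in percent, matching the field's
reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["EvaluationReport", "evaluate_metrics", "youden_threshold"]


@dataclass(frozen=True)
class EvaluationReport:
    """One metrics row: AUC plus thresholded confusion-matrix statistics."""

    auc: float
    sensitivity: float   # percent, TP / (TP + FN) * 100
    specificity: float   # percent, TN / (TN + FP) * 100
    f1: float
    precision: float
    recall: float
    threshold: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return scores, labels


def evaluate_metrics(scores, labels, threshold: float = 0.5
                     ) -> EvaluationReport:
    """Compute AUC and confusion-matrix metrics at ``threshold``.

    ``labels`` are 1 for cases and 0 for controls; a score >= threshold
    predicts a case.
    """
    scores, labels = _validate(scores, labels)
    auc = float(roc_auc_score(labels, scores))
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = sens
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return EvaluationReport(auc=auc, sensitivity=100.0 * sens,
                            specificity=100.0 * spec, f1=f1, precision=prec,
                            recall=rec, threshold=float(threshold),
                            n=len(labels))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smallest qualifying threshold; candidate
    thresholds are the observed scores (a midpoint below the minimum is
    included so 'predict everything positive' is reachable).
    """
    scores, labels = _validate(scores, labels)
    candidates = np.unique(scores)
    candidates = np.concatenate([[candidates[0] - 1e-9], candidates])
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)
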