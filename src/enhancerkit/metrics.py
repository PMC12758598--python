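"""Binary-classification metrics.

AUROC is computed from the rank statistic (Mann–Whitney form, tie-aware);
AUPRC by step integration of the precision–recall curve; both are checked
against brute-force oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "confusion_counts", "classification_metrics",
           "auroc_score", "auprc_score"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def auroc_score(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """AUROC via the rank-sum statistic; ties handled by midranks."""
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined for single-class labels")
    ranks = rankdata(y_prob)
    pos_rank_sum = ranks[y_true == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc_score(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Average precision: sum of precision × recall increments, descending scores."""
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    if n_pos == 0 or (y_true == 0).sum() == 0:
        raise ValueError("AUPRC undefined for single-class labels")
    order = np.argsort(-y_prob, kind="stable")
    y_sorted = y_true[order]
    p_sorted = y_prob[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    # evaluate only at distinct-threshold boundaries (last index of each tie group)
    distinct = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tp = tp_cum[distinct]
    fp = fp_cum[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def classification_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> dict:
    """Accuracy, sensitivity, specificity, MCC, AUROC, AUPRC at a threshold.

    MCC denominator factors of 0 yield MCC = 0.  Single-class labels make
    AUROC/AUPRC undefined: they are returned as None with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("y_true must be binary 0/1")
    if ((y_prob < 0) | (y_prob > 1)).any():
        raise ValueError("y_prob must lie in [0, 1]")
    y_pred = (y_prob >= threshold).astype(int)
    c = confusion_counts(y_true, y_pred)
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    accuracy = (tp + tn) / c.n if c.n else 0.0
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    out = {
        "accuracy": float(accuracy),
        "sensitivity": float(sensitivity),
        "specificity": float(specificity),
        "mcc": float(mcc),
        "confusion": c,
    }
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class labels: AUROC/AUPRC undefined", stacklevel=2)
        out["auroc"] = None
        out["auprc"] = None
    else:
        out["auroc"] = auroc_score(y_true, y_prob)
        out["auprc"] = auprc_score(y_true, y_prob)
    return out
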