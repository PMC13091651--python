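"""Ranking and classification metrics for link prediction.

All metrics are computed from first principles on NumPy arrays so their
exact definitions are pinned down and testable against brute-force
references: AUC via the average-rank Mann-Whitney statistic, AUPR via
step-wise precision-recall integration over all unique score thresholds,
and NDCG on the single globally ranked list with binary gains and a
1/log2(rank+1) discount.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricsReport", "compute_metrics", "roc_auc", "average_precision",
           "ndcg", "aggregate_reports"]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return scores, labels.astype(np.int64)


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U with average-rank ties."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = rankdata(scores)  # average ranks for ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """AUPR via step-wise integration: sum (R_i - R_{i-1}) * P_i."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at the last index of each tied score block
    last_of_block = np.r_[s[1:] != s[:-1], True]
    tp_b = tp[last_of_block]
    fp_b = fp[last_of_block]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def ndcg(scores, labels) -> float:
    """Binary-gain NDCG over the globally ranked list.

    DCG uses discount 1/log2(rank+1); ties share the average discount of
    their rank block so the value is invariant to tie ordering.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("NDCG undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(np.float64)
    discounts = 1.0 / np.log2(np.arange(2, s.size + 2))
    # average discount within tied-score blocks
    block_ids = np.r_[0, np.cumsum(s[1:] != s[:-1])]
    dcg = 0.0
    for b in range(block_ids[-1] + 1):
        mask = block_ids == b
        dcg += y[mask].sum() * discounts[mask].mean()
    idcg = discounts[:n_pos].sum()
    return float(dcg / idcg)


@dataclass
class MetricsReport:
    """Metric values plus the confusion counts behind the thresholded ones.

    Metrics that are undefined for the given label vector (single class)
    are None, with their names listed in ``undefined``.
    """

    auc: float | None
    aupr: float | None
    ndcg: float | None
    f1: float
    precision: float
    recall: float
    threshold: float
    n_pos: int
    n_neg: int
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "AUC": self.auc, "AUPR": self.aupr, "NDCG": self.ndcg,
            "F1": self.f1, "Pre": self.precision, "Rec": self.recall,
            "threshold": self.threshold,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "undefined": list(self.undefined),
        }


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full metric suite at a probability ``threshold``.

    ``scores`` are probabilities (or any monotone transform for the
    ranking metrics).  Single-class inputs yield the defined subset with
    the missing metrics flagged in ``undefined``.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)

    undefined: list[str] = []
    auc = aupr = ndcg_val = None
    if n_pos and n_neg:
        auc = roc_auc(scores, labels)
    else:
        undefined.append("AUC")
    if n_pos:
        aupr = average_precision(scores, labels)
        ndcg_val = ndcg(scores, labels)
    else:
        undefined.extend(["AUPR", "NDCG"])

    return MetricsReport(auc=auc, aupr=aupr, ndcg=ndcg_val, f1=f1,
                         precision=precision, recall=recall,
                         threshold=threshold, n_pos=n_pos, n_neg=n_neg,
                         undefined=undefined)


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Mean and standard deviation per metric across folds."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict[str, dict[str, float]] = {}
    for key in ("AUC", "AUPR", "NDCG", "F1", "Pre", "Rec"):
        values = [r.to_dict()[key] for r in reports]
        if any(v is None for v in values):
            continue
        arr = np.asarray(values, dtype=np.float64)
        out[key] = {"mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0}
    return out
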