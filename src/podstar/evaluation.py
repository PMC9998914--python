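"""IoU matching of predicted vs ground-truth instances and derived metrics.

A prediction counts as a true positive at IoU threshold tau when it is
matched one-to-one to a ground-truth instance with IoU >= tau.  Matching
uses the optimal (maximum-total-IoU) assignment; for tau >= 0.5 at most
one prediction can exceed tau per ground-truth instance so greedy and
optimal coincide, and below 0.5 the optimal assignment provides a
deterministic, documented rule.

From a match: recall = TP/(TP+FN), precision = TP/(TP+FP), F1 their
harmonic mean; mean matched score = mean IoU over matched pairs; mean
true score = summed matched IoU / number of ground-truth instances;
panoptic quality = summed matched IoU / (TP + FP/2 + FN/2).  All 0/0
cases are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "match_instances",
    "detection_metrics",
    "segmentation_scores",
    "evaluate_over_taus",
    "iou_matrix",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching of ground-truth and predicted instances at tau."""

    n_true: int
    n_pred: int
    matches: tuple[tuple[int, int, float], ...]  # (gt label, pred label, IoU)
    tau: float

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fn(self) -> int:
        return self.n_true - self.tp

    @property
    def fp(self) -> int:
        return self.n_pred - self.tp

    @property
    def matched_ious(self) -> np.ndarray:
        return np.array([m[2] for m in self.matches], dtype=float)

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, mean_matched_iou: float = 1.0, tau: float = 0.5
    ) -> "MatchResult":
        """Build a match from confusion counts (worked-example entry point).

        Used to push published confusion tables through the metric
        formulas; each of the tp matches carries the stated mean IoU.
        """
        matches = tuple((i + 1, i + 1, float(mean_matched_iou)) for i in range(tp))
        return cls(n_true=tp + fn, n_pred=tp + fp, matches=matches, tau=tau)


def iou_matrix(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IoU between every gt and pred instance via the joint
    label histogram.  Returns (gt_ids, pred_ids, iou[gt, pred])."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    if gt.shape != pred.shape:
        raise ValueError("volumes must share a shape")
    gt_ids, gt_inv = np.unique(gt, return_inverse=True)
    pred_ids, pred_inv = np.unique(pred, return_inverse=True)
    joint = np.bincount(
        gt_inv.astype(np.int64) * len(pred_ids) + pred_inv,
        minlength=len(gt_ids) * len(pred_ids),
    ).reshape(len(gt_ids), len(pred_ids))
    gt_sizes = joint.sum(axis=1)
    pred_sizes = joint.sum(axis=0)
    keep_g = gt_ids > 0
    keep_p = pred_ids > 0
    inter = joint[np.ix_(keep_g, keep_p)].astype(float)
    union = gt_sizes[keep_g][:, None] + pred_sizes[keep_p][None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return gt_ids[keep_g], pred_ids[keep_p], iou


def match_instances(gt: np.ndarray, pred: np.ndarray, tau: float) -> MatchResult:
    """Optimal one-to-one IoU matching at threshold tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    gt_ids, pred_ids, iou = iou_matrix(gt, pred)
    matches: list[tuple[int, int, float]] = []
    if iou.size:
        cost = np.where(iou >= max(tau, 1e-12), iou, 0.0)
        rows, cols = linear_sum_assignment(cost, maximize=True)
        for r, c in zip(rows, cols):
            if iou[r, c] >= tau and iou[r, c] > 0:
                matches.append((int(gt_ids[r]), int(pred_ids[c]), float(iou[r, c])))
    matches.sort()
    return MatchResult(
        n_true=len(gt_ids), n_pred=len(pred_ids), matches=tuple(matches), tau=tau
    )


def detection_metrics(m: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, f1); any 0/0 is 0."""
    tp, fp, fn = m.tp, m.fp, m.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def segmentation_scores(m: MatchResult) -> tuple[float, float, float]:
    """(mean_matched_score, mean_true_score, panoptic_quality)."""
    total = float(m.matched_ious.sum())
    mean_matched = total / m.tp if m.tp else 0.0
    mean_true = total / m.n_true if m.n_true else 0.0
    denom = m.tp + m.fp / 2.0 + m.fn / 2.0
    pq = total / denom if denom else 0.0
    return mean_matched, mean_true, pq


def evaluate_over_taus(
    gt: np.ndarray, pred: np.ndarray, taus: tuple[float, ...]
) -> pd.DataFrame:
    """One metrics row per tau: counts plus detection/segmentation scores."""
    rows = []
    for tau in taus:
        m = match_instances(gt, pred, tau)
        precision, recall, f1 = detection_metrics(m)
        mean_matched, mean_true, pq = segmentation_scores(m)
        rows.append(
            {
                "tau": tau,
                "n_true": m.n_true,
                "n_pred": m.n_pred,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "mean_true_score": mean_true,
                "mean_matched_score": mean_matched,
                "panoptic_quality": pq,
            }
        )
    return pd.DataFrame(rows)
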