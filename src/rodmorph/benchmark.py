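"""Instance-segmentation benchmarking: IoU matching, TP/FP/FN, F1 curves.

Predicted instance masks are matched one-to-one against ground-truth
instances by maximizing total matched IoU (optimal assignment). At each IoU
threshold, matched pairs with IoU ≥ threshold count as true positives;
unmatched or below-threshold predictions are false positives and unmatched
ground truths false negatives. F1 = 2TP/(2TP+FP+FN) is evaluated on a grid
of thresholds (default 0.5 to 1.0 in steps of 0.05, eleven points) and
aggregated across images as the unweighted per-image mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import LabelMask

#: Default IoU threshold grid: 0.5 to 1.0 in 0.05 steps (11 thresholds).
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0 + 1e-9, 0.05), 2))

#: Slack so threshold 1.0 admits exact matches despite floating-point IoU.
IOU_SLACK = 1e-9


@dataclass
class MatchResult:
    """TP/FP/FN counts and matched (gt, pred, IoU) triples at one threshold."""

    threshold: float
    tp: int
    fp: int
    fn: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


@dataclass
class BenchmarkCurve:
    """Per-image and mean F1 across an IoU threshold grid."""

    thresholds: np.ndarray
    per_image: pd.DataFrame    # columns: image_id, threshold, tp, fp, fn, f1
    mean_f1: np.ndarray        # per threshold, unweighted mean across images


def _instance_areas(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return ids, counts


def instance_iou_matrix(gt: LabelMask, pred: LabelMask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IoU between ground-truth and predicted instances.

    Returns ``(iou, gt_ids, pred_ids)`` with ``iou[i, j]`` the intersection
    over union of ground-truth instance ``gt_ids[i]`` and predicted instance
    ``pred_ids[j]``. Background (0) is excluded.
    """
    if gt.shape != pred.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    g, p = gt.labels.ravel(), pred.labels.ravel()
    gt_ids, gt_areas = _instance_areas(g)
    pred_ids, pred_areas = _instance_areas(p)
    iou = np.zeros((gt_ids.size, pred_ids.size))
    if iou.size == 0:
        return iou, gt_ids, pred_ids
    both = (g > 0) & (p > 0)
    if both.any():
        pairs, inter = np.unique(np.stack([g[both], p[both]]), axis=1, return_counts=True)
        gi = np.searchsorted(gt_ids, pairs[0])
        pj = np.searchsorted(pred_ids, pairs[1])
        union = gt_areas[gi] + pred_areas[pj] - inter
        iou[gi, pj] = inter / union
    return iou, gt_ids, pred_ids


def match_at_threshold(iou: np.ndarray, threshold: float, greedy: bool = False) -> MatchResult:
    """Match instances one-to-one and count TP/FP/FN at one IoU threshold.

    Default matching maximizes total matched IoU over all one-to-one
    assignments; ``greedy`` instead repeatedly takes the highest remaining
    IoU pair (for comparison only — it can only lose true positives).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    iou = np.asarray(iou, dtype=float)
    n_gt, n_pred = iou.shape
    matches: list[tuple[int, int, float]] = []
    if n_gt and n_pred:
        if greedy:
            remaining = iou.copy()
            while True:
                i, j = np.unravel_index(np.argmax(remaining), remaining.shape)
                if remaining[i, j] <= 0:
                    break
                matches.append((i, j, float(iou[i, j])))
                remaining[i, :] = -1
                remaining[:, j] = -1
        else:
            rows, cols = linear_sum_assignment(iou, maximize=True)
            matches = [(int(i), int(j), float(iou[i, j])) for i, j in zip(rows, cols)]
    kept = [(i, j, v) for i, j, v in matches if v >= threshold - IOU_SLACK and v > 0]
    tp = len(kept)
    return MatchResult(threshold=float(threshold), tp=tp, fp=n_pred - tp, fn=n_gt - tp,
                       matches=kept)


def f1_curve(pairs: list[tuple[LabelMask, LabelMask]],
             thresholds=DEFAULT_THRESHOLDS,
             image_ids: list[str] | None = None,
             greedy: bool = False) -> BenchmarkCurve:
    """F1 across IoU thresholds for a list of (ground-truth, predicted) pairs.

    Per image and threshold, F1 = 2TP/(2TP+FP+FN) (0 when the denominator
    is 0). The aggregate curve is the unweighted mean of per-image F1 at
    each threshold.
    """
    if not pairs:
        raise ValueError("at least one (ground-truth, predicted) mask pair is required")
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if image_ids is None:
        image_ids = [f"image_{k}" for k in range(len(pairs))]
    rows = []
    for image_id, (gt, pred) in zip(image_ids, pairs):
        iou, _, _ = instance_iou_matrix(gt, pred)
        for t in thresholds:
            m = match_at_threshold(iou, t, greedy=greedy)
            rows.append({"image_id": image_id, "threshold": t,
                         "tp": m.tp, "fp": m.fp, "fn": m.fn, "f1": m.f1})
    per_image = pd.DataFrame(rows)
    mean_f1 = per_image.groupby("threshold")["f1"].mean().reindex(thresholds).to_numpy()
    return BenchmarkCurve(thresholds=thresholds, per_image=per_image, mean_f1=mean_f1)
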