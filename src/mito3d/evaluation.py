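"""Pixel-wise segmentation metrics and instance-level detection metrics.

Segmentation is scored by the Jaccard index |X∩Y|/|X∪Y|, the Dice
coefficient 2|X∩Y|/(|X|+|Y|) and the conformity coefficient (2J−1)/J — a
stricter global score that goes negative once J < 0.5 and to −∞ as J → 0.

Detection matches predicted 3D instances to ground-truth instances
one-to-one (greedy, by descending overlap); a match counts as a true
positive only when its voxel-wise overlap reaches the threshold τ (default
0.70). Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R). The
overlap functional is IoU by default; a ground-truth-coverage variant
|P∩G|/|G| is selectable. A sweep over τ (default 0.65–0.85) reports the
stability of the detection scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import LabelVolume

__all__ = [
    "SegScores",
    "DetectionCounts",
    "DetectionConfig",
    "segmentation_scores",
    "match_instances",
    "detection_scores",
    "threshold_sweep",
]

#: Sentinel for the conformity coefficient at Jaccard = 0 (its Eq. limit).
CONFORMITY_UNDEFINED = -math.inf


@dataclass(frozen=True)
class SegScores:
    jaccard: float
    dice: float
    conformity: float

    @property
    def conformity_defined(self) -> bool:
        return math.isfinite(self.conformity)


@dataclass(frozen=True)
class DetectionConfig:
    overlap_threshold: float = 0.70
    overlap: str = "iou"  # or "gt_coverage": |P∩G| / |G|
    sweep_grid: tuple[float, ...] = (0.65, 0.70, 0.75, 0.80, 0.85)

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap threshold must lie in (0, 1]")
        if self.overlap not in ("iou", "gt_coverage"):
            raise ValueError(f"unknown overlap definition {self.overlap!r}")


@dataclass
class DetectionCounts:
    tp: int
    fp: int
    fn: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    """(pred id, gt id, overlap) for each matched pair counted as TP."""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def _as_bool(mask: LabelVolume | np.ndarray) -> np.ndarray:
    data = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
    return data > 0


def segmentation_scores(
    pred_mask: LabelVolume | np.ndarray,
    gt_mask: LabelVolume | np.ndarray,
) -> SegScores:
    """Jaccard / Dice / conformity of two congruent binary masks.

    Raises on two empty masks (all three metrics undefined); a zero Jaccard
    yields the −∞ conformity sentinel rather than a number.
    """
    x = _as_bool(pred_mask)
    y = _as_bool(gt_mask)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    inter = int(np.logical_and(x, y).sum())
    union = int(np.logical_or(x, y).sum())
    if union == 0:
        raise ValueError("both masks are empty; segmentation scores are undefined")
    jaccard = inter / union
    dice = 2.0 * inter / (x.sum() + y.sum())
    conformity = (2.0 * jaccard - 1.0) / jaccard if jaccard > 0 else CONFORMITY_UNDEFINED
    return SegScores(jaccard=jaccard, dice=dice, conformity=conformity)


def _instance_overlaps(
    pred: np.ndarray, gt: np.ndarray, definition: str
) -> list[tuple[float, int, int]]:
    """(overlap, pred id, gt id) for all pairs with non-empty intersection."""
    both = (pred > 0) & (gt > 0)
    results: list[tuple[float, int, int]] = []
    if not both.any():
        return results
    pairs = np.stack([pred[both], gt[both]], axis=1)
    uniq, inter = np.unique(pairs, axis=0, return_counts=True)
    pred_sizes = np.bincount(pred.ravel())
    gt_sizes = np.bincount(gt.ravel())
    for (p, g), i in zip(uniq, inter):
        if definition == "iou":
            ov = i / (pred_sizes[p] + gt_sizes[g] - i)
        else:
            ov = i / gt_sizes[g]
        results.append((float(ov), int(p), int(g)))
    return results


def match_instances(
    pred_instances: LabelVolume | np.ndarray,
    gt_instances: LabelVolume | np.ndarray,
    config: DetectionConfig | None = None,
) -> DetectionCounts:
    """Greedy one-to-one instance matching with the >= τ overlap TP rule.

    Candidate pairs are those with non-zero voxel intersection, matched in
    descending overlap with each prediction and each ground-truth instance
    used at most once. Matched pairs reaching the threshold are TPs;
    unmatched predictions are FPs and unmatched ground-truth instances FNs.
    """
    config = config or DetectionConfig()
    pred = pred_instances.data if isinstance(pred_instances, LabelVolume) else np.asarray(pred_instances)
    gt = gt_instances.data if isinstance(gt_instances, LabelVolume) else np.asarray(gt_instances)
    if pred.shape != gt.shape:
        raise ValueError(f"instance volumes differ in shape: {pred.shape} vs {gt.shape}")

    n_pred = len(np.setdiff1d(np.unique(pred), [0]))
    n_gt = len(np.setdiff1d(np.unique(gt), [0]))

    candidates = _instance_overlaps(pred, gt, config.overlap)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_pred: set[int] = set()
    used_gt: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for ov, p, g in candidates:
        if p in used_pred or g in used_gt:
            continue
        if ov >= config.overlap_threshold:
            used_pred.add(p)
            used_gt.add(g)
            matches.append((p, g, ov))

    tp = len(matches)
    return DetectionCounts(tp=tp, fp=n_pred - tp, fn=n_gt - tp, matches=matches)


def detection_scores(counts: DetectionCounts) -> tuple[float, float, float]:
    """(precision, recall, f1) from TP/FP/FN tallies; undefined -> error."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0:
        raise ZeroDivisionError("precision undefined: no predicted instances")
    if tp + fn == 0:
        raise ZeroDivisionError("recall undefined: no ground-truth instances")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return precision, recall, 0.0
    f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def threshold_sweep(
    pred_instances: LabelVolume | np.ndarray,
    gt_instances: LabelVolume | np.ndarray,
    grid: tuple[float, ...] | None = None,
    config: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Detection scores across overlap thresholds τ (columns: tau, tp, fp,
    fn, precision, recall, f1). F1 is non-increasing in τ."""
    config = config or DetectionConfig()
    grid = tuple(grid) if grid is not None else config.sweep_grid
    rows = []
    for tau in grid:
        cfg = DetectionConfig(overlap_threshold=tau, overlap=config.overlap)
        counts = match_instances(pred_instances, gt_instances, cfg)
        precision, recall, f1 = detection_scores(counts)
        rows.append(
            {
                "tau": tau,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows)
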