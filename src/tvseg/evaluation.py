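"""Segmentation scoring: precision, recall, and Dice overlap.

Detections are matched one-to-one to ground-truth nuclei greedily by
mask Dice (pairs above a configurable threshold, best overlaps first).
Precision is the fraction of detections that hit a true nucleus; recall
the fraction of true nuclei that were hit.  Dice is reported both at
the image level (union of detected masks vs union of true masks) and as
the mean over matched pairs, since segmentation accuracy and detection
accuracy are distinct failure modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroundTruth",
    "DetectionCounts",
    "dice_coefficient",
    "match_detections",
    "precision_recall",
    "image_dice",
    "evaluate_segmentation",
]


@dataclass(frozen=True)
class GroundTruth:
    """Integer-labeled reference mask: 0 = background, k > 0 = nucleus k."""

    label_mask: np.ndarray

    @classmethod
    def from_label_mask(cls, mask: np.ndarray) -> "GroundTruth":
        """Wrap an arbitrary integer mask, relabeling to dense 1..n."""
        mask = np.asarray(mask)
        labels = np.unique(mask)
        labels = labels[labels > 0]
        dense = np.zeros_like(mask, dtype=np.int32)
        for new, old in enumerate(labels, start=1):
            dense[mask == old] = new
        return cls(label_mask=dense)

    @property
    def n_nuclei(self) -> int:
        return int(self.label_mask.max())

    def nucleus_mask(self, label: int) -> np.ndarray:
        return self.label_mask == label


@dataclass(frozen=True)
class DetectionCounts:
    true_positive: int
    false_positive: int
    false_negative: int


def dice_coefficient(mask_m: np.ndarray, mask_n: np.ndarray) -> float:
    """Dice overlap ``2 |M & N| / (|M| + |N|)`` between two pixel sets.

    Two empty masks are identical, so their Dice is defined as 1.0
    (with a warning, since this usually signals an upstream problem).
    """
    mask_m = np.asarray(mask_m, dtype=bool)
    mask_n = np.asarray(mask_n, dtype=bool)
    if mask_m.shape != mask_n.shape:
        raise ValueError("mask shapes differ")
    size = int(mask_m.sum()) + int(mask_n.sum())
    if size == 0:
        warnings.warn("Dice of two empty masks; returning 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((mask_m & mask_n).sum()) / size


def _detection_masks(segments) -> list[np.ndarray]:
    return [np.asarray(s.mask, dtype=bool) if hasattr(s, "mask") else np.asarray(s, dtype=bool)
            for s in segments]


def _pair_dices(det_masks: list[np.ndarray], gt: GroundTruth) -> np.ndarray:
    """Dice between every detection and every GT nucleus, via label counts."""
    n_gt = gt.n_nuclei
    gt_sizes = np.bincount(gt.label_mask.ravel(), minlength=n_gt + 1)[1:]
    dices = np.zeros((len(det_masks), n_gt))
    for i, mask in enumerate(det_masks):
        inter = np.bincount(gt.label_mask[mask], minlength=n_gt + 1)[1:]
        denom = mask.sum() + gt_sizes
        with np.errstate(invalid="ignore"):
            dices[i] = np.where(denom > 0, 2.0 * inter / denom, 0.0)
    return dices


def match_detections(
    segments, gt: GroundTruth, dice_threshold: float = 0.2
) -> DetectionCounts:
    """Greedy one-to-one matching of detections to true nuclei by Dice.

    Candidate pairs with Dice above ``dice_threshold`` are taken in
    descending Dice order; every detection and every true nucleus may be
    matched at most once.
    """
    det_masks = _detection_masks(segments)
    if det_masks and det_masks[0].shape != gt.label_mask.shape:
        raise ValueError("detection and ground-truth shapes differ")
    tp, _ = _greedy_matches(det_masks, gt, dice_threshold)
    return DetectionCounts(
        true_positive=len(tp),
        false_positive=len(det_masks) - len(tp),
        false_negative=gt.n_nuclei - len(tp),
    )


def _greedy_matches(det_masks, gt: GroundTruth, dice_threshold: float):
    dices = _pair_dices(det_masks, gt) if det_masks and gt.n_nuclei else np.zeros((0, 0))
    pairs = [
        (dices[i, j], i, j)
        for i in range(dices.shape[0])
        for j in range(dices.shape[1])
        if dices[i, j] > dice_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_det: set[int] = set()
    used_gt: set[int] = set()
    matches: list[tuple[int, int]] = []
    scores: list[float] = []
    for d, i, j in pairs:
        if i in used_det or j in used_gt:
            continue
        used_det.add(i)
        used_gt.add(j)
        matches.append((i, j))
        scores.append(d)
    return matches, scores


def precision_recall(counts: DetectionCounts) -> tuple[float, float]:
    """``TP/(TP+FP)`` and ``TP/(TP+FN)``; NaN with a warning when undefined."""
    tp, fp, fn = counts.true_positive, counts.false_positive, counts.false_negative
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("precision undefined (no detections)", stacklevel=2)
        precision = float("nan")
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("recall undefined (no ground-truth nuclei)", stacklevel=2)
        recall = float("nan")
    return precision, recall


def image_dice(
    segments, gt: GroundTruth, dice_threshold: float = 0.2
) -> tuple[float, float]:
    """Image-level Dice and mean per-matched-pair Dice.

    The image-level score compares the union of all detected masks with
    the union of all true masks; the pair score averages Dice over the
    greedy one-to-one matches (NaN when nothing matches).
    """
    det_masks = _detection_masks(segments)
    union_det = np.zeros(gt.label_mask.shape, dtype=bool)
    for mask in det_masks:
        union_det |= mask
    union_gt = gt.label_mask > 0
    overall = dice_coefficient(union_det, union_gt) if (union_det.any() or union_gt.any()) else 1.0
    _, scores = _greedy_matches(det_masks, gt, dice_threshold)
    pair_mean = float(np.mean(scores)) if scores else float("nan")
    return overall, pair_mean


def evaluate_segmentation(
    segments, gt: GroundTruth, dice_threshold: float = 0.2
) -> dict:
    """Full metrics report as a plain dict (JSON/CSV friendly)."""
    counts = match_detections(segments, gt, dice_threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall = precision_recall(counts)
    overall, pair_mean = image_dice(segments, gt, dice_threshold)
    return {
        "n_detections": counts.true_positive + counts.false_positive,
        "n_ground_truth": gt.n_nuclei,
        "true_positive": counts.true_positive,
        "false_positive": counts.false_positive,
        "false_negative": counts.false_negative,
        "precision": precision,
        "recall": recall,
        "image_dice": overall,
        "mean_pair_dice": pair_mean,
    }
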