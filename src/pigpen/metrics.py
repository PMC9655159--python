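"""Box-level detection evaluation: IoU matching, precision/recall, AP@0.5.

Matching follows the PASCAL VOC protocol: predictions are visited in order
of descending confidence and each is greedily assigned to the unmatched
ground-truth box of highest IoU, counting as a true positive when that IoU
reaches the threshold (default 0.5).  Average precision uses the all-point
interpolation (area under the precision envelope over recall), reported on a
0-100 scale.  The integrated performance index is detection accuracy (AP@0.5)
multiplied by processing speed in frames per second, summarizing the
accuracy/throughput trade-off of a deployed detector in a single number.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .frames import Box, box_iou

__all__ = ["MatchCounts", "iou", "match_detections", "precision", "recall",
           "average_precision_50", "integrated_performance", "evaluate_images"]

iou = box_iou  # box IoU lives with the Box type; re-exported under its field name


@dataclasses.dataclass(frozen=True)
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _greedy_match(
    preds: Sequence[Box], truths: Sequence[Box], iou_thr: float
) -> list[bool]:
    """Per-prediction TP flags, confidence-ordered greedy VOC matching."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    matched = [False] * len(truths)
    flags = [False] * len(preds)
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = box_iou(preds[i], t)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thr:
            matched[best_j] = True
            flags[i] = True
    return flags


def match_detections(
    preds: Sequence[Box], truths: Sequence[Box], iou_thr: float = 0.5
) -> MatchCounts:
    """TP/FP/FN counts for one image."""
    flags = _greedy_match(preds, truths, iou_thr)
    tp = sum(flags)
    return MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp)


def precision(tp: int, fp: int) -> float:
    """tp / (tp + fp); 0 when there are no predictions."""
    return tp / (tp + fp) if tp + fp > 0 else 0.0


def recall(tp: int, fn: int) -> float:
    """tp / (tp + fn); 0 when there is no ground truth."""
    return tp / (tp + fn) if tp + fn > 0 else 0.0


def average_precision_50(
    all_preds: Sequence[Sequence[Box]],
    all_truths: Sequence[Sequence[Box]],
    iou_thr: float = 0.5,
    interpolation: str = "all_point",
) -> float:
    """AP@IoU over an image set, on the 0-100 scale.

    Predictions from all images are pooled and swept by confidence; the
    precision/recall curve is integrated with all-point interpolation (the
    area under the precision envelope) or the legacy 11-point rule.
    """
    n_truth = sum(len(t) for t in all_truths)
    if n_truth == 0:
        raise ValueError("no ground-truth boxes to evaluate against")
    scored: list[tuple[float, bool]] = []
    for preds, truths in zip(all_preds, all_truths):
        flags = _greedy_match(preds, truths, iou_thr)
        scored.extend((p.confidence, f) for p, f in zip(preds, flags))
    if not scored:
        return 0.0
    scored.sort(key=lambda s: -s[0])
    tps = np.cumsum([f for _, f in scored])
    ranks = np.arange(1, len(scored) + 1)
    prec = tps / ranks
    rec = tps / n_truth
    if interpolation == "all_point":
        # precision envelope, then sum precision * recall increments
        mrec = np.concatenate([[0.0], rec, [rec[-1]]])
        mpre = np.concatenate([[0.0], prec, [0.0]])
        for i in range(len(mpre) - 2, -1, -1):
            mpre[i] = max(mpre[i], mpre[i + 1])
        idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
        ap = float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    elif interpolation == "11_point":
        ap = float(np.mean([
            prec[rec >= r].max() if np.any(rec >= r) else 0.0
            for r in np.linspace(0.0, 1.0, 11)
        ]))
    else:
        raise ValueError(f"unknown interpolation: {interpolation!r}")
    return 100.0 * ap


def integrated_performance(accuracy: float, speed_fps: float) -> float:
    """Accuracy (AP@0.5, 0-100) x speed (FPS), rounded to 1 decimal."""
    if accuracy < 0 or speed_fps < 0:
        raise ValueError("accuracy and speed must be non-negative")
    return round(accuracy * speed_fps, 1)


def evaluate_images(
    preds_by_image: Mapping[str, Sequence[Box]],
    truths_by_image: Mapping[str, Sequence[Box]],
    iou_thr: float = 0.5,
    conf_cutoff: float = 0.0,
) -> dict:
    """Full evaluation report over name-matched images.

    TP/FP/FN, precision and recall are accumulated at ``conf_cutoff``;
    AP@0.5 sweeps all confidences.  Precision/recall are rounded to two
    decimals and AP to two, matching common reporting conventions.
    """
    names = sorted(set(preds_by_image) | set(truths_by_image))
    counts = MatchCounts()
    all_preds, all_truths = [], []
    for name in names:
        preds = [b for b in preds_by_image.get(name, ()) if b.confidence >= conf_cutoff]
        truths = list(truths_by_image.get(name, ()))
        counts = counts + match_detections(preds, truths, iou_thr)
        all_preds.append(list(preds_by_image.get(name, ())))
        all_truths.append(truths)
    ap = average_precision_50(all_preds, all_truths, iou_thr)
    return {
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "precision": round(precision(counts.tp, counts.fp), 2),
        "recall": round(recall(counts.tp, counts.fn), 2),
        "ap50": round(ap, 2),
    }
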