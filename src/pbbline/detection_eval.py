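"""Precision, recall and mean average precision for polygon detections.

Matching follows the standard detection-benchmark protocol: detections are
visited in descending confidence order and greedily matched one-to-one to
the unmatched ground-truth polygon of the same class with the highest
polygon IoU, counting a true positive when that IoU reaches the matching
threshold.  Average precision integrates the precision-recall curve under
its monotone-decreasing envelope with all-point (continuous) interpolation;
mAP averages AP over classes, at IoU 0.5 by default with an optional
0.5:0.95 sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .polygon_core import QuadPBB, polygon_iou
from .suppression import DetectionSet

__all__ = [
    "EvalResult",
    "match_detections",
    "precision_recall",
    "average_precision",
    "evaluate_detections",
    "MAP_THRESHOLDS_50_95",
]

MAP_THRESHOLDS_50_95: Tuple[float, ...] = tuple(np.arange(0.5, 1.0, 0.05).round(2))


@dataclass
class EvalResult:
    precision: float
    recall: float
    map_value: float
    per_image_matches: List[dict] = field(default_factory=list)


def match_detections(
    dets: DetectionSet,
    gts: Sequence[QuadPBB],
    iou_threshold: float = 0.5,
) -> Tuple[List[bool], List[bool], int]:
    """Greedy one-to-one matching in confidence order.

    Returns per-detection TP and FP flags (ordered by descending
    confidence) and the count of unmatched ground truths (FN).
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ParameterError("iou_threshold must be in [0, 1]")
    ordered = list(dets.sorted_by_confidence())
    matched = [False] * len(gts)
    tp_flags: List[bool] = []
    for det in ordered:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[j] or gt.class_id != det.class_id:
                continue
            iou = polygon_iou(det, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    fp_flags = [not t for t in tp_flags]
    fn = matched.count(False)
    return tp_flags, fp_flags, fn


def precision_recall(tp_flags: Sequence[bool], fp_flags: Sequence[bool], fn: int) -> Tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); empty denominators count as 1
    (no predictions means no false alarms; no ground truth means nothing
    was missed)."""
    tp = sum(map(bool, tp_flags))
    fp = sum(map(bool, fp_flags))
    if fn < 0:
        raise ParameterError("fn must be >= 0")
    p = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    return p, r


def _ap_from_ranked(is_tp: Sequence[bool], n_gt: int) -> float:
    """All-point interpolated AP from confidence-ranked TP flags."""
    if n_gt == 0:
        return 1.0 if len(is_tp) == 0 else 0.0
    if len(is_tp) == 0:
        return 0.0
    tp_cum = np.cumsum(np.asarray(is_tp, dtype=float))
    fp_cum = np.cumsum(~np.asarray(is_tp, dtype=bool))
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone-decreasing precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def average_precision(
    image_pairs: Sequence[Tuple[DetectionSet, Sequence[QuadPBB]]],
    iou_threshold: float = 0.5,
) -> float:
    """Mean AP over classes, pooling ranked detections across images.

    Matching is per image (a detection can only claim ground truth from its
    own frame); the precision-recall sweep ranks all detections jointly by
    confidence.  A class with neither ground truth nor detections scores 1
    by convention; ground-truth-free classes with detections score 0.
    """
    ranked: Dict[int, List[Tuple[float, bool]]] = {}
    n_gt: Dict[int, int] = {}
    for dets, gts in image_pairs:
        for gt in gts:
            n_gt[gt.class_id] = n_gt.get(gt.class_id, 0) + 1
        tp_flags, _, _ = match_detections(dets, gts, iou_threshold)
        for det, is_tp in zip(dets.sorted_by_confidence(), tp_flags):
            ranked.setdefault(det.class_id, []).append((det.confidence, is_tp))
    classes = sorted(set(ranked) | set(n_gt))
    if not classes:
        return 1.0
    aps = []
    for cls in classes:
        entries = sorted(ranked.get(cls, []), key=lambda e: -e[0])
        aps.append(_ap_from_ranked([tp for _, tp in entries], n_gt.get(cls, 0)))
    return float(np.mean(aps))


def evaluate_detections(
    image_pairs: Sequence[Tuple[DetectionSet, Sequence[QuadPBB]]],
    iou_threshold: float = 0.5,
    map_sweep_50_95: bool = False,
) -> EvalResult:
    """Aggregate P/R at ``iou_threshold`` plus mAP (at 0.5 or averaged over
    the 0.5:0.95 thresholds)."""
    tp = fp = fn = 0
    per_image = []
    for i, (dets, gts) in enumerate(image_pairs):
        tpf, fpf, fni = match_detections(dets, gts, iou_threshold)
        tp += sum(tpf)
        fp += sum(fpf)
        fn += fni
        per_image.append({"image": i, "tp": sum(tpf), "fp": sum(fpf), "fn": fni})
    p = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    if map_sweep_50_95:
        m = float(np.mean([average_precision(image_pairs, t) for t in MAP_THRESHOLDS_50_95]))
    else:
        m = average_precision(image_pairs, iou_threshold)
    return EvalResult(precision=p, recall=r, map_value=m, per_image_matches=per_image)
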