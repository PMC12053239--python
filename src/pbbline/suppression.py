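"""Polygon-aware non-maximum suppression.

Rectangle NMS underestimates the overlap of two slanted B-line wedges whose
axis-aligned boxes barely intersect, and overestimates it for wedges that
share a bounding box but lean apart.  Suppression here therefore scores
overlap with the exact polygon IoU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

from .errors import ParameterError
from .polygon_core import QuadPBB, polygon_iou

DEFAULT_IOU_THRESHOLD = 0.45
DEFAULT_CONF_THRESHOLD = 0.25

__all__ = ["DetectionSet", "polygon_nms", "DEFAULT_IOU_THRESHOLD", "DEFAULT_CONF_THRESHOLD"]


@dataclass
class DetectionSet:
    """An ordered collection of polygonal detections."""

    detections: List[QuadPBB] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def sorted_by_confidence(self) -> "DetectionSet":
        """Descending confidence; ties keep input order (stable sort)."""
        order = sorted(
            range(len(self.detections)),
            key=lambda i: -self.detections[i].confidence,
        )
        return DetectionSet([self.detections[i] for i in order])


def polygon_nms(
    dets: DetectionSet,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> DetectionSet:
    """Greedy class-aware NMS with polygon IoU.

    Detections below ``conf_threshold`` are dropped; the rest are visited in
    descending confidence order, keeping a detection unless it overlaps an
    already-kept detection of the same class with IoU >= ``iou_threshold``.
    Cross-class overlaps never suppress.  Returns kept detections in
    descending confidence order.
    """
    for name, t in (("iou_threshold", iou_threshold), ("conf_threshold", conf_threshold)):
        if not 0.0 <= t <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {t}")

    candidates = [d for d in dets.sorted_by_confidence() if d.confidence >= conf_threshold]
    kept: List[QuadPBB] = []
    for det in candidates:
        suppressed = False
        for k in kept:
            if k.class_id != det.class_id:
                continue
            iou = polygon_iou(k, det)
            # disjoint detections (IoU 0) never suppress, so a threshold of
            # 0 keeps one detection per overlapping cluster
            if iou > 0.0 and iou >= iou_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(det)
    return DetectionSet(kept)
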