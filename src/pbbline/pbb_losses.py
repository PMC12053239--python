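"""Loss family for polygonal bounding-box detectors, plus anchor matching.

Two detector variants share these terms.  The anchor-based variant combines
a box loss — polygon-overlap term, vertex-ordering hinge, and SmoothL1 on
the eight vertex coordinates — with a binary-cross-entropy objectness loss:

    L_box = L_CIoU + L_order + L_vertex
    L     = lambda_box * L_box + lambda_obj * L_obj

The segmentation-based variant adds a distribution focal loss on discretized
regression targets and an area-normalized mask BCE:

    L_total = lambda_1 * L_obj + lambda_2 * L_CIoU
            + lambda_3 * L_dfl + lambda_4 * L_seg

All functions are pure scorers over already-decoded coordinates: gradients,
optimizers and the training loop are out of scope.  The only stateful piece
is :class:`AutoBalance`, the slowly-varying per-scale objectness weight used
when dynamic weighting is enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, List, Sequence, Tuple, Union

import numpy as np
import yaml

from .errors import ParameterError
from .polygon_core import QuadPBB, SimplePolygon, min_bounding_rect, polygon_iou

_EPS_CLIP = 1e-7

__all__ = [
    "LossConfig",
    "ObjectnessGrid",
    "DflTarget",
    "MaskPair",
    "AutoBalance",
    "ciou_loss",
    "order_loss",
    "vertex_loss",
    "box_loss",
    "objectness_loss",
    "dfl_loss",
    "seg_loss",
    "total_loss_v5",
    "total_loss_v8",
    "match_anchors",
]

#: Optimizer settings used by the reference training recipe; recorded as
#: configuration constants only (no training loop ships with this package).
TRAINING_DEFAULTS = {
    "optimizer": "AdamW",
    "lr0": 0.01,
    "momentum": 0.937,
    "weight_decay": 0.0005,
    "epochs": 500,
    "batch_size": 16,
    "image_size": 320,
}


@dataclass
class LossConfig:
    """Hyperparameters of the loss family.

    ``beta`` is the SmoothL1 quadratic/linear transition point.  The lambda
    weights are exposed in config because the training recipe leaves them
    tunable; defaults follow the detector family's conventions.
    """

    beta: float = 0.11
    lambda_box: float = 0.05
    lambda_obj: float = 1.0
    lambda_1: float = 1.0
    lambda_2: float = 1.0
    lambda_3: float = 1.0
    lambda_4: float = 1.0
    autobalance: bool = False
    anchor_ratio_threshold: float = 4.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ParameterError(f"beta must be > 0, got {self.beta}")
        for name in ("lambda_box", "lambda_obj", "lambda_1", "lambda_2", "lambda_3", "lambda_4"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.anchor_ratio_threshold <= 1:
            raise ParameterError("anchor_ratio_threshold must be > 1")

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        """Build from a config block with ``box:``, ``obj:``, ``beta:``,
        ``autobalance:``, ``lambda1..4:`` and ``anchor_t:`` keys."""
        kwargs = {}
        mapping = {
            "box": "lambda_box",
            "obj": "lambda_obj",
            "beta": "beta",
            "autobalance": "autobalance",
            "anchor_t": "anchor_ratio_threshold",
            "lambda1": "lambda_1",
            "lambda2": "lambda_2",
            "lambda3": "lambda_3",
            "lambda4": "lambda_4",
        }
        for key, attr in mapping.items():
            if key in d:
                kwargs[attr] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, stream: Union[str, IO[str]]) -> "LossConfig":
        data = yaml.safe_load(stream)
        if not isinstance(data, dict):
            raise ParameterError("loss config must be a YAML mapping")
        return cls.from_dict(data)


@dataclass
class ObjectnessGrid:
    """Predicted vs target objectness over all anchor-cells of one scale."""

    predicted: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.predicted.shape != self.target.shape:
            raise ParameterError(
                f"shape mismatch: {self.predicted.shape} vs {self.target.shape}"
            )
        if np.any((self.predicted < 0) | (self.predicted > 1)):
            raise ParameterError("predicted objectness must lie in [0, 1]")
        if np.any((self.target < 0) | (self.target > 1)):
            raise ParameterError("target objectness must lie in [0, 1]")


@dataclass
class DflTarget:
    """A continuous regression target ``t`` and a probability vector over
    the integer bins, for the distribution focal loss.

    ``t`` is bracketed by ``t_l = floor(t)`` and ``t_r = t_l + 1`` with
    proximity weights ``w_l = t_r - t`` and ``w_r = t - t_l``.
    """

    t: float
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or self.p.size < 2:
            raise ParameterError("p must be a 1-D probability vector with >= 2 bins")
        if np.any(self.p < 0) or not math.isclose(float(self.p.sum()), 1.0, abs_tol=1e-6):
            raise ParameterError("p must be non-negative and sum to 1")
        if not 0.0 <= self.t <= self.p.size - 1:
            raise ParameterError(
                f"target {self.t} outside bin range [0, {self.p.size - 1}]"
            )

    @property
    def t_l(self) -> int:
        # floor(t), kept inside the bin range when t sits on the last bin
        return min(int(math.floor(self.t)), self.p.size - 2)

    @property
    def t_r(self) -> int:
        return self.t_l + 1

    @property
    def w_l(self) -> float:
        return self.t_r - self.t

    @property
    def w_r(self) -> float:
        return self.t - self.t_l


@dataclass
class MaskPair:
    """Predicted probability mask vs binary ground-truth mask, with the
    pixel area of the associated bounding box for normalization."""

    predicted_mask: np.ndarray
    gt_mask: np.ndarray
    box_area: float

    def __post_init__(self) -> None:
        self.predicted_mask = np.asarray(self.predicted_mask, dtype=float)
        self.gt_mask = np.asarray(self.gt_mask, dtype=float)
        if self.predicted_mask.shape != self.gt_mask.shape:
            raise ParameterError("predicted and ground-truth masks must share a shape")
        if self.box_area <= 0:
            raise ParameterError(f"box_area must be > 0, got {self.box_area}")


def ciou_loss(pred: QuadPBB, target: QuadPBB) -> float:
    """Polygon-overlap loss ``1 - IoU(pred, target)`` in [0, 1]."""
    return 1.0 - polygon_iou(pred, target)


_ORDER_PAIRS = ((1, 5), (1, 7), (3, 5), (3, 7), (0, 2), (6, 4))
# flat-index pairs (i, j) requiring coord[i] <= coord[j]:
# y1<=y3, y1<=y4, y2<=y3, y2<=y4, x1<=x2, x4<=x3


def order_loss(pred: QuadPBB) -> float:
    """Mean squared hinge over the six vertex-ordering constraints.

    Each violated inequality contributes ``max(0, p_i - p_j)^2`` where
    ``p_i`` is the coordinate required not to exceed ``p_j``; quads that
    satisfy the canonical ordering score exactly 0.
    """
    flat = pred.flat()
    total = 0.0
    for i, j in _ORDER_PAIRS:
        total += max(0.0, flat[i] - flat[j]) ** 2
    return total / len(_ORDER_PAIRS)


def _smooth_l1(d: float, beta: float) -> float:
    ad = abs(d)
    if ad < beta:
        return 0.5 * d * d / beta
    return ad - 0.5 * beta


def vertex_loss(pred: QuadPBB, target: QuadPBB, beta: float = 0.11) -> float:
    """SmoothL1 vertex-misalignment loss, averaged over the 8 coordinates."""
    if beta <= 0:
        raise ParameterError(f"beta must be > 0, got {beta}")
    dp = [p - t for p, t in zip(pred.flat(), target.flat())]
    return sum(_smooth_l1(d, beta) for d in dp) / 8.0


def box_loss(pred: QuadPBB, target: QuadPBB, cfg: LossConfig | None = None) -> float:
    """``L_box = L_CIoU + L_order + L_vertex``."""
    cfg = cfg or LossConfig()
    return ciou_loss(pred, target) + order_loss(pred) + vertex_loss(pred, target, cfg.beta)


def _bce(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS_CLIP, 1.0 - _EPS_CLIP)
    return -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))


def objectness_loss(grid: ObjectnessGrid) -> float:
    """Sum of per-cell binary cross-entropies over the grid."""
    return float(np.sum(_bce(grid.predicted, grid.target)))


def dfl_loss(targets: Sequence[DflTarget]) -> float:
    """Distribution focal loss: cross-entropy on the two integer bins
    bracketing each continuous target, weighted by proximity, averaged over
    targets."""
    if len(targets) == 0:
        raise ParameterError("dfl_loss needs at least one target")
    total = 0.0
    for tgt in targets:
        p = np.clip(tgt.p, _EPS_CLIP, None)
        term = 0.0
        if tgt.w_l > 0:
            term += -math.log(p[tgt.t_l]) * tgt.w_l
        if tgt.w_r > 0:
            term += -math.log(p[tgt.t_r]) * tgt.w_r
        total += term
    return total / len(targets)


def seg_loss(pair: MaskPair) -> float:
    """Mask BCE summed over pixels, normalized by the bounding-box area."""
    return float(np.sum(_bce(pair.predicted_mask, pair.gt_mask)) / pair.box_area)


class AutoBalance:
    """Per-scale dynamic objectness weights.

    When dynamic weighting is enabled, the objectness weight of each
    detection scale is modulated by a factor that follows a slow exponential
    moving average of the reciprocal objectness loss at that scale.  Factors
    start at 1 and stay strictly positive.
    """

    def __init__(self, n_scales: int = 3, decay: float = 0.9999, floor: float = 1e-6):
        if n_scales < 1:
            raise ParameterError("need at least one scale")
        self.decay = decay
        self.floor = floor
        self.factors = [1.0] * n_scales

    def update(self, obj_losses: Sequence[float]) -> List[float]:
        if len(obj_losses) != len(self.factors):
            raise ParameterError("one objectness loss per scale required")
        for i, loss in enumerate(obj_losses):
            contrib = (1.0 - self.decay) / max(loss, self.floor)
            self.factors[i] = max(self.factors[i] * self.decay + contrib, self.floor)
        return list(self.factors)


def total_loss_v5(
    box: float,
    obj: float,
    cfg: LossConfig | None = None,
    balance_factor: float = 1.0,
) -> float:
    """``L = lambda_box * L_box + lambda_obj * L_obj`` with static weights;
    when ``cfg.autobalance`` is set, the caller supplies the current
    per-scale :class:`AutoBalance` factor which further multiplies the
    objectness weight."""
    cfg = cfg or LossConfig()
    obj_weight = cfg.lambda_obj
    if cfg.autobalance:
        if balance_factor <= 0:
            raise ParameterError("balance factor must stay positive")
        obj_weight *= balance_factor
    return cfg.lambda_box * box + obj_weight * obj


def total_loss_v8(
    obj: float, ciou: float, dfl: float, seg: float, cfg: LossConfig | None = None
) -> float:
    """Weighted sum of the four loss terms of the segmentation variant."""
    cfg = cfg or LossConfig()
    return cfg.lambda_1 * obj + cfg.lambda_2 * ciou + cfg.lambda_3 * dfl + cfg.lambda_4 * seg


def match_anchors(
    polys: Sequence[SimplePolygon | QuadPBB],
    anchors: Sequence[Tuple[float, float]],
    ratio_threshold: float = 4.0,
) -> List[Tuple[int, int]]:
    """Shape-based polygon-to-anchor assignment.

    Each polygon is reduced to its minimum bounding rectangle and matched to
    every anchor prior whose width/height ratios satisfy
    ``max(w/p_w, p_w/w, h/p_h, p_h/h) < ratio_threshold``.  Polygons may
    match several anchors or none (degenerate boxes match none).
    """
    if len(anchors) == 0:
        raise ParameterError("anchor list must not be empty")
    for p_w, p_h in anchors:
        if p_w <= 0 or p_h <= 0:
            raise ParameterError("anchor dimensions must be positive")
    matches: List[Tuple[int, int]] = []
    for pi, poly in enumerate(polys):
        rect = min_bounding_rect(poly)
        for ai, (p_w, p_h) in enumerate(anchors):
            if rect.w <= 0 or rect.h <= 0:
                continue
            ratio = max(rect.w / p_w, p_w / rect.w, rect.h / p_h, p_h / rect.h)
            if ratio < ratio_threshold:
                matches.append((pi, ai))
    return matches
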