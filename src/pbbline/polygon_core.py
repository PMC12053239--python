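"""Geometry foundation for polygonal bounding boxes (PBBs).

B-line artifacts in lung ultrasound are wedge shaped: narrow where they
originate on the pleural line and wider toward the bottom of the fan.  An
axis-aligned rectangle (RBB) either clips the wedge or swallows background,
so localization here uses a four-vertex polygonal bounding box whose vertex
labels follow a fixed convention: ``(x1, y1)`` and ``(x2, y2)`` are the two
top vertices with ``x1 <= x2``, ``(x4, y4)`` and ``(x3, y3)`` the two bottom
vertices with ``x4 <= x3``, and every bottom vertex lies at or below every
top vertex (image coordinates, y growing downward).

This module provides the PBB/RBB containers, areas and IoU via polygon
clipping, conversions, canonical vertex ordering, and the decoding of raw
detection-head outputs into boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InvalidPolygonError, ParameterError

Point = Tuple[float, float]

__all__ = [
    "RectBox",
    "QuadPBB",
    "SimplePolygon",
    "HeadPrediction",
    "polygon_area",
    "polygon_iou",
    "rbb_to_pbb",
    "min_bounding_rect",
    "canonicalize_vertices",
    "reduce_to_quad",
    "decode_rbb",
]


def _check_finite(points: Iterable[Point]) -> None:
    for x, y in points:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise InvalidPolygonError(f"non-finite coordinate ({x}, {y})")


@dataclass(frozen=True)
class RectBox:
    """Axis-aligned box parameterized by center and size, in pixels."""

    c_x: float
    c_y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.c_x, self.c_y, self.w, self.h))):
            raise ParameterError("RectBox fields must be finite")
        if self.w < 0 or self.h < 0:
            raise ParameterError(f"RectBox requires w, h >= 0, got ({self.w}, {self.h})")

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class QuadPBB:
    """Four-vertex polygonal bounding box with confidence and class label.

    The constructor does not enforce the vertex-ordering constraints — loss
    functions need to score quads that violate them — but
    :meth:`satisfies_constraints` reports whether an instance is canonical.
    """

    vertices: Tuple[Point, Point, Point, Point]
    confidence: float = 1.0
    class_id: int = 0

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) != 4:
            raise InvalidPolygonError(f"QuadPBB needs exactly 4 vertices, got {len(verts)}")
        _check_finite(verts)
        object.__setattr__(self, "vertices", verts)
        if not 0.0 <= self.confidence <= 1.0:
            raise ParameterError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def xs(self) -> Tuple[float, float, float, float]:
        return tuple(v[0] for v in self.vertices)  # type: ignore[return-value]

    @property
    def ys(self) -> Tuple[float, float, float, float]:
        return tuple(v[1] for v in self.vertices)  # type: ignore[return-value]

    def coords(self) -> np.ndarray:
        """Vertices as a (4, 2) float array."""
        return np.asarray(self.vertices, dtype=float)

    def flat(self) -> Tuple[float, ...]:
        """(x1, y1, x2, y2, x3, y3, x4, y4)."""
        return tuple(c for v in self.vertices for c in v)

    def satisfies_constraints(self, tol: float = 0.0) -> bool:
        """True when the vertex ordering convention holds (within ``tol``)."""
        (x1, y1), (x2, y2), (x3, y3), (x4, y4) = self.vertices
        pairs = [(y1, y3), (y1, y4), (y2, y3), (y2, y4), (x1, x2), (x4, x3)]
        return all(lo <= hi + tol for lo, hi in pairs)

    def polygon(self) -> "SimplePolygon":
        return SimplePolygon(self.vertices, _skip_checks=True)

    def translated(self, dx: float, dy: float) -> "QuadPBB":
        return QuadPBB(
            tuple((x + dx, y + dy) for x, y in self.vertices),  # type: ignore[arg-type]
            confidence=self.confidence,
            class_id=self.class_id,
        )


@dataclass(frozen=True)
class SimplePolygon:
    """N-vertex simple (non-self-intersecting) polygon in pixel coordinates.

    Construction checks vertex count and finiteness; the (more expensive)
    simplicity check runs inside operations that require it, or explicitly
    via :meth:`is_simple`.
    """

    vertices: Tuple[Point, ...]
    _skip_checks: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise InvalidPolygonError(f"polygon needs >= 3 vertices, got {len(verts)}")
        if not self._skip_checks:
            _check_finite(verts)
        object.__setattr__(self, "vertices", verts)

    def coords(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def is_simple(self) -> bool:
        """Edge-crossing test; collinear degenerate rings count as simple."""
        if _is_degenerate(self.vertices):
            return True
        return _ShapelyPolygon(self.vertices).is_valid

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class HeadPrediction:
    """Raw per-cell detection-head output plus its grid/anchor context.

    ``T_x``/``T_y`` are center logits relative to the cell corner
    ``(c_x, c_y)``; ``t_w``/``t_h`` scale the anchor prior ``(p_w, p_h)``
    exponentially; ``t_c`` is the objectness/confidence logit.
    """

    T_x: float
    T_y: float
    t_w: float
    t_h: float
    t_c: float
    c_x: float = 0.0
    c_y: float = 0.0
    p_w: float = 1.0
    p_h: float = 1.0

    def __post_init__(self) -> None:
        if self.p_w <= 0 or self.p_h <= 0:
            raise ParameterError("anchor priors p_w, p_h must be positive")


def _signed_area(vertices: Sequence[Point]) -> float:
    arr = np.asarray(vertices, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_degenerate(vertices: Sequence[Point]) -> bool:
    """All vertices collinear (or coincident): the polygon has no interior."""
    arr = np.asarray(vertices, dtype=float)
    centered = arr - arr.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-9) < 2


def polygon_area(poly: SimplePolygon | QuadPBB | Sequence[Point]) -> float:
    """Unsigned shoelace area in pixels², independent of orientation."""
    verts = _as_vertices(poly)
    if len(verts) < 3:
        raise InvalidPolygonError("area needs >= 3 vertices")
    return abs(_signed_area(verts))


def _as_vertices(poly: SimplePolygon | QuadPBB | Sequence[Point]) -> Tuple[Point, ...]:
    if isinstance(poly, QuadPBB):
        return poly.vertices
    if isinstance(poly, SimplePolygon):
        return poly.vertices
    return tuple((float(x), float(y)) for x, y in poly)


def polygon_iou(a: SimplePolygon | QuadPBB, b: SimplePolygon | QuadPBB) -> float:
    """Intersection-over-union of two simple polygons by polygon clipping.

    Degenerate (zero-area) inputs give IoU 0, including against themselves,
    so downstream ratios never see 0/0.  Self-intersecting inputs raise
    :class:`InvalidPolygonError`.
    """
    va, vb = _as_vertices(a), _as_vertices(b)
    deg_a, deg_b = _is_degenerate(va), _is_degenerate(vb)
    if va == vb and not deg_a:
        if not _ShapelyPolygon(va).is_valid:
            raise InvalidPolygonError("polygon is self-intersecting")
        return 1.0
    if deg_a or deg_b:
        return 0.0
    pa, pb = _ShapelyPolygon(va), _ShapelyPolygon(vb)
    for name, p in (("first", pa), ("second", pb)):
        if not p.is_valid:
            raise InvalidPolygonError(f"{name} polygon is self-intersecting")
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    if union <= 0.0:
        return 0.0
    return float(min(max(inter / union, 0.0), 1.0))


def rbb_to_pbb(r: RectBox, confidence: float = 1.0, class_id: int = 0) -> QuadPBB:
    """Expand an axis-aligned box into its canonical four-corner PBB."""
    hw, hh = r.w / 2.0, r.h / 2.0
    return QuadPBB(
        (
            (r.c_x - hw, r.c_y - hh),
            (r.c_x + hw, r.c_y - hh),
            (r.c_x + hw, r.c_y + hh),
            (r.c_x - hw, r.c_y + hh),
        ),
        confidence=confidence,
        class_id=class_id,
    )


def min_bounding_rect(poly: SimplePolygon | QuadPBB | Sequence[Point]) -> RectBox:
    """Axis-aligned bounding rectangle of a polygon's vertices."""
    arr = np.asarray(_as_vertices(poly), dtype=float)
    x_min, y_min = arr.min(axis=0)
    x_max, y_max = arr.max(axis=0)
    return RectBox(
        c_x=(x_min + x_max) / 2.0,
        c_y=(y_min + y_max) / 2.0,
        w=x_max - x_min,
        h=y_max - y_min,
    )


def canonicalize_vertices(
    points: Sequence[Point], confidence: float = 1.0, class_id: int = 0
) -> QuadPBB:
    """Relabel four points into the canonical PBB vertex order.

    The two smallest-y points become the top pair ``(x1, y1), (x2, y2)``
    with ``x1 <= x2``; the two largest-y points become the bottom pair with
    ``x4 <= x3``.  Ties break by a stable sort on ``(y, x)``, so the result
    is deterministic for any input ordering.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) != 4:
        raise InvalidPolygonError(f"canonicalization needs exactly 4 points, got {len(pts)}")
    _check_finite(pts)
    ordered = sorted(pts, key=lambda p: (p[1], p[0]))
    top = sorted(ordered[:2], key=lambda p: p[0])
    bottom = sorted(ordered[2:], key=lambda p: p[0])
    v1, v2 = top
    v4, v3 = bottom
    return QuadPBB((v1, v2, v3, v4), confidence=confidence, class_id=class_id)


def reduce_to_quad(
    poly: SimplePolygon | Sequence[Point],
    confidence: float = 1.0,
    class_id: int = 0,
) -> QuadPBB:
    """Reduce an N-vertex polygon to the canonical quad through the four
    ring-ordered vertices whose quadrilateral has maximum area.

    For wedge-like shapes whose outline carries a few extra boundary points
    this recovers the four true corners.  Polygons with many vertices are
    first reduced to their convex hull.
    """
    verts = list(_as_vertices(poly))
    if len(verts) < 3:
        raise InvalidPolygonError("quad reduction needs >= 3 vertices")
    if len(verts) == 3:
        # a triangle is a quad with one edge collapsed: duplicate the apex
        # (the vertex opposite the shortest edge), preserving area exactly
        arr = np.asarray(verts + [verts[0]])
        lengths = np.hypot(*(np.diff(arr, axis=0).T))
        apex = (int(np.argmin(lengths)) + 2) % 3
        verts = verts[: apex + 1] + [verts[apex]] + verts[apex + 1 :]
    if len(verts) > 12:
        hull = _ShapelyPolygon(verts).convex_hull
        hull_verts = list(hull.exterior.coords[:-1])
        if len(hull_verts) >= 4:
            verts = hull_verts
        else:
            verts = hull_verts + hull_verts[-1:] * (4 - len(hull_verts))
    if len(verts) == 4:
        best = verts
    else:
        from itertools import combinations

        best, best_area = None, -1.0
        for idx in combinations(range(len(verts)), 4):
            quad = [verts[i] for i in idx]
            area = abs(_signed_area(quad))
            if area > best_area:
                best_area, best = area, quad
    candidate = canonicalize_vertices(best, confidence=confidence, class_id=class_id)
    if candidate.polygon().is_simple():
        return candidate
    # canonical relabeling scrambled a sliver: keep the ring order (cyclic
    # chords of a simple ring cannot cross)
    return QuadPBB(tuple(best), confidence=confidence, class_id=class_id)


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def decode_rbb(pred: HeadPrediction) -> Tuple[RectBox, float]:
    """Decode raw head logits into an axis-aligned box and confidence.

    ``B_x = sigmoid(T_x) + c_x``, ``B_y = sigmoid(T_y) + c_y``,
    ``B_w = p_w * exp(t_w)``, ``B_h = p_h * exp(t_h)``,
    ``P_c = sigmoid(t_c)``.
    """
    box = RectBox(
        c_x=_sigmoid(pred.T_x) + pred.c_x,
        c_y=_sigmoid(pred.T_y) + pred.c_y,
        w=pred.p_w * math.exp(pred.t_w),
        h=pred.p_h * math.exp(pred.t_h),
    )
    return box, _sigmoid(pred.t_c)
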