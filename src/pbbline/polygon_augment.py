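"""Polygon-aware data augmentation: horizontal flip and 4-image mosaic.

Both transforms carry the polygon labels through the same geometric map as
the pixels.  Flipping breaks the left/right vertex ordering of a PBB, so
flipped quads are re-canonicalized; mosaic placement can clip a polygon at
the canvas edge, in which case the clipped shape is either reduced back to
a quad (default, matching the fixed-size 8-coordinate label format) or kept
as an N-vertex polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import box as _shapely_box

from .errors import ParameterError
from .polygon_core import QuadPBB, SimplePolygon, canonicalize_vertices, reduce_to_quad

__all__ = ["Sample", "AugmentConfig", "hflip", "mosaic"]


@dataclass
class Sample:
    """An image and its polygon labels, in pixel coordinates."""

    image: np.ndarray
    labels: List[QuadPBB] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ParameterError("Sample images are 2-D grayscale arrays")

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]


@dataclass
class AugmentConfig:
    """Augmentation settings, mirroring the two training-recipe parameters
    (flip probability 0.5, mosaic scale 1.0)."""

    hflip_prob: float = 0.5
    mosaic_scale: float = 1.0
    #: side of one mosaic tile; None uses the first input image's larger side
    tile_size: int | None = None
    #: mosaic center jitter is uniform over the central 50% of the canvas
    center_jitter: float = 0.5
    #: drop clipped fragments below this area (pixels²)
    min_clip_area: float = 1.0
    #: keep N-vertex clipped polygons instead of reducing them to quads
    keep_clipped_polygons: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ParameterError("hflip_prob must be in [0, 1]")
        if self.mosaic_scale <= 0:
            raise ParameterError("mosaic_scale must be > 0")
        if not 0.0 <= self.center_jitter <= 1.0:
            raise ParameterError("center_jitter must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        """Accepts an ``augment: {fliplr: 0.5, mosaic: 1.0}`` block."""
        kwargs = {}
        if "fliplr" in d:
            kwargs["hflip_prob"] = d["fliplr"]
        if "mosaic" in d:
            kwargs["mosaic_scale"] = d["mosaic"]
        return cls(**kwargs)


def _flip_quad(q: QuadPBB, width: int) -> QuadPBB:
    mirrored = [((width - 1) - x, y) for x, y in q.vertices]
    return canonicalize_vertices(mirrored, confidence=q.confidence, class_id=q.class_id)


def hflip(
    sample: Sample,
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
    force: bool | None = None,
) -> Sample:
    """Mirror the image and labels left-right with probability
    ``cfg.hflip_prob`` (or deterministically via ``force``).

    Vertex x maps to ``width - 1 - x`` (pixel-center convention, so the
    flip is an exact involution); flipped quads are re-canonicalized.
    """
    cfg = cfg or AugmentConfig()
    if force is None:
        rng = rng or np.random.default_rng()
        apply = rng.random() < cfg.hflip_prob
    else:
        apply = force
    if not apply:
        return sample
    return Sample(
        image=np.fliplr(sample.image).copy(),
        labels=[_flip_quad(q, sample.width) for q in sample.labels],
    )


def _clipped_to_quad(poly: _ShapelyPolygon, confidence: float, class_id: int) -> QuadPBB:
    """Canonical quad for a clipped shape: its maximum-area 4-vertex subset
    (axis-extreme vertices degenerate for slanted quads)."""
    pts = list(map(tuple, np.asarray(poly.exterior.coords[:-1], dtype=float)))
    return reduce_to_quad(pts, confidence=confidence, class_id=class_id)


def mosaic(
    samples: Sequence[Sample],
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Sample:
    """Combine four samples into one 2x2 mosaic.

    A canvas of two tiles per side is split by a center jittered uniformly
    over its central region; each input (scaled by ``mosaic_scale``) is
    placed into one quadrant with its inner corner at the center, so tiles
    never overlap.  Labels follow the per-tile scale and translation, are
    clipped to the canvas, and fragments below ``min_clip_area`` are
    dropped.
    """
    cfg = cfg or AugmentConfig()
    rng = rng or np.random.default_rng()
    if len(samples) != 4:
        raise ParameterError(f"mosaic needs exactly 4 samples, got {len(samples)}")

    tile = cfg.tile_size or max(samples[0].height, samples[0].width)
    side = 2 * tile
    # center_jitter 0.5 -> center uniform over the central 50% of the canvas
    lo = tile * (1.0 - cfg.center_jitter)
    hi = tile * (1.0 + cfg.center_jitter)
    xc = float(rng.uniform(lo, hi))
    yc = float(rng.uniform(lo, hi))
    ixc, iyc = int(round(xc)), int(round(yc))

    canvas = np.zeros((side, side), dtype=samples[0].image.dtype)
    canvas_rect = _shapely_box(0.0, 0.0, float(side), float(side))
    labels: List[Union[QuadPBB, SimplePolygon]] = []

    for quadrant, sample in enumerate(samples):
        img = sample.image
        if cfg.mosaic_scale != 1.0:
            img = ndimage.zoom(img.astype(float), cfg.mosaic_scale, order=1)
        h, w = img.shape
        # inner corner of each quadrant sits at the mosaic center
        if quadrant == 0:      # top-left
            dx, dy = ixc - w, iyc - h
        elif quadrant == 1:    # top-right
            dx, dy = ixc, iyc - h
        elif quadrant == 2:    # bottom-left
            dx, dy = ixc - w, iyc
        else:                  # bottom-right
            dx, dy = ixc, iyc
        x0, y0 = max(dx, 0), max(dy, 0)
        x1, y1 = min(dx + w, side), min(dy + h, side)
        if x1 > x0 and y1 > y0:
            patch = img[y0 - dy : y1 - dy, x0 - dx : x1 - dx]
            canvas[y0:y1, x0:x1] = patch.astype(canvas.dtype)
        for q in sample.labels:
            moved = [
                (x * cfg.mosaic_scale + dx, y * cfg.mosaic_scale + dy)
                for x, y in q.vertices
            ]
            shp = _ShapelyPolygon(moved)
            if not shp.is_valid:
                shp = shp.buffer(0)
            clipped = shp.intersection(canvas_rect)
            if clipped.is_empty or clipped.area < cfg.min_clip_area:
                continue
            if clipped.geom_type == "MultiPolygon":
                clipped = max(clipped.geoms, key=lambda g: g.area)
            if abs(clipped.area - shp.area) < 1e-9:
                # fully visible: exact affine image of the original quad
                labels.append(
                    QuadPBB(tuple(moved), confidence=q.confidence, class_id=q.class_id)
                )
            elif cfg.keep_clipped_polygons:
                pts = tuple(map(tuple, np.asarray(clipped.exterior.coords[:-1])))
                labels.append(SimplePolygon(pts, _skip_checks=True))
            else:
                labels.append(_clipped_to_quad(clipped, q.confidence, q.class_id))

    return Sample(image=canvas, labels=labels)
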