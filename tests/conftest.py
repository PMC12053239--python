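"""Shared fixtures and independent geometry oracles.

The oracles here deliberately avoid the package's own computational paths:
point-in-polygon uses the even-odd crossing rule in plain numpy, and the
rasterization IoU counts pixel centers on a fixed grid, so they can verify
the shapely-backed clipping route independently.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def points_in_polygon(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd crossing-number test, vectorized over points."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
    return inside


def raster_iou(verts_a: np.ndarray, verts_b: np.ndarray, step: float = 1.0) -> float:
    """IoU by counting pixel centers of a regular grid over both shapes."""
    verts_a = np.asarray(verts_a, float)
    verts_b = np.asarray(verts_b, float)
    allv = np.vstack([verts_a, verts_b])
    x0, y0 = np.floor(allv.min(axis=0)) - 1
    x1, y1 = np.ceil(allv.max(axis=0)) + 1
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(y0 + step / 2, y1, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_a = points_in_polygon(pts, verts_a)
    in_b = points_in_polygon(pts, verts_b)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return np.count_nonzero(in_a & in_b) / union


def random_convex_quad(rng: np.random.Generator, lo: float = 0.0, hi: float = 900.0) -> np.ndarray:
    """Convex quad from four sorted angles on a random ellipse."""
    cx, cy = rng.uniform(lo + 150, hi - 150, size=2)
    a, b = rng.uniform(30, 140, size=2)
    rot = rng.uniform(0, np.pi)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=4))
    # keep angles separated so the quad is not a sliver
    while np.min(np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))) < 0.35:
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=4))
    ex = a * np.cos(angles)
    ey = b * np.sin(angles)
    x = cx + ex * np.cos(rot) - ey * np.sin(rot)
    y = cy + ex * np.sin(rot) + ey * np.cos(rot)
    return np.clip(np.column_stack([x, y]), lo, hi)


def random_canonical_quad(rng: np.random.Generator, scale: float = 100.0) -> np.ndarray:
    """Quad satisfying the PBB ordering constraints by construction: two
    top vertices strictly above two bottom vertices, left before right."""
    cx, cy = rng.uniform(scale, 4 * scale, size=2)
    w_top = rng.uniform(0.1, 0.8) * scale
    w_bot = rng.uniform(0.2, 1.0) * scale
    h = rng.uniform(0.5, 1.5) * scale
    skew = rng.uniform(-0.3, 0.3) * scale
    y_jit = rng.uniform(0, 0.15 * h, size=4)
    return np.array(
        [
            (cx - w_top / 2, cy + y_jit[0]),
            (cx + w_top / 2, cy + y_jit[1]),
            (cx + skew + w_bot / 2, cy + h + y_jit[2]),
            (cx + skew - w_bot / 2, cy + h + y_jit[3]),
        ]
    )


def random_simple_quad(rng: np.random.Generator, scale: float = 100.0) -> np.ndarray:
    """Star-shaped (hence simple) quad: sorted angles, varying radii."""
    cx, cy = rng.uniform(2 * scale, 6 * scale, size=2)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=4))
    while np.min(np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))) < 0.3:
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=4))
    radii = rng.uniform(0.4 * scale, 1.6 * scale, size=4)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
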