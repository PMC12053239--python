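"""Seeded lung-ultrasound phantom generator with exact polygon ground truth.

The generator emulates the phenomenology of a convex-probe B-mode frame:
a dark background, a bright fan-shaped scan sector, a bright pleural arc, a
few dimmer A-line reverberation arcs repeating at multiples of the pleural
depth, and one or more bright B-line wedges that start narrow on the
pleural line and widen toward the far sector boundary.  Multiplicative
log-normal speckle is applied over the anatomy, and bright glyph-like text
blocks can be stamped near the borders to exercise text removal.

The B-line wedge is rendered by rasterizing exactly the quadrilateral that
is reported as ground truth, so recovery error downstream is attributable
to the pipeline rather than to a geometric mismatch.  No claim of acoustic
realism is made: this is a controllable fixture, not a wave simulation.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from PIL import Image
from skimage.draw import polygon as _draw_polygon

from .errors import ParameterError
from .polygon_core import QuadPBB, canonicalize_vertices

__all__ = ["PhantomParams", "PhantomScene", "render_phantom", "make_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one phantom frame.

    Distances are pixels, angles radians.  The fan apex sits above the
    image so the sector fills the frame like a convex-probe acquisition.
    Default frame size is 320 x 320, the input resolution of the detection
    models this generator feeds.
    """

    height: int = 320
    width: int = 320
    apex: Tuple[float, float] = (160.0, -30.0)
    r_min: float = 50.0
    r_max: float = 330.0
    half_span: float = math.radians(30.0)
    pleural_depth: float = 40.0
    n_blines: int = 2
    n_alines: int = 2
    confluent: bool = False
    speckle_sigma: float = 0.15
    #: glyph blocks: ((x, y), (height, width)) in pixels
    text_labels: Tuple[Tuple[Tuple[int, int], Tuple[int, int]], ...] = ()
    #: B-line wedge half-widths in radians: narrow at the pleura, wider at
    #: the far boundary (a few degrees, like real discrete B-lines)
    bline_top_half_angle: Tuple[float, float] = (0.030, 0.050)
    bline_bottom_half_angle: Tuple[float, float] = (0.055, 0.085)
    background_intensity: float = 5.0
    sector_intensity: float = 110.0
    pleura_intensity: float = 185.0
    aline_intensity: float = 150.0
    bline_intensity: float = 235.0

    def __post_init__(self) -> None:
        if self.n_blines < 0 or self.n_alines < 0:
            raise ParameterError("counts must be >= 0")
        if not 0 < self.r_min < self.r_max:
            raise ParameterError("need 0 < r_min < r_max")
        if self.speckle_sigma < 0:
            raise ParameterError("speckle_sigma must be >= 0")

    @property
    def pleural_radius(self) -> float:
        return self.r_min + self.pleural_depth

    def sector_bbox(self) -> Tuple[float, float, float, float]:
        """Continuous (x_min, y_min, x_max, y_max) of the sector, clipped
        to the frame."""
        ax, ay = self.apex
        s = math.sin(self.half_span)
        x_min = ax - self.r_max * s
        x_max = ax + self.r_max * s
        y_min = ay + self.r_min * math.cos(self.half_span)
        y_max = ay + self.r_max
        return (
            max(x_min, 0.0),
            max(y_min, 0.0),
            min(x_max, self.width - 1.0),
            min(y_max, self.height - 1.0),
        )


@dataclass
class PhantomScene:
    """A rendered frame with its exact ground truth."""

    image: np.ndarray
    gt: List[QuadPBB]
    params: PhantomParams
    seed: int


def _polar_point(params: PhantomParams, r: float, theta: float) -> Tuple[float, float]:
    ax, ay = params.apex
    return ax + r * math.sin(theta), ay + r * math.cos(theta)


def _bline_quad(params: PhantomParams, theta_c: float, w_top: float, w_bot: float) -> QuadPBB:
    """Wedge quad: narrow interval on the pleural arc, wider at the far
    boundary.  Angles are half-widths in radians."""
    r_top = params.pleural_radius
    r_bot = params.r_max
    p1 = _polar_point(params, r_top, theta_c - w_top)
    p2 = _polar_point(params, r_top, theta_c + w_top)
    p3 = _polar_point(params, r_bot, theta_c + w_bot)
    p4 = _polar_point(params, r_bot, theta_c - w_bot)
    return canonicalize_vertices([p1, p2, p3, p4])


def render_phantom(params: PhantomParams | None = None, seed: int = 0) -> PhantomScene:
    """Render one phantom frame deterministically from ``seed``.

    Raises :class:`ParameterError` when the requested B-lines cannot fit
    side by side inside the angular span.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    ax, ay = params.apex

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - ax, yy - ay
    r = np.hypot(dx, dy)
    theta = np.arctan2(dx, dy)  # 0 points straight down

    img = np.full((h, w), params.background_intensity)
    in_span = np.abs(theta) <= params.half_span
    sector = in_span & (r >= params.r_min) & (r <= params.r_max)
    img[sector] = params.sector_intensity

    r_p = params.pleural_radius
    pleura = in_span & (np.abs(r - r_p) <= 2.0)
    img[pleura] = params.pleura_intensity
    for k in range(1, params.n_alines + 1):
        r_a = r_p + (k + 1) * params.pleural_depth
        if r_a >= params.r_max:
            break
        aline = sector & (np.abs(r - r_a) <= 1.5)
        img[aline] = params.aline_intensity

    gt: List[QuadPBB] = []
    if params.confluent:
        if params.n_blines > 0:
            # one merged wedge spanning most of the intercostal space
            quad = _bline_quad(params, 0.0, 0.25 * params.half_span, 0.45 * params.half_span)
            gt.append(quad)
    elif params.n_blines > 0:
        span = 2.0 * params.half_span
        slot = span / params.n_blines
        w_bot_hi = params.bline_bottom_half_angle[1]
        # wedges must fit side by side with clearance inside their slots
        if 2.0 * w_bot_hi > 0.9 * slot:
            raise ParameterError(
                f"{params.n_blines} B-lines do not fit the angular span"
            )
        jitter = max(0.0, 0.5 * (0.9 * slot - 2.0 * w_bot_hi))
        for i in range(params.n_blines):
            theta_c = -params.half_span + (i + 0.5) * slot + rng.uniform(-jitter, jitter)
            w_top = rng.uniform(*params.bline_top_half_angle)
            w_bot = max(rng.uniform(*params.bline_bottom_half_angle), 1.3 * w_top)
            gt.append(_bline_quad(params, theta_c, w_top, w_bot))

    for quad in gt:
        arr = quad.coords()
        rr, cc = _draw_polygon(arr[:, 1], arr[:, 0], shape=(h, w))
        img[rr, cc] = params.bline_intensity

    if params.speckle_sigma > 0:
        z = rng.standard_normal((h, w))
        sig = params.speckle_sigma
        img = img * np.exp(sig * z - 0.5 * sig * sig)

    for (x0, y0), (gh, gw) in params.text_labels:
        if x0 < 0 or y0 < 0 or y0 + gh > h or x0 + gw > w:
            raise ParameterError("text label outside the frame")
        glyph = rng.random((gh, gw)) < 0.7
        block = img[y0 : y0 + gh, x0 : x0 + gw]
        block[glyph] = 255.0

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    for quad in gt:
        assert quad.satisfies_constraints(tol=1e-9)
        arr = quad.coords()
        if (arr[:, 0].min() < 0 or arr[:, 1].min() < 0
                or arr[:, 0].max() > w - 1 or arr[:, 1].max() > h - 1):
            raise ParameterError("ground-truth quad falls outside the frame")

    return PhantomScene(image=image, gt=gt, params=params, seed=seed)


def _derive_seed(master_seed: int, index: int) -> int:
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_dataset(
    n_images: int,
    params_ranges: Dict[str, Tuple[float, float]] | None = None,
    seed: int = 0,
    out_dir: str | Path = "phantom_dataset",
    base_params: PhantomParams | None = None,
) -> List[Path]:
    """Render ``n_images`` phantoms to ``out_dir`` as PNG images, normalized
    polygon label files, and one VIA-style JSON index.

    ``params_ranges`` draws integer ``n_blines``/``n_alines`` and float
    ``speckle_sigma`` per image from inclusive ranges; each image uses a
    deterministic seed derived from the master seed, so regenerating with
    the same arguments reproduces the files byte for byte.
    """
    from .formats_cli import write_labels, write_via  # local import: avoids a cycle

    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    base = base_params or PhantomParams()
    ranges = params_ranges or {"n_blines": (1, 3), "speckle_sigma": (0.1, 0.2)}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    written: List[Path] = []
    via_records = {}
    for i in range(n_images):
        img_seed = _derive_seed(seed, i)
        rng = np.random.default_rng(img_seed)
        overrides = {}
        for key, (lo, hi) in ranges.items():
            if key in ("n_blines", "n_alines"):
                overrides[key] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                overrides[key] = float(rng.uniform(lo, hi))
        scene = render_phantom(replace(base, **overrides), seed=img_seed)

        name = f"phantom_{i:04d}"
        img_path = out / f"{name}.png"
        Image.fromarray(scene.image, mode="L").save(img_path)
        label_path = out / f"{name}.txt"
        write_labels(scene.gt, (base.width, base.height), label_path)
        written.extend([img_path, label_path])

        via_records[f"{name}.png"] = {
            "filename": f"{name}.png",
            "size": img_path.stat().st_size,
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [round(x, 2) for x in q.xs],
                        "all_points_y": [round(y, 2) for y in q.ys],
                    },
                    "region_attributes": {"label": "B-line"},
                }
                for q in scene.gt
            ],
        }

    via_path = out / "via_project.json"
    write_via(via_records, via_path)
    written.append(via_path)
    return written
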