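"""Image-quality chain for B-mode lung ultrasound frames.

Exported clips carry two kinds of nuisance content: everything outside the
fan-shaped scan sector (black margins, measure scales) and burned-in text
labels.  The chain here (a) extracts the scan region of interest by Otsu
thresholding, morphological refinement and largest-contour selection, and
(b) removes text by detecting label regions and harmonically inpainting
them from their surroundings.  By default text removal runs before
cropping, so border labels influence neither the threshold nor the contour.

Text detection is pluggable: any object with a ``detect(img)`` method
works.  The package ships a stub detector (caller-specified boxes, for
pipelines where label positions are known) and a heuristic detector for
small bright glyph blocks near the image border; an external OCR engine can
be plugged in behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Protocol, Sequence, Tuple

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve
from skimage import measure, morphology

from .errors import DegenerateImageError, NoRoIError, ParameterError, TextDetectionError

__all__ = [
    "TextRegion",
    "TextDetector",
    "StubTextDetector",
    "HeuristicTextDetector",
    "PreprocessConfig",
    "otsu_threshold",
    "morph_refine",
    "extract_roi",
    "inpaint_regions",
    "detect_text",
    "preprocess_image",
]


@dataclass(frozen=True)
class TextRegion:
    """Axis-aligned region suspected to contain burned-in text.

    Bounds are half-open pixel indices: ``x_min <= x < x_max``.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    detector_tag: str = ""

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ParameterError(f"empty text region {self!r}")

    def validate_inside(self, shape: Tuple[int, int]) -> None:
        h, w = shape
        if self.x_min < 0 or self.y_min < 0 or self.x_max > w or self.y_max > h:
            raise ParameterError(f"region {self!r} outside image of shape {shape}")

    def slices(self) -> Tuple[slice, slice]:
        return slice(self.y_min, self.y_max), slice(self.x_min, self.x_max)


class TextDetector(Protocol):
    def detect(self, img: np.ndarray) -> List[TextRegion]: ...


def _check_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ParameterError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ParameterError("image contains non-finite values")
    return arr


def otsu_threshold(img: np.ndarray) -> int:
    """Integer threshold maximizing between-class variance of the 256-bin
    histogram; pixels strictly above the threshold are foreground.

    Ties pick the smallest maximizing threshold.  A constant image has no
    two classes to separate and raises :class:`DegenerateImageError`.
    """
    arr = _check_image(img)
    values = np.clip(np.round(arr.astype(float)), 0, 255).astype(np.int64)
    hist = np.bincount(values.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    total = hist.sum()
    p = hist / total
    omega0 = np.cumsum(p)              # class {0..t}
    mu_t = np.cumsum(p * np.arange(256))
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.zeros(256)
    sigma_b[valid] = (mu_total * omega0[valid] - mu_t[valid]) ** 2 / (
        omega0[valid] * omega1[valid]
    )
    return int(np.argmax(sigma_b))     # argmax returns the smallest maximizer


def morph_refine(mask: np.ndarray, open_radius: int = 2, close_radius: int = 5) -> np.ndarray:
    """Binary opening (disk ``open_radius``) then closing (disk
    ``close_radius``); radius 0 skips the corresponding step."""
    if open_radius < 0 or close_radius < 0:
        raise ParameterError("radii must be >= 0")
    out = np.asarray(mask).astype(bool)
    if open_radius > 0:
        out = morphology.opening(out, morphology.disk(open_radius))
    if close_radius > 0:
        out = morphology.closing(out, morphology.disk(close_radius))
    return out


def extract_roi(
    img: np.ndarray, open_radius: int = 2, close_radius: int = 5
) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Crop the image to the bounding rectangle of the largest bright blob.

    Binarizes at the Otsu threshold, refines with morphology, labels the
    foreground and selects the largest component.  Returns the crop and its
    ``(x, y)`` offset in the original frame.  A constant bright image is its
    own RoI; a constant dark image has none.
    """
    arr = _check_image(img)
    flat = arr.astype(float)
    if flat.max() == flat.min():
        if flat.max() > 0:
            return arr.copy(), (0, 0)
        raise NoRoIError("all-black image: no region of interest")
    t = otsu_threshold(arr)
    mask = morph_refine(flat > t, open_radius, close_radius)
    if not mask.any():
        raise NoRoIError("no foreground left after morphological refinement")
    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    y0, x0, y1, x1 = largest.bbox
    return arr[y0:y1, x0:x1].copy(), (int(x0), int(y0))


def inpaint_regions(img: np.ndarray, regions: Sequence[TextRegion]) -> np.ndarray:
    """Fill each region harmonically from the surrounding pixels.

    Region pixels are replaced by the solution of the discrete Laplace
    equation with the non-region pixels as boundary values (each filled
    pixel becomes the average of its 4-neighbors).  Values therefore stay
    within the range of the surrounding ring, and pixels outside all
    regions are returned bit-identical.
    """
    arr = _check_image(img)
    if not regions:
        return arr.copy()
    h, w = arr.shape
    region_mask = np.zeros((h, w), dtype=bool)
    for reg in regions:
        reg.validate_inside((h, w))
        region_mask[reg.slices()] = True
    if region_mask.all():
        raise ParameterError("text regions cover the whole image: nothing to inpaint from")

    out = arr.copy()
    values = arr.astype(float)
    idx_of = -np.ones((h, w), dtype=np.int64)
    ys, xs = np.nonzero(region_mask)
    n = len(ys)
    idx_of[ys, xs] = np.arange(n)

    A = lil_matrix((n, n))
    b = np.zeros(n)
    for k, (y, x) in enumerate(zip(ys, xs)):
        degree = 0
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w):
                continue
            degree += 1
            j = idx_of[ny, nx]
            if j >= 0:
                A[k, j] = -1.0
            else:
                b[k] += values[ny, nx]
        A[k, k] = float(degree)
    filled = spsolve(A.tocsr(), b)
    if np.issubdtype(out.dtype, np.integer):
        info = np.iinfo(out.dtype)
        filled = np.clip(np.round(filled), info.min, info.max)
    out[ys, xs] = filled.astype(out.dtype)
    return out


@dataclass
class StubTextDetector:
    """Returns caller-specified fixture regions verbatim."""

    regions: List[TextRegion] = field(default_factory=list)

    def detect(self, img: np.ndarray) -> List[TextRegion]:
        shape = _check_image(img).shape
        for reg in self.regions:
            reg.validate_inside(shape)
        return list(self.regions)


@dataclass
class HeuristicTextDetector:
    """Flags small, bright connected components near the image border.

    Burned-in labels on exported ultrasound frames sit at the margins,
    are much brighter than the background there, and form glyph-sized
    components — unlike the scan sector, whose blob is large.  Components
    brighter than ``intensity_threshold`` with a bounding box no bigger
    than ``max_height`` x ``max_width`` whose box lies within
    ``border_margin`` pixels of an image edge are reported; nearby boxes
    (within ``merge_gap``) merge into one region.
    """

    intensity_threshold: float = 200.0
    max_height: int = 32
    max_width: int = 64
    border_margin: int = 48
    merge_gap: int = 3
    pad: int = 1

    def detect(self, img: np.ndarray) -> List[TextRegion]:
        arr = _check_image(img).astype(float)
        h, w = arr.shape
        bright = arr >= self.intensity_threshold
        if not bright.any():
            return []
        labels = measure.label(bright, connectivity=2)
        boxes: List[List[int]] = []
        for region in measure.regionprops(labels):
            y0, x0, y1, x1 = region.bbox
            if (y1 - y0) > self.max_height or (x1 - x0) > self.max_width:
                continue
            edge_dist = min(y0, x0, h - y1, w - x1)
            if edge_dist > self.border_margin:
                continue
            boxes.append([x0, y0, x1, y1])
        merged = self._merge(boxes)
        out = []
        for x0, y0, x1, y1 in merged:
            out.append(
                TextRegion(
                    x_min=max(x0 - self.pad, 0),
                    y_min=max(y0 - self.pad, 0),
                    x_max=min(x1 + self.pad, w),
                    y_max=min(y1 + self.pad, h),
                    detector_tag="heuristic",
                )
            )
        return out

    def _merge(self, boxes: List[List[int]]) -> List[List[int]]:
        merged = [list(b) for b in boxes]
        changed = True
        while changed:
            changed = False
            for i in range(len(merged)):
                for j in range(i + 1, len(merged)):
                    a, c = merged[i], merged[j]
                    if (
                        a[0] - self.merge_gap <= c[2]
                        and c[0] - self.merge_gap <= a[2]
                        and a[1] - self.merge_gap <= c[3]
                        and c[1] - self.merge_gap <= a[3]
                    ):
                        merged[i] = [
                            min(a[0], c[0]),
                            min(a[1], c[1]),
                            max(a[2], c[2]),
                            max(a[3], c[3]),
                        ]
                        del merged[j]
                        changed = True
                        break
                if changed:
                    break
        return merged


def detect_text(img: np.ndarray, detector: TextDetector) -> List[TextRegion]:
    """Run the injected detector; failures surface as
    :class:`TextDetectionError`."""
    if detector is None:
        raise ParameterError("a text detector must be provided")
    try:
        return detector.detect(img)
    except (ParameterError, DegenerateImageError):
        raise
    except Exception as exc:  # detector implementations are external code
        raise TextDetectionError(f"text detector failed: {exc}") from exc


@dataclass
class PreprocessConfig:
    """Settings of the preprocessing chain."""

    open_radius: int = 2
    close_radius: int = 5
    text_detector: Optional[TextDetector] = None
    #: remove text before cropping (default) or on the cropped RoI
    text_before_crop: bool = True


def preprocess_image(
    img: np.ndarray, cfg: PreprocessConfig | None = None
) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Full chain: text detection → inpainting → RoI extraction.

    Without a text detector this reduces to :func:`extract_roi`.  Returns
    the cleaned crop and its ``(x, y)`` offset in the input frame.
    """
    cfg = cfg or PreprocessConfig()
    arr = _check_image(img)
    if cfg.text_detector is not None and cfg.text_before_crop:
        regions = detect_text(arr, cfg.text_detector)
        arr = inpaint_regions(arr, regions)
    crop, offset = extract_roi(arr, cfg.open_radius, cfg.close_radius)
    if cfg.text_detector is not None and not cfg.text_before_crop:
        regions = detect_text(crop, cfg.text_detector)
        crop = inpaint_regions(crop, regions)
    return crop, offset
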