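"""Mask construction: contour rasterization, within-lesion thresholding, and
the surrounding reference region.

Rasterization uses the pixel-center even-odd rule with the half-open edge
convention (a center lying exactly on a lower/left edge is inside, on an
upper/right edge outside), so masks are bit-exact and translation-equivariant
under whole-pixel shifts.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .datatypes import AnnotationError, BinaryMask, GrayscaleImage, LesionAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "rasterize_contour",
    "otsu_threshold",
    "binarize_lesion",
    "default_reference_margin",
    "extract_reference_region",
]


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd crossing test for points against a closed polygon.

    A ray is cast in the +x direction from each point; an edge is crossed when
    the point's y lies in the half-open span [y_a, y_b) of the edge and the
    edge's x at that height is strictly right of the point.
    """
    xa, ya = poly[:, 0], poly[:, 1]
    xb, yb = np.roll(xa, -1), np.roll(ya, -1)
    inside = np.zeros(xs.shape, dtype=bool)
    for k in range(len(xa)):
        if ya[k] == yb[k]:
            continue
        spans = ((ya[k] <= ys) & (ys < yb[k])) | ((yb[k] <= ys) & (ys < ya[k]))
        if not spans.any():
            continue
        xint = xa[k] + (ys - ya[k]) * (xb[k] - xa[k]) / (yb[k] - ya[k])
        inside ^= spans & (xint > xs)
    return inside


def rasterize_contour(annotation: LesionAnnotation, image_shape: tuple[int, int]) -> BinaryMask:
    """Fill a closed contour into a boolean lesion mask.

    A pixel belongs to the mask iff its center (integer coordinates) lies
    inside the polygon under the even-odd rule.

    Raises
    ------
    AnnotationError
        If the polygon leaves the image bounds or encloses no pixel center.
    """
    nrow, ncol = image_shape
    v = annotation.vertices
    if v[:, 0].min() < 0 or v[:, 1].min() < 0 or v[:, 0].max() > ncol - 1 or v[:, 1].max() > nrow - 1:
        raise AnnotationError(
            f"lesion {annotation.lesion_id}: contour exceeds image bounds {image_shape}"
        )
    x0 = int(math.floor(v[:, 0].min()))
    x1 = int(math.ceil(v[:, 0].max()))
    y0 = int(math.floor(v[:, 1].min()))
    y1 = int(math.ceil(v[:, 1].max()))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = _points_in_polygon(xs.astype(float), ys.astype(float), v)
    mask = np.zeros(image_shape, dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    if not mask.any():
        raise AnnotationError(
            f"lesion {annotation.lesion_id}: contour encloses no pixel center"
        )
    return BinaryMask(mask, role="lesion")


def otsu_threshold(values: np.ndarray) -> int | None:
    """Otsu's threshold on an 8-bit sample, with the high class = values >= t.

    Scans every candidate split t in 1..255 of the 256-bin histogram and
    returns the t maximizing the between-class variance (tie -> smallest t).
    Returns ``None`` for a constant sample, where no split exists.
    """
    values = np.asarray(values).ravel()
    hist = np.bincount(values.astype(np.uint8), minlength=256).astype(np.float64)
    total = hist.sum()
    lvls = np.arange(256, dtype=np.float64)
    # cumulative count / intensity sum of the low class {v < t} for t = 1..255
    w_low = np.cumsum(hist)[:-1]
    s_low = np.cumsum(hist * lvls)[:-1]
    w_high = total - w_low
    s_high = (hist * lvls).sum() - s_low
    valid = (w_low > 0) & (w_high > 0)
    if not valid.any():
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        between = w_low * w_high * (s_low / w_low - s_high / w_high) ** 2
    between[~valid] = -np.inf
    return int(np.argmax(between)) + 1  # index i corresponds to split t = i + 1


def binarize_lesion(image: GrayscaleImage, lesion: BinaryMask) -> BinaryMask:
    """Threshold the within-lesion intensities (Otsu) into the high-intensity mask.

    The threshold is computed from the lesion pixels only; the returned mask is
    the subset of lesion pixels with intensity >= threshold.  A constant-
    intensity lesion has no data-driven split, in which case the whole lesion
    is classed high-intensity (area ratio 1) rather than raising.
    """
    if not lesion.pixels.any():
        raise ValueError("lesion mask is empty")
    vals = image.pixels[lesion.pixels]
    t = otsu_threshold(vals)
    if t is None:
        logger.info("constant-intensity lesion: whole lesion classed high-intensity")
        return BinaryMask(lesion.pixels.copy(), role="high_intensity")
    return BinaryMask(lesion.pixels & (image.pixels >= t), role="high_intensity")


def default_reference_margin(lesion: BinaryMask) -> int:
    """Default reference-band width: max(5 px, 25% of the equivalent diameter)."""
    eq_dia_px = 2.0 * math.sqrt(lesion.count / math.pi)
    return max(5, int(round(0.25 * eq_dia_px)))


def extract_reference_region(lesion: BinaryMask, margin_px: int | None = None) -> BinaryMask:
    """Surrounding reference region: the lesion's bounding box expanded by
    ``margin_px`` on each side (clipped to the image), minus the lesion pixels.

    Raises
    ------
    ValueError
        If ``margin_px`` < 1 or the band is empty (lesion fills the image).
    """
    if margin_px is None:
        margin_px = default_reference_margin(lesion)
    if margin_px < 1:
        raise ValueError(f"margin_px must be >= 1, got {margin_px}")
    ys, xs = np.nonzero(lesion.pixels)
    if len(xs) == 0:
        raise ValueError("lesion mask is empty")
    nrow, ncol = lesion.shape
    r0 = max(0, ys.min() - margin_px)
    r1 = min(nrow - 1, ys.max() + margin_px)
    c0 = max(0, xs.min() - margin_px)
    c1 = min(ncol - 1, xs.max() + margin_px)
    box = np.zeros(lesion.shape, dtype=bool)
    box[r0 : r1 + 1, c0 : c1 + 1] = True
    ref = box & ~lesion.pixels
    if not ref.any():
        raise ValueError(
            "reference region is empty: the lesion fills its expanded bounding box; "
            "use an image with more margin around the lesion"
        )
    return BinaryMask(ref, role="reference")
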