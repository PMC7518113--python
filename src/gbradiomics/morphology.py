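"""Morphological (shape) features of a lesion mask.

Eight features, all in physical units derived from the pixel spacing:
Area and convex area (cm²); major/minor axis length of the moment-matched
ellipse and perimeter (cm); orientation (degrees); equivalent diameter (cm);
solidity (dimensionless).

The "fitting ellipse" is the ellipse with the same second-order central
moments as the pixel region: axis length = 4·sqrt(eigenvalue of the
coordinate covariance matrix).  Orientation is the major-axis angle against
the x-axis with y pointing up, signed, in [-90, 90], ties broken toward 0.
Perimeter is the count of 8-connected boundary pixels times the spacing.
The convex hull is taken over pixel-corner points so that solidity <= 1
holds exactly even for thin shapes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import ConvexHull

from .datatypes import BinaryMask

logger = logging.getLogger(__name__)

__all__ = ["MORPH_FEATURE_NAMES", "morphological_features", "boundary_pixel_count"]

MORPH_FEATURE_NAMES = (
    "Area",
    "C.Area",
    "Maj.Len",
    "Min.Len",
    "Per",
    "Ori",
    "Eq.Dia",
    "Sol",
)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def boundary_pixel_count(mask: np.ndarray) -> int:
    """Number of mask pixels with at least one 8-neighbour outside the mask."""
    interior = binary_erosion(mask, structure=_EIGHT_CONN, border_value=0)
    return int((mask & ~interior).sum())


def _convex_area_px(xs: np.ndarray, ys: np.ndarray, mask: np.ndarray) -> float:
    """Convex-hull area (px²) over the corners of the boundary pixels."""
    interior = binary_erosion(mask, structure=_EIGHT_CONN, border_value=0)
    by, bx = np.nonzero(mask & ~interior)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (np.stack([bx, by], axis=1)[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return float(ConvexHull(corners).volume)  # 2-D hull "volume" is its area


def morphological_features(lesion: BinaryMask, pixel_spacing: float) -> dict[str, float]:
    """The 8 shape features of a lesion mask, in cm-based units.

    A single-pixel lesion is degenerate: both axis lengths are 0 and the
    orientation is defined as 0 (logged).
    """
    if not pixel_spacing > 0:
        raise ValueError(f"pixel_spacing must be > 0, got {pixel_spacing}")
    mask = lesion.pixels
    ys, xs = np.nonzero(mask)
    n = len(xs)
    if n == 0:
        raise ValueError("lesion mask is empty")
    sp = float(pixel_spacing)
    area = n * sp**2
    eq_dia = 2.0 * math.sqrt(area / math.pi)
    per = boundary_pixel_count(mask) * sp
    c_area = _convex_area_px(xs, ys, mask) * sp**2
    sol = area / c_area

    # second-order central moments of the pixel coordinates, y flipped up so
    # the orientation sign follows the mathematical convention
    x = xs - xs.mean()
    y_up = -(ys - ys.mean())
    mu20 = float((x**2).mean())
    mu02 = float((y_up**2).mean())
    mu11 = float((x * y_up).mean())
    if n == 1:
        logger.info("single-pixel lesion: axis lengths 0, orientation 0")
        maj = minr = 0.0
        ori = 0.0
    else:
        half_trace = (mu20 + mu02) / 2.0
        half_gap = math.hypot(mu20 - mu02, 2.0 * mu11) / 2.0
        lam1 = half_trace + half_gap
        lam2 = max(half_trace - half_gap, 0.0)
        maj = 4.0 * math.sqrt(lam1) * sp
        minr = 4.0 * math.sqrt(lam2) * sp
        ori = math.degrees(0.5 * math.atan2(2.0 * mu11, mu20 - mu02))
    return {
        "Area": area,
        "C.Area": c_area,
        "Maj.Len": maj,
        "Min.Len": minr,
        "Per": per,
        "Ori": ori,
        "Eq.Dia": eq_dia,
        "Sol": sol,
    }
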