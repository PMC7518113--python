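"""Core data containers for the radiomics pipeline.

All image coordinates are 0-based with ``x`` = column and ``y`` = row; pixel
centers sit at integer coordinates.  Physical calibration is an isotropic
pixel spacing in centimetres per pixel, carried explicitly because the
morphological features (axis lengths, perimeter, areas) are meaningless
without it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from shapely.geometry import Polygon


class AnnotationError(ValueError):
    """Raised for degenerate or out-of-bounds lesion contours."""


class ConfigurationError(ValueError):
    """Raised for invalid pipeline or cohort configuration."""


@dataclass
class GrayscaleImage:
    """A 2-D 8-bit grayscale ultrasound image with physical calibration.

    Parameters
    ----------
    pixels
        2-D array of intensities in [0, 255] (stored as ``uint8``).
    pixel_spacing
        Isotropic pixel spacing in cm per pixel; must be positive.
    """

    pixels: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ConfigurationError("image must be a 2-D array of at least 2x2 pixels")
        if arr.min() < 0 or arr.max() > 255:
            raise ConfigurationError("pixel intensities must lie in [0, 255]")
        self.pixels = arr.astype(np.uint8)
        if not self.pixel_spacing > 0:
            raise ConfigurationError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LesionAnnotation:
    """A closed lesion contour (ordered polygon) with identifiers and label.

    ``vertices`` is an (n, 2) array of [x, y] pixel coordinates.  The polygon
    is implicitly closed (last vertex connects to the first); a duplicated
    closing vertex is tolerated and dropped.  Label 0 = cholesterol polyp
    (pseudo polyp), 1 = tubular adenoma (true polyp).
    """

    vertices: np.ndarray
    lesion_id: str
    patient_id: str
    label: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise AnnotationError(f"lesion {self.lesion_id}: vertices must be an (n, 2) array")
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise AnnotationError(f"lesion {self.lesion_id}: a contour needs >= 3 distinct vertices")
        poly = Polygon(v)
        if not poly.is_valid:
            raise AnnotationError(f"lesion {self.lesion_id}: contour is self-intersecting or degenerate")
        if poly.area <= 0:
            raise AnnotationError(f"lesion {self.lesion_id}: contour encloses zero area")
        self.vertices = v

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


MaskRole = Literal["lesion", "high_intensity", "reference"]


@dataclass
class BinaryMask:
    """A boolean pixel mask tied to one of the three pipeline roles."""

    pixels: np.ndarray
    role: MaskRole = "lesion"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ConfigurationError("mask must be 2-D")
        self.pixels = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        return int(self.pixels.sum())

    def __and__(self, other: "BinaryMask") -> np.ndarray:
        return self.pixels & other.pixels


def check_mask_algebra(lesion: BinaryMask, high: BinaryMask, reference: BinaryMask) -> None:
    """Assert the mask invariants: high ⊆ lesion and reference ∩ lesion = ∅."""
    if np.any(high.pixels & ~lesion.pixels):
        raise ValueError("high-intensity mask is not a subset of the lesion mask")
    if np.any(reference.pixels & lesion.pixels):
        raise ValueError("reference mask overlaps the lesion mask")
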