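"""Spatial (intensity and texture) features of a lesion.

Three groups, 72 features in total per lesion:

* 9 first-order statistics of the within-lesion intensity histogram,
  including the lesion/reference intensity ratios RImean and RImedian;
* 60 gray-level co-occurrence matrix (GLCM) statistics — energy, contrast,
  entropy and homogeneity, each at pixel offsets d = 1..15;
* 3 binary-texture features of the high-intensity mask: area ratio (AR),
  center deviation degree (CDD) and dispersion degree (DD).

Conventions (documented, configurable where noted): GLCM intensities are
quantized to 64 equal-width bins over [0, 255]; pair counting is symmetric
and summed over the four directions 0°/45°/90°/135°; entropies are base-2;
homogeneity uses the 1/(1 + |i-j|) kernel; kurtosis is non-excess (normal
distribution = 3); CDD/DD distances are normalized by the lesion's
equivalent radius sqrt(area/π).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from skimage.feature import graycomatrix

from .datatypes import BinaryMask, GrayscaleImage

logger = logging.getLogger(__name__)

__all__ = [
    "FIRST_ORDER_NAMES",
    "GLCM_TYPES",
    "GLCM_OFFSETS",
    "BINARY_TEXTURE_NAMES",
    "SPATIAL_FEATURE_NAMES",
    "first_order_features",
    "glcm",
    "glcm_statistics",
    "binary_texture_features",
    "spatial_features",
]

FIRST_ORDER_NAMES = (
    "IMean",
    "IMedian",
    "SD",
    "CoV",
    "HistEntropy",
    "Skewness",
    "Kurtosis",
    "RImean",
    "RImedian",
)
GLCM_TYPES = ("Ener", "Cont", "Entr", "Homo")
GLCM_OFFSETS = tuple(range(1, 16))
BINARY_TEXTURE_NAMES = ("AR", "CDD", "DD")
SPATIAL_FEATURE_NAMES = (
    FIRST_ORDER_NAMES
    + tuple(f"{t}{d}" for t in GLCM_TYPES for d in GLCM_OFFSETS)
    + BINARY_TEXTURE_NAMES
)

_FOUR_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def first_order_features(
    image: GrayscaleImage, lesion: BinaryMask, reference: BinaryMask
) -> dict[str, float]:
    """First-order intensity statistics of the lesion, plus reference ratios.

    CoV = SD / IMean; HistEntropy is the base-2 Shannon entropy of the
    normalized 256-bin intensity histogram; Skewness/Kurtosis are the sample
    moment estimators (kurtosis non-excess).  RImean (RImedian) is the lesion
    mean (median) divided by the reference mean (median); a zero reference
    statistic yields NaN, logged.
    """
    vals = image.pixels[lesion.pixels].astype(np.float64)
    ref = image.pixels[reference.pixels].astype(np.float64)
    if vals.size == 0 or ref.size == 0:
        raise ValueError("lesion and reference masks must be nonempty")
    mean = float(vals.mean())
    median = float(np.median(vals))
    sd = float(vals.std(ddof=0))
    cov = sd / mean if mean != 0 else math.nan
    counts = np.bincount(vals.astype(np.uint8), minlength=256)
    hist_entropy = float(stats.entropy(counts, base=2))
    if sd == 0:
        skew, kurt = 0.0, 0.0  # degenerate constant lesion
    else:
        skew = float(stats.skew(vals, bias=True))
        kurt = float(stats.kurtosis(vals, fisher=False, bias=True))
    ref_mean = float(ref.mean())
    ref_median = float(np.median(ref))
    if ref_mean == 0 or ref_median == 0:
        logger.warning("reference mean/median is 0; intensity ratios reported missing")
    ri_mean = mean / ref_mean if ref_mean != 0 else math.nan
    ri_median = median / ref_median if ref_median != 0 else math.nan
    return {
        "IMean": mean,
        "IMedian": median,
        "SD": sd,
        "CoV": cov,
        "HistEntropy": hist_entropy,
        "Skewness": skew,
        "Kurtosis": kurt,
        "RImean": ri_mean,
        "RImedian": ri_median,
    }


def glcm(
    image: GrayscaleImage,
    lesion: BinaryMask,
    d: int,
    levels: int = 64,
    angles: tuple[float, ...] = _FOUR_ANGLES,
) -> np.ndarray | None:
    """Normalized symmetric GLCM at offset ``d``, restricted to the lesion.

    Intensities are quantized to ``levels`` equal-width bins over [0, 255];
    only pixel pairs with both members inside the lesion are counted, for the
    given ``angles``, symmetrized and summed over directions, then normalized
    to sum 1.  Returns ``None`` when the lesion admits no valid pair at this
    offset.
    """
    if d < 1:
        raise ValueError(f"offset d must be >= 1, got {d}")
    quant = (image.pixels.astype(np.uint16) * levels) // 256
    # out-of-lesion pixels get a sentinel level so library co-occurrence
    # counting can run on the full frame and the sentinel row/col is dropped
    framed = np.where(lesion.pixels, quant, levels).astype(np.uint8 if levels < 255 else np.uint16)
    counts = graycomatrix(
        framed, distances=[d], angles=list(angles), levels=levels + 1, symmetric=True
    )
    mat = counts[:levels, :levels, 0, :].sum(axis=-1).astype(np.float64)
    total = mat.sum()
    if total == 0:
        return None
    return mat / total


def glcm_statistics(P: np.ndarray) -> tuple[float, float, float, float]:
    """(Ener, Cont, Entr, Homo) of a normalized co-occurrence matrix.

    Ener = ΣP²; Cont = Σ(i-j)²P; Entr = -ΣP log2 P (zero terms skipped);
    Homo = ΣP/(1+|i-j|).
    """
    P = np.asarray(P, dtype=np.float64)
    i, j = np.indices(P.shape)
    ener = float((P**2).sum())
    cont = float(((i - j) ** 2 * P).sum())
    nz = P[P > 0]
    entr = float(-(nz * np.log2(nz)).sum())
    homo = float((P / (1.0 + np.abs(i - j))).sum())
    return ener, cont, entr, homo


def binary_texture_features(
    lesion: BinaryMask, high_intensity: BinaryMask
) -> tuple[float, float, float]:
    """(AR, CDD, DD) of the high-intensity mask.

    AR is the high-intensity fraction of the lesion area.  CDD (DD) is the
    mean Euclidean distance from each high-intensity pixel to the lesion
    (high-intensity) centroid, divided by the lesion's equivalent radius
    R_eq = sqrt(area/π) in pixels.  Low DD means the bright echoes cluster
    tightly, as cholesterol-crystal foci do.
    """
    if not lesion.pixels.any() or not high_intensity.pixels.any():
        raise ValueError("lesion and high-intensity masks must be nonempty")
    if np.any(high_intensity.pixels & ~lesion.pixels):
        raise ValueError("high-intensity mask must be a subset of the lesion mask")
    ly, lx = np.nonzero(lesion.pixels)
    hy, hx = np.nonzero(high_intensity.pixels)
    r_eq = math.sqrt(len(lx) / math.pi)
    lesion_c = (lx.mean(), ly.mean())
    high_c = (hx.mean(), hy.mean())
    cdd = float(np.hypot(hx - lesion_c[0], hy - lesion_c[1]).mean() / r_eq)
    dd = float(np.hypot(hx - high_c[0], hy - high_c[1]).mean() / r_eq)
    ar = len(hx) / len(lx)
    return ar, cdd, dd


def spatial_features(
    image: GrayscaleImage,
    lesion: BinaryMask,
    high_intensity: BinaryMask,
    reference: BinaryMask,
    levels: int = 64,
) -> dict[str, float]:
    """All 72 spatial features of one lesion, in stable order.

    GLCM statistics at offsets the lesion cannot support are reported as NaN.
    """
    out = first_order_features(image, lesion, reference)
    glcm_vals: dict[str, float] = {f"{t}{d}": math.nan for t in GLCM_TYPES for d in GLCM_OFFSETS}
    for d in GLCM_OFFSETS:
        P = glcm(image, lesion, d, levels=levels)
        if P is None:
            logger.warning("no valid GLCM pair at offset %d; statistics reported missing", d)
            continue
        ener, cont, entr, homo = glcm_statistics(P)
        glcm_vals[f"Ener{d}"] = ener
        glcm_vals[f"Cont{d}"] = cont
        glcm_vals[f"Entr{d}"] = entr
        glcm_vals[f"Homo{d}"] = homo
    out.update({name: glcm_vals[name] for t in GLCM_TYPES for d in GLCM_OFFSETS for name in [f"{t}{d}"]})
    ar, cdd, dd = binary_texture_features(lesion, high_intensity)
    out.update({"AR": ar, "CDD": cdd, "DD": dd})
    assert tuple(out.keys()) == SPATIAL_FEATURE_NAMES
    return out
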