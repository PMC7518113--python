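"""Per-lesion feature extraction driver: 72 spatial + 8 morphological = 80."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import GrayscaleImage, LesionAnnotation, check_mask_algebra
from .masks import binarize_lesion, extract_reference_region, rasterize_contour
from .morphology import MORPH_FEATURE_NAMES, morphological_features
from .spatial import SPATIAL_FEATURE_NAMES, spatial_features

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "ExtractionConfig",
    "extract_features",
    "extract_feature_table",
]

#: The 80 feature names in stable extraction order.
FEATURE_NAMES: tuple[str, ...] = SPATIAL_FEATURE_NAMES + MORPH_FEATURE_NAMES

#: Feature name -> family ("spatial" | "morphological").
FEATURE_FAMILIES: dict[str, str] = {
    **{n: "spatial" for n in SPATIAL_FEATURE_NAMES},
    **{n: "morphological" for n in MORPH_FEATURE_NAMES},
}


@dataclass
class ExtractionConfig:
    """Knobs of the extraction stage.

    glcm_levels
        Gray-level count for GLCM quantization (equal-width bins on [0, 255]).
    reference_margin_px
        Width of the surrounding reference band; ``None`` uses the default
        max(5 px, 25% of the lesion's equivalent diameter).
    """

    glcm_levels: int = 64
    reference_margin_px: int | None = None


def extract_features(
    image: GrayscaleImage,
    annotation: LesionAnnotation,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Extract all 80 features for one lesion.

    Rasterizes the contour, thresholds the lesion interior into the
    high-intensity mask, builds the surrounding reference band, checks the
    mask algebra, and evaluates the spatial and morphological feature sets.
    """
    config = config or ExtractionConfig()
    lesion = rasterize_contour(annotation, image.shape)
    high = binarize_lesion(image, lesion)
    reference = extract_reference_region(lesion, config.reference_margin_px)
    check_mask_algebra(lesion, high, reference)
    out = spatial_features(image, lesion, high, reference, levels=config.glcm_levels)
    out.update(morphological_features(lesion, image.pixel_spacing))
    assert len(out) == 80 and tuple(out.keys()) == FEATURE_NAMES
    return out


def extract_feature_table(
    lesions,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Extract features for an iterable of lesions into a table.

    Each element must expose ``image`` (:class:`GrayscaleImage`), ``contour``
    (:class:`LesionAnnotation`) and ``label``; the returned DataFrame is
    indexed by lesion id with ``patient_id`` and ``label`` columns followed
    by the 80 feature columns.
    """
    rows = []
    index = []
    for les in lesions:
        try:
            feats = extract_features(les.image, les.contour, config)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for lesion {les.contour.lesion_id}: {exc}"
            ) from exc
        rows.append({"patient_id": les.contour.patient_id, "label": les.label, **feats})
        index.append(les.contour.lesion_id)
    cols = ["patient_id", "label", *FEATURE_NAMES]
    table = pd.DataFrame(rows, index=pd.Index(index, name="lesion_id"), columns=cols)
    if len(table):
        table["label"] = table["label"].astype(int)
    return table
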