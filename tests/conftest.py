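"""Shared fixtures: small geometric masks and session-scoped synthetic
cohorts (generated once, reused by the property and acceptance tests)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gbradiomics import (
    BinaryMask,
    CohortConfig,
    GrayscaleImage,
    LesionAnnotation,
    extract_feature_table,
    generate_cohort,
)


def disk_mask(radius: int, size: int | None = None, center: tuple[float, float] | None = None) -> BinaryMask:
    """Rasterized filled disk: pixel centers within ``radius`` of the center."""
    size = size or (2 * radius + 5)
    cx, cy = center or ((size - 1) / 2.0, (size - 1) / 2.0)
    yy, xx = np.mgrid[0:size, 0:size]
    return BinaryMask((xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2)


def square_annotation(lo: float = 1.0, hi: float = 5.0, lesion_id: str = "sq") -> LesionAnnotation:
    verts = np.array([[lo, lo], [hi, lo], [hi, hi], [lo, hi]], dtype=float)
    return LesionAnnotation(verts, lesion_id=lesion_id, patient_id="p0")


def constant_image(shape=(20, 20), value: int = 100, spacing: float = 0.01) -> GrayscaleImage:
    return GrayscaleImage(np.full(shape, value, dtype=np.uint8), pixel_spacing=spacing)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort for unit-level checks."""
    return generate_cohort(CohortConfig(n0=6, n1=6, seed=42))


@pytest.fixture(scope="session")
def default_cohort_table() -> pd.DataFrame:
    """Feature table of a 100 + 100 default-parameter cohort (seed 202)."""
    cohort = generate_cohort(CohortConfig(n0=100, n1=100, seed=202))
    return extract_feature_table(cohort)


@pytest.fixture(scope="session")
def null_cohort_table() -> pd.DataFrame:
    """Feature table of a cohort whose two classes share identical
    generative parameters (no real class signal)."""
    cohort = generate_cohort(CohortConfig.null(n0=50, n1=50, seed=77))
    return extract_feature_table(cohort)


@pytest.fixture(scope="session")
def multi_seed_aucs() -> list[float]:
    """Held-out AUC of the all-selected-features SVM over 20 independent
    default cohorts of 100 + 100 lesions (seeds 0..19)."""
    from gbradiomics import PipelineConfig, run_pipeline

    aucs = []
    for seed in range(20):
        cfg = PipelineConfig(cohort=CohortConfig(n0=100, n1=100, seed=seed), seed=seed)
        result = run_pipeline(cfg)
        aucs.append(result.reports["All features"].auc)
    return aucs
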