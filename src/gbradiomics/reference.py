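"""Published summary statistics of the original clinical cohort.

The study that introduced this pipeline analysed 99 pathologically proven
gallbladder polyps (58 cholesterol polyps in 55 patients, class 0; 41
tubular adenomas in 41 patients, class 1).  The tables below encode its
printed per-feature summaries (value ± spread, p, Fv, F) after first-stage
selection, and the reported test-set classifier performance.  They serve as
regression fixtures: replaying second-stage selection on these rows must
reproduce the published thresholds and the final 8-feature set, and the
screening statistics recomputed from the printed class summaries must match
the printed Fv/F columns.

For rows flagged non-normal the printed location/spread is a median/IQR, so
only mean±SD rows can be used to recompute Fv and F from summaries.
"""

from __future__ import annotations

from .selection import GroupSummary, SelectionRecord

__all__ = [
    "N0",
    "N1",
    "STAGE1_TABLE",
    "SELECTED_SPATIAL",
    "SELECTED_MORPHOLOGICAL",
    "REPORTED_PERFORMANCE",
    "reference_stage1_records",
]

N0, N1 = 58, 41

# feature, family, (val0, spread0, normal0), (val1, spread1, normal1), p, Fv, F
STAGE1_TABLE = [
    ("CDD", "spatial", (0.614, 0.052, True), (0.639, 0.031, True), 0.007, 0.413, 0.545),
    ("DD", "spatial", (0.579, 0.054, True), (0.608, 0.041, True), 0.005, 0.421, 0.564),
    ("AR", "spatial", (0.536, 0.119, True), (0.580, 0.090, True), 0.046, 0.298, 0.408),
    ("Imedian", "spatial", (88.474, 24.727, True), (104.256, 31.886, True), 0.007, 0.391, 0.550),
    ("Imean", "spatial", (88.237, 24.154, True), (102.897, 30.604, True), 0.009, 0.376, 0.530),
    ("CoV", "spatial", (0.307, 0.105, False), (0.263, 0.084, True), 0.001, 0.322, 0.674),
    ("Kurtosis", "spatial", (2.858, 0.858, False), (3.279, 1.051, False), 0.012, 0.310, 0.235),
    ("Cont14", "spatial", (4.063, 1.682, False), (2.715, 1.867, True), 0.001, 0.536, 0.883),
    ("Ener8", "spatial", (0.050, 0.023, False), (0.068, 0.038, False), 0.002, 0.414, 0.583),
    ("Homo13", "spatial", (0.500, 0.069, True), (0.572, 0.057, True), 0.001, 0.796, 0.980),
    ("Entr6", "spatial", (4.712, 0.427, False), (4.380, 0.720, True), 0.003, 0.396, 0.564),
    ("Area", "morphological", (0.525, 0.489, False), (1.623, 1.405, False), 0.001, 0.738, 0.883),
    ("Maj.Len", "morphological", (0.971, 0.485, False), (1.738, 0.912, False), 0.001, 0.742, 1.045),
    ("Min.Len", "morphological", (0.651, 0.298, False), (1.135, 0.602, False), 0.001, 0.720, 1.117),
    ("C.Area", "morphological", (0.537, 0.511, False), (1.707, 1.423, False), 0.001, 0.774, 0.882),
    ("Eq.Dia", "morphological", (0.818, 0.393, True), (1.438, 0.650, False), 0.001, 0.816, 1.131),
    ("Ori", "morphological", (15.261, 41.013, False), (33.606, 44.117, True), 0.002, 0.305, 0.562),
    ("Per", "morphological", (2.637, 1.281, False), (5.033, 2.353, False), 0.001, 0.894, 1.124),
    ("Sol", "morphological", (0.980, 0.030, False), (0.963, 0.053, False), 0.005, 0.273, 0.283),
]

#: Features retained by second-stage selection in the original study.
SELECTED_SPATIAL = {"Cont14", "Ener8", "Homo13", "Entr6", "DD"}
SELECTED_MORPHOLOGICAL = {"Maj.Len", "Eq.Dia", "Per"}

#: Reported test-set performance (Acc, Sen, Spc, Yi, AUC) per feature subset.
REPORTED_PERFORMANCE = {
    "All features": (0.875, 0.885, 0.857, 0.742, 0.898),
    "Morphological features": (0.825, 0.826, 0.824, 0.650, 0.862),
    "Spatial features": (0.850, 0.864, 0.833, 0.697, 0.886),
}


def reference_stage1_records() -> list[SelectionRecord]:
    """The published stage-1 survivor table as SelectionRecord fixtures.

    For non-normal rows the printed location/spread is a median/IQR and is
    stored in the summary's median/iqr slots; means/SDs are only populated
    for normal rows.
    """
    records = []
    for feature, family, (v0, s0, norm0), (v1, s1, norm1), p, fv, f in STAGE1_TABLE:
        summary = GroupSummary(
            n0=N0,
            n1=N1,
            mean0=v0 if norm0 else float("nan"),
            sd0=s0 if norm0 else float("nan"),
            mean1=v1 if norm1 else float("nan"),
            sd1=s1 if norm1 else float("nan"),
            median0=v0 if not norm0 else float("nan"),
            iqr0=s0 if not norm0 else float("nan"),
            median1=v1 if not norm1 else float("nan"),
            iqr1=s1 if not norm1 else float("nan"),
            normal0=norm0,
            normal1=norm1,
        )
        rec = SelectionRecord(
            feature=feature,
            family=family,
            glcm_type=feature[:4] if feature[:4] in ("Ener", "Cont", "Entr", "Homo") else "none",
            p=p,
            Fv=fv,
            F=f,
            summary=summary,
            stage1_kept=True,
        )
        records.append(rec)
    return records
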