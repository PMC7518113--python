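"""Two-stage univariate feature selection.

Stage 1: each feature is tested for a class difference with a
normality-routed test (Shapiro–Wilk per group at α = 0.05; both groups
normal → Welch two-sample t-test, otherwise Kruskal–Wallis).  Features with
p >= 0.05 are dropped.  Because the 60 GLCM features are internally
redundant, each GLCM type (Ener/Cont/Entr/Homo) contributes only its single
significant member with the largest Fisher ratio Fv; all other significant
features are kept.

Stage 2: within each feature family (spatial, morphological) independently,
the medians of the survivors' Fv and F values are computed and only features
with Fv >= median(Fv) AND F >= median(F) are retained (inclusive, so a
feature sitting exactly at a median survives).

The two screening statistics:

* Fv — Fisher's inter–intraclass variance ratio,
  ``|x̄0 - x̄1| / sqrt(σ0² + σ1²)``;
* F — z-score separation: both classes are standardized against the pooled
  sample (all n0 + n1 values), and F is the absolute difference of the
  class-mean z-scores, which equals ``|x̄0 - x̄1| / SD(pooled sample)``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "SelectionRecord",
    "univariate_test",
    "fisher_ratio",
    "fisher_ratio_from_summary",
    "z_score_separation",
    "z_score_separation_from_summary",
    "glcm_type_of",
    "build_selection_records",
    "first_stage_select",
    "family_medians",
    "second_stage_select",
    "summarize_feature",
    "select_features",
]

_GLCM_NAME = re.compile(r"^(Ener|Cont|Entr|Homo)(\d+)$")


@dataclass
class GroupSummary:
    """Per-class sample statistics of one feature (class 0 vs class 1)."""

    n0: int
    n1: int
    mean0: float
    sd0: float
    mean1: float
    sd1: float
    median0: float = math.nan
    iqr0: float = math.nan
    median1: float = math.nan
    iqr1: float = math.nan
    normal0: bool = True
    normal1: bool = True

    @classmethod
    def from_samples(cls, x0: np.ndarray, x1: np.ndarray) -> "GroupSummary":
        x0 = np.asarray(x0, dtype=float)
        x1 = np.asarray(x1, dtype=float)
        q0 = np.percentile(x0, [25, 75])
        q1 = np.percentile(x1, [25, 75])
        return cls(
            n0=len(x0),
            n1=len(x1),
            mean0=float(x0.mean()),
            sd0=float(x0.std(ddof=1)) if len(x0) > 1 else 0.0,
            mean1=float(x1.mean()),
            sd1=float(x1.std(ddof=1)) if len(x1) > 1 else 0.0,
            median0=float(np.median(x0)),
            iqr0=float(q0[1] - q0[0]),
            median1=float(np.median(x1)),
            iqr1=float(q1[1] - q1[0]),
            normal0=_is_normal(x0),
            normal1=_is_normal(x1),
        )


@dataclass
class SelectionRecord:
    """Per-feature selection bookkeeping across both stages."""

    feature: str
    family: str  # "spatial" | "morphological"
    glcm_type: str  # "Ener" | "Cont" | "Entr" | "Homo" | "none"
    p: float
    Fv: float
    F: float
    summary: GroupSummary | None = None
    stage1_kept: bool = False
    stage2_kept: bool = False


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk normality at level alpha; a constant sample is non-normal."""
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue >= alpha


def univariate_test(x0: np.ndarray, x1: np.ndarray) -> tuple[float, bool, bool]:
    """Normality-routed two-sided group comparison.

    Returns ``(p, normal0, normal1)``.  Both groups normal (Shapiro–Wilk,
    α = 0.05) routes to the Welch t-test, anything else to Kruskal–Wallis.
    Two groups with zero variance and equal values yield p = 1 by convention.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if len(x0) < 3 or len(x1) < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(np.concatenate([x0, x1])) == 0:
        logger.info("degenerate feature: all values identical; p = 1 by convention")
        return 1.0, False, False
    normal0, normal1 = _is_normal(x0), _is_normal(x1)
    if normal0 and normal1:
        p = float(stats.ttest_ind(x0, x1, equal_var=False).pvalue)
    else:
        p = float(stats.kruskal(x0, x1).pvalue)
    return p, normal0, normal1


def fisher_ratio_from_summary(mean0: float, sd0: float, mean1: float, sd1: float) -> float:
    """Fv = |x̄0 - x̄1| / sqrt(σ0² + σ1²)."""
    denom = math.sqrt(sd0**2 + sd1**2)
    if denom == 0:
        raise ValueError("Fisher ratio undefined: both class variances are zero")
    return abs(mean0 - mean1) / denom


def fisher_ratio(summary: GroupSummary) -> float:
    """Fisher inter–intraclass variance ratio of a summarized feature."""
    return fisher_ratio_from_summary(summary.mean0, summary.sd0, summary.mean1, summary.sd1)


def z_score_separation(x0: np.ndarray, x1: np.ndarray) -> float:
    """F = |mean z-score of class 0 - mean z-score of class 1| under pooled
    standardization, i.e. |x̄0 - x̄1| / SD(concatenated sample, ddof=1)."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    pooled = np.concatenate([x0, x1])
    sd = pooled.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score separation undefined: pooled variance is zero")
    z = (pooled - pooled.mean()) / sd
    return abs(float(z[: len(x0)].mean()) - float(z[len(x0) :].mean()))


def z_score_separation_from_summary(
    n0: int, mean0: float, sd0: float, n1: int, mean1: float, sd1: float
) -> float:
    """Pooled-z F reconstructed from per-class sample means/SDs and sizes.

    The pooled (ddof=1) variance decomposes as
    [(n0-1)σ0² + (n1-1)σ1² + n0(x̄0-m̄)² + n1(x̄1-m̄)²] / (n0+n1-1)
    with m̄ the size-weighted grand mean.
    """
    n = n0 + n1
    grand = (n0 * mean0 + n1 * mean1) / n
    ss = (
        (n0 - 1) * sd0**2
        + (n1 - 1) * sd1**2
        + n0 * (mean0 - grand) ** 2
        + n1 * (mean1 - grand) ** 2
    )
    var = ss / (n - 1)
    if var == 0:
        raise ValueError("z-score separation undefined: pooled variance is zero")
    return abs(mean0 - mean1) / math.sqrt(var)


def glcm_type_of(feature: str) -> str:
    m = _GLCM_NAME.match(feature)
    return m.group(1) if m else "none"


def _glcm_offset_of(feature: str) -> int:
    m = _GLCM_NAME.match(feature)
    return int(m.group(2)) if m else -1


def build_selection_records(
    features: "np.ndarray | object",
    labels: np.ndarray,
    families: dict[str, str],
) -> list[SelectionRecord]:
    """Compute p, Fv and F for every feature column of a table.

    ``features`` is a pandas DataFrame (columns = feature names, rows =
    lesions); ``labels`` holds 0/1 class labels; ``families`` maps feature
    name -> "spatial" | "morphological".  Features that are entirely missing
    or constant in a class get Fv/F of NaN and are never selected.
    """
    labels = np.asarray(labels)
    records: list[SelectionRecord] = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        keep = ~np.isnan(col)
        x0 = col[keep & (labels == 0)]
        x1 = col[keep & (labels == 1)]
        summary = GroupSummary.from_samples(x0, x1)
        try:
            p, n0_flag, n1_flag = univariate_test(x0, x1)
            summary.normal0, summary.normal1 = n0_flag, n1_flag
            fv = fisher_ratio(summary)
            f = z_score_separation(x0, x1)
        except ValueError as exc:
            logger.warning("feature %s skipped: %s", name, exc)
            p, fv, f = 1.0, math.nan, math.nan
        records.append(
            SelectionRecord(
                feature=name,
                family=families[name],
                glcm_type=glcm_type_of(name),
                p=p,
                Fv=fv,
                F=f,
                summary=summary,
            )
        )
    return records


def first_stage_select(records: list[SelectionRecord]) -> list[SelectionRecord]:
    """Significance screen plus per-type GLCM redundancy reduction.

    Drops features with p >= 0.05.  Among the significant members of each
    GLCM type, only the one with the largest Fv survives as the type's
    representative (tie → smallest offset d); every significant non-GLCM
    feature survives.  Returns the surviving records with ``stage1_kept``
    set (flags are also set in place on the input records).
    """
    significant = [r for r in records if r.p < 0.05 and not math.isnan(r.Fv)]
    kept: list[SelectionRecord] = []
    for r in significant:
        if r.glcm_type == "none":
            r.stage1_kept = True
            kept.append(r)
    for gtype in ("Ener", "Cont", "Entr", "Homo"):
        members = [r for r in significant if r.glcm_type == gtype]
        if not members:
            logger.info("GLCM type %s has no significant member; no representative", gtype)
            continue
        best = min(members, key=lambda r: (-r.Fv, _glcm_offset_of(r.feature)))
        best.stage1_kept = True
        kept.append(best)
    order = {r.feature: i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[r.feature])
    return kept


def family_medians(records: list[SelectionRecord], family: str) -> tuple[float, float]:
    """(median Fv, median F) over the records of one family (even count →
    mean of the two middle order statistics)."""
    fam = [r for r in records if r.family == family]
    if not fam:
        raise ValueError(f"no records in family {family!r}")
    return float(np.median([r.Fv for r in fam])), float(np.median([r.F for r in fam]))


def second_stage_select(records: list[SelectionRecord]) -> list[SelectionRecord]:
    """Family-wise median thresholding of the stage-1 survivors.

    Within each family, compute the median Fv and median F over that family's
    records (even count → mean of the two middle order statistics) and keep
    features with Fv >= median(Fv) and F >= median(F).  A single-member
    family is its own median and is retained.
    """
    kept: list[SelectionRecord] = []
    for family in ("spatial", "morphological"):
        fam = [r for r in records if r.family == family]
        if not fam:
            continue
        med_fv, med_f = family_medians(records, family)
        logger.info("family %s: median Fv = %.3f, median F = %.3f", family, med_fv, med_f)
        for r in fam:
            if r.Fv >= med_fv and r.F >= med_f:
                r.stage2_kept = True
                kept.append(r)
    return kept


def summarize_feature(summary: GroupSummary, cls: int, ndigits: int = 3) -> str:
    """Display string for one class of a feature: "mean ± SD" when the class
    sample is normal, otherwise "median ± IQR" with a ``*`` marker."""
    if cls == 0:
        normal, mean, sd, med, iqr = summary.normal0, summary.mean0, summary.sd0, summary.median0, summary.iqr0
    else:
        normal, mean, sd, med, iqr = summary.normal1, summary.mean1, summary.sd1, summary.median1, summary.iqr1
    if normal:
        return f"{mean:.{ndigits}f} ± {sd:.{ndigits}f}"
    return f"{med:.{ndigits}f} ± {iqr:.{ndigits}f}*"


def select_features(features, labels, families: dict[str, str]):
    """Run both selection stages on a feature table.

    Returns ``(records, stage2_names)`` where ``records`` is the full list of
    per-feature :class:`SelectionRecord` (flags set) and ``stage2_names`` the
    retained feature names in table order.
    """
    records = build_selection_records(features, labels, families)
    survivors = first_stage_select(records)
    final = second_stage_select(survivors)
    return records, [r.feature for r in final]
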