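"""End-to-end orchestration: cohort -> masks -> 80 features -> two-stage
selection -> three SVM reports (all selected features, morphological only,
spatial only), with CSV artifacts and full seed logging."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .classify import ClassifierReport, SplitSpec, evaluate, split_train_test, train_svm_cv
from .datatypes import ConfigurationError
from .features import FEATURE_FAMILIES, ExtractionConfig, extract_feature_table
from .selection import SelectionRecord, select_features, summarize_feature
from .synthetic import CohortConfig, generate_cohort, read_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "selection_report_frame", "classification_report_frame"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one input source: a synthetic ``cohort`` config, or a
    ``manifest`` path to an on-disk cohort (which must carry pixel spacing).
    """

    cohort: CohortConfig | None = None
    manifest: str | Path | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    positive_class: int = 0
    cv_folds: int = 5
    svm_kernel: str = "rbf"
    feature_override: list[str] | None = None
    seed: int = 0
    out_dir: str | Path | None = None


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline run."""

    features: pd.DataFrame
    records: list[SelectionRecord]
    selected: list[str]
    reports: dict[str, ClassifierReport]

    @property
    def selection_report(self) -> pd.DataFrame:
        return selection_report_frame(self.records)

    @property
    def classification_report(self) -> pd.DataFrame:
        return classification_report_frame(self.reports)


def selection_report_frame(records: list[SelectionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "Feature": r.feature,
            "Family": r.family,
            "p": r.p,
            "Fv": r.Fv,
            "F": r.F,
            "Stage1": r.stage1_kept,
            "Stage2": r.stage2_kept,
        }
        if r.summary is not None:
            row["Class0"] = summarize_feature(r.summary, 0)
            row["Class1"] = summarize_feature(r.summary, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def classification_report_frame(reports: dict[str, ClassifierReport]) -> pd.DataFrame:
    return pd.DataFrame([rep.as_row() for rep in reports.values()])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the seven analysis steps end to end.

    Returns the artifact bundle; when ``config.out_dir`` is set, also writes
    ``features.csv``, ``selection_report.csv``, ``classification_report.csv``
    and ``run_log.json`` there.  Any stage failure is re-raised with the
    stage name in context.
    """
    if (config.cohort is None) == (config.manifest is None):
        raise ConfigurationError("provide exactly one of cohort config or manifest path")
    if config.cohort is not None:
        lesions = generate_cohort(config.cohort)
    else:
        lesions = read_cohort(config.manifest)

    table = extract_feature_table(lesions, config.extraction)
    feature_cols = table.columns[2:]
    records, selected = select_features(table[feature_cols], table["label"].to_numpy(), FEATURE_FAMILIES)
    if config.feature_override is not None:
        logger.info("classifying a fixed feature list instead of the selected set")
        selected = list(config.feature_override)
    if not selected:
        raise RuntimeError("feature selection retained no features; classes may be indistinguishable")
    incomplete = [f for f in selected if table[f].isna().any()]
    if incomplete:
        logger.warning("excluding features with missing values from classification: %s", incomplete)
        selected = [f for f in selected if f not in incomplete]

    subsets = {
        "All features": selected,
        "Morphological features": [f for f in selected if FEATURE_FAMILIES[f] == "morphological"],
        "Spatial features": [f for f in selected if FEATURE_FAMILIES[f] == "spatial"],
    }
    split = SplitSpec(
        train_fraction=config.split.train_fraction,
        stratified=config.split.stratified,
        seed=config.seed,
        grouping=config.split.grouping,
    )
    train, test = split_train_test(table.reset_index(), split)
    reports: dict[str, ClassifierReport] = {}
    for name, feats in subsets.items():
        if not feats:
            logger.warning("subset %r is empty after selection; skipped", name)
            continue
        try:
            model, cv_summary = train_svm_cv(
                train, feats, folds=config.cv_folds, seed=config.seed, kernel=config.svm_kernel
            )
            reports[name] = evaluate(
                model, test, feats,
                positive_class=config.positive_class,
                feature_set=name,
                cv_config=cv_summary,
            )
        except Exception as exc:
            raise RuntimeError(f"classification stage failed for subset {name!r}: {exc}") from exc

    result = PipelineResult(features=table, records=records, selected=selected, reports=reports)
    if config.out_dir is not None:
        _write_artifacts(config, result)
    return result


def _write_artifacts(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv")
    result.selection_report.to_csv(out / "selection_report.csv", index=False)
    result.classification_report.to_csv(out / "classification_report.csv", index=False)
    log = {
        "seed": config.seed,
        "positive_class": config.positive_class,
        "cv_folds": config.cv_folds,
        "svm_kernel": config.svm_kernel,
        "split": asdict(config.split),
        "extraction": asdict(config.extraction),
        "cohort": asdict(config.cohort) if config.cohort is not None else None,
        "manifest": str(config.manifest) if config.manifest is not None else None,
        "selected_features": result.selected,
        "cv": {k: rep.cv_config for k, rep in result.reports.items()},
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    logger.info("artifacts written to %s", out)
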