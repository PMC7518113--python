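"""SVM classification of selected features: stratified 6:4 split, 5-fold
cross-validated hyperparameter search, and test-set performance reporting
(accuracy, sensitivity, specificity, Youden index, AUC).

The positive class defaults to class 0 (cholesterol polyp), configurable.
Sensitivity is the recall of the positive class, specificity that of the
other class, and AUC is computed from the SVM decision scores over all
thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "ClassifierReport", "split_train_test", "train_svm_cv", "evaluate"]


@dataclass
class SplitSpec:
    """Train/test split specification (train fraction 0.6, stratified)."""

    train_fraction: float = 0.6
    stratified: bool = True
    seed: int = 0
    grouping: str = "lesion"  # "lesion" | "patient"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.grouping not in ("lesion", "patient"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class ClassifierReport:
    """Test-set performance of one feature subset."""

    feature_set: str
    features: list[str]
    acc: float
    sen: float
    spc: float
    youden: float
    auc: float
    confusion: dict[str, int]
    cv_config: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "Features": self.feature_set,
            "Acc": self.acc,
            "Sen": self.sen,
            "Spc": self.spc,
            "Yi": self.youden,
            "AUC": self.auc,
        }


def split_train_test(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of a feature table (``label`` column).

    With ``grouping="patient"`` all lesions of one patient land on the same
    side: patients are split stratified by their (majority) label and lesions
    follow their patient.
    """
    labels = table["label"].to_numpy()
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 lesions per class to split")
    if spec.grouping == "patient":
        per_patient = table.groupby("patient_id")["label"].agg(lambda s: int(round(s.mean())))
        tr_pat, te_pat = train_test_split(
            per_patient.index.to_numpy(),
            train_size=spec.train_fraction,
            stratify=per_patient.to_numpy() if spec.stratified else None,
            random_state=spec.seed,
        )
        train = table[table["patient_id"].isin(tr_pat)]
        test = table[table["patient_id"].isin(te_pat)]
    else:
        train, test = train_test_split(
            table,
            train_size=spec.train_fraction,
            stratify=labels if spec.stratified else None,
            random_state=spec.seed,
        )
    for part, name in ((train, "train"), (test, "test")):
        if part["label"].nunique() < 2:
            raise ValueError(
                f"{name} set lost a class; use stratified splitting or another seed"
            )
    return train, test


_DEFAULT_GRID = {
    "svc__C": [0.1, 1.0, 10.0, 100.0],
    "svc__gamma": ["scale", 0.01, 0.1, 1.0],
}


def train_svm_cv(
    train: pd.DataFrame,
    features: list[str],
    folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
    grid: dict | None = None,
):
    """Fit an RBF SVM with standardized features and a cross-validated grid.

    Features are standardized with training-set statistics inside the model
    pipeline; hyperparameters are chosen by mean CV accuracy over seeded
    stratified folds (grid order resolves ties toward the simplest model,
    i.e. smallest C first); the winning model is refit on the full training
    set.  Constant features are dropped with a warning.

    Returns ``(model, cv_summary)``.
    """
    X = train[features]
    usable = [f for f in features if X[f].nunique() > 1]
    dropped = sorted(set(features) - set(usable))
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    if not usable:
        raise ValueError("no non-constant features to train on")
    y = train["label"].to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"cannot form {folds} stratified folds with class counts {counts.tolist()}"
        )
    pipe = Pipeline([("scaler", StandardScaler()), ("svc", SVC(kernel=kernel))])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid or _DEFAULT_GRID, scoring="accuracy", cv=cv)
    search.fit(train[usable], y)
    summary = {
        "features": usable,
        "best_params": search.best_params_,
        "cv_accuracy": float(search.best_score_),
        "folds": folds,
        "seed": seed,
    }
    logger.info("CV selected %s (mean accuracy %.3f)", search.best_params_, search.best_score_)
    return search.best_estimator_, summary


def _scores(model, X: pd.DataFrame) -> np.ndarray:
    return model.decision_function(X)


def evaluate(
    model,
    test: pd.DataFrame,
    features: list[str],
    positive_class: int = 0,
    feature_set: str = "features",
    cv_config: dict | None = None,
) -> ClassifierReport:
    """Test-set report: Acc/Sen/Spc at the SVM decision threshold, the Youden
    index Sen + Spc - 1, and the decision-score AUC."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    y = test["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("test set contains a single class; metrics undefined")
    feats = cv_config.get("features", features) if cv_config else features
    pred = model.predict(test[feats])
    scores = _scores(model, test[feats])
    pos = y == positive_class
    tp = int(((pred == positive_class) & pos).sum())
    fn = int(((pred != positive_class) & pos).sum())
    tn = int(((pred != positive_class) & ~pos).sum())
    fp = int(((pred == positive_class) & ~pos).sum())
    acc = (tp + tn) / len(y)
    sen = tp / (tp + fn)
    spc = tn / (tn + fp)
    # decision_function scores the class sklearn orders last; flip for class 0
    auc_scores = scores if positive_class == model.classes_[-1] else -scores
    auc = float(roc_auc_score(pos.astype(int), auc_scores))
    return ClassifierReport(
        feature_set=feature_set,
        features=list(feats),
        acc=float(acc),
        sen=float(sen),
        spc=float(spc),
        youden=float(sen + spc - 1.0),
        auc=auc,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        cv_config=cv_config or {},
    )
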