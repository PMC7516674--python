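"""Imbalance-aware boosted-tree prediction of cardiovascular outcomes.

Feature vectors combine 11 clinical covariates with 10 hypnopompic HRV
metrics (TP, LF, HF, HFnorm, SDNN, RMSSD, MSE1, MSE2, MSE10, MPE).  For
short-term outcome prediction the control group is under-sampled to the
case count (with KS/JSD similarity validation against the full control
group), followed by stratified 5-fold cross-validation of an XGBoost
classifier.  Performance is summarised by the six confusion-matrix
measures

    ACC = (TP + TN) / (TP + TN + FP + FN)
    TPR = TP / (TP + FN)          TNR = TN / (TN + FP)
    PPV = TP / (TP + FP)          F1  = 2 PPV TPR / (PPV + TPR)
    MCC = (TP TN - FP FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with ACC..F1 reported in percent, and feature importance by the number
of times each feature is used to split a tree node, normalised to sum 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .entropy import EntropyParams, entropy_profile
from .linear import linear_metrics
from .stats import similarity_report

logger = logging.getLogger(__name__)

__all__ = [
    "CLINICAL_FEATURES", "HRV_FEATURES", "ALL_FEATURES", "CATEGORY_CODES",
    "ConfusionMatrix", "PerformanceMetrics", "CVReport", "ExperimentConfig",
    "ExperimentResult", "assemble_features", "build_feature_table",
    "undersample_controls", "kfold_split", "train_classifier",
    "metrics_from_confusion", "average_metrics", "cv_report",
    "relative_change", "feature_importance", "run_experiment", "run_ablation",
]

CLINICAL_FEATURES = [
    "age", "gender", "bmi", "height", "waist_hip_ratio", "smoking_status",
    "lifetime_cigarettes", "diabetes", "hypertension", "ahi", "rdi",
]
HRV_FEATURES = ["tp", "lf", "hf", "hfnorm", "sdnn", "rmssd",
                "mse1", "mse2", "mse10", "mpe"]
ALL_FEATURES = CLINICAL_FEATURES + HRV_FEATURES

# declared encodings for categorical features
CATEGORY_CODES: dict[str, dict[str, int]] = {
    "gender": {"female": 0, "male": 1},
    "smoking_status": {"never": 0, "current": 1, "former": 2},
    "diabetes": {"no": 0, "yes": 1},
    "hypertension": {"no": 0, "yes": 1},
}


def _encode(name: str, value) -> float:
    if name in CATEGORY_CODES and isinstance(value, str):
        codes = CATEGORY_CODES[name]
        key = value.lower()
        if key not in codes:
            raise ValueError(f"unknown category {value!r} for feature {name!r}")
        return float(codes[key])
    return float(value)


def assemble_features(record: Mapping, feature_set: str = "full") -> pd.Series:
    """Build one subject's ordered, typed feature vector.

    ``feature_set`` is ``"full"`` (21 features) or ``"clinical_only"``
    (11 features).  Categorical string labels are encoded per
    :data:`CATEGORY_CODES`; unknown labels raise.  Missing (NaN) values
    are preserved; table-level assembly drops such subjects.
    """
    names = _feature_names(feature_set)
    return pd.Series({n: _encode(n, record[n]) for n in names}, name=record.get("subject_id"))


def _feature_names(feature_set: str) -> list[str]:
    if feature_set == "full":
        return ALL_FEATURES
    if feature_set == "clinical_only":
        return CLINICAL_FEATURES
    raise ValueError(f"feature_set must be 'full' or 'clinical_only', got {feature_set!r}")


def build_feature_table(cohort: pd.DataFrame, segment_length: float = 300.0,
                        entropy_params: EntropyParams | None = None,
                        drop_incomplete: bool = True) -> pd.DataFrame:
    """Compute the 21-feature table for a cohort with per-subject RR series.

    ``cohort`` must carry the clinical columns, the label column ``cvd``
    and an ``rr_series`` object column.  Subjects with any undefined
    feature (e.g. entropy with no template matches) are dropped and the
    count logged.
    """
    entropy_params = entropy_params or EntropyParams()
    rows = []
    for _, rec in cohort.iterrows():
        rr = rec["rr_series"]
        feats = dict(linear_metrics(rr, segment_length=segment_length))
        prof = entropy_profile(rr, entropy_params)
        feats["mse1"] = prof.mse[0]
        feats["mse2"] = prof.mse[1]
        feats["mse10"] = prof.mse[9]
        feats["mpe"] = prof.mpe
        for name in CLINICAL_FEATURES:
            feats[name] = _encode(name, rec[name])
        feats["cvd"] = int(rec["cvd"])
        feats["subject_id"] = rec.get("subject_id", "")
        rows.append(feats)
    table = pd.DataFrame(rows)[["subject_id", "cvd"] + ALL_FEATURES]
    if drop_incomplete:
        complete = table[ALL_FEATURES].notna().all(axis=1)
        dropped = int((~complete).sum())
        if dropped:
            logger.info("dropped %d subjects with undefined features", dropped)
        table = table.loc[complete].reset_index(drop=True)
    return table


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; Positive is the cardiovascular-event group."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class PerformanceMetrics:
    """ACC/TPR/TNR/PPV/F1 in percent; MCC unitless in [-1, 1]."""

    acc: float
    tpr: float
    tnr: float
    ppv: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return dict(acc=self.acc, tpr=self.tpr, tnr=self.tnr,
                    ppv=self.ppv, f1=self.f1, mcc=self.mcc)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; returning 0")
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> PerformanceMetrics:
    """The six performance measures of a binary confusion matrix.

    Zero-denominator cells return 0 with a warning; MCC with any zero
    marginal is 0.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    acc = (tp + tn) / cm.total
    tpr = _safe_ratio(tp, tp + fn, "TPR")
    tnr = _safe_ratio(tn, tn + fp, "TNR")
    ppv = _safe_ratio(tp, tp + fp, "PPV")
    f1 = _safe_ratio(2 * ppv * tpr, ppv + tpr, "F1")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return PerformanceMetrics(acc=acc * 100, tpr=tpr * 100, tnr=tnr * 100,
                              ppv=ppv * 100, f1=f1 * 100, mcc=float(mcc))


def average_metrics(metrics: Sequence[PerformanceMetrics]) -> PerformanceMetrics:
    """Field-wise arithmetic mean over folds."""
    if not metrics:
        raise ValueError("cannot average an empty metrics list")
    return PerformanceMetrics(**{
        k: float(np.mean([m.as_dict()[k] for m in metrics]))
        for k in ("acc", "tpr", "tnr", "ppv", "f1", "mcc")
    })


@dataclass
class CVReport:
    """Per-fold and averaged metrics of a k-fold cross-validation run."""

    folds: list[PerformanceMetrics]
    average: PerformanceMetrics
    k: int
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.folds] + [self.average.as_dict()]
        idx = [f"{i + 1}-fold" for i in range(len(self.folds))] + ["average"]
        return pd.DataFrame(rows, index=idx)


def cv_report(confusions: Sequence[ConfusionMatrix], seed: int | None = None) -> CVReport:
    """Per-fold metrics plus field-wise means from per-fold confusion matrices."""
    if len(confusions) < 2:
        raise ValueError("need at least 2 folds")
    folds = [metrics_from_confusion(cm) for cm in confusions]
    return CVReport(folds=folds, average=average_metrics(folds),
                    k=len(confusions), seed=seed)


def relative_change(new_value: float, reference_value: float) -> float:
    """Percent change of ``new_value`` relative to ``reference_value``."""
    if reference_value == 0:
        raise ValueError("reference value must be non-zero")
    return (new_value - reference_value) / reference_value * 100.0


def undersample_controls(table: pd.DataFrame, target_n: int, seed: int = 0,
                         label_col: str = "cvd",
                         variables: list[str] | None = None,
                         max_tries: int = 100,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Under-sample controls to ``target_n`` with similarity validation.

    Draws uniform random subsets of the control (label 0) rows until every
    continuous feature has a two-sample KS p > 0.05 against the full
    control group (at most ``max_tries`` draws; the best draw by minimum
    KS p is returned with a warning if none passes).  Returns the subset
    and its per-variable similarity report (KS D, KS p, JSD).
    """
    controls = table[table[label_col] == 0]
    if len(controls) < target_n:
        raise ValueError(
            f"control group ({len(controls)}) smaller than target_n ({target_n})"
        )
    if variables is None:
        variables = [c for c in ALL_FEATURES
                     if c in table.columns and c not in
                     ("gender", "smoking_status", "diabetes", "hypertension")]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max_tries):
        idx = rng.choice(controls.index.to_numpy(), size=target_n, replace=False)
        subset = controls.loc[np.sort(idx)]
        report = similarity_report(subset, controls, variables)
        min_p = report["ks_p"].min()
        if best is None or min_p > best[2]:
            best = (subset, report, min_p)
        if min_p > 0.05:
            return subset, report
    warnings.warn(
        f"no subset passed KS p > 0.05 on all variables in {max_tries} draws; "
        "returning the best draw"
    )
    return best[0], best[1]


def kfold_split(table: pd.DataFrame, k: int = 5, seed: int = 0,
                label_col: str = "cvd") -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition; fold sizes differ by at most one.

    Returns ``(train_idx, test_idx)`` positional index pairs; every row
    appears in exactly one test fold.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = table[label_col].to_numpy()
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


DEFAULT_XGB_PARAMS: dict = dict(
    max_depth=3, learning_rate=0.1, n_estimators=100,
    objective="binary:logistic", tree_method="hist", n_jobs=1,
)


def train_classifier(X: np.ndarray, y: np.ndarray,
                     params: dict | None = None, seed: int = 0) -> XGBClassifier:
    """Fit the gradient-boosted-tree classifier with declared hyperparameters."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    merged = {**DEFAULT_XGB_PARAMS, **(params or {})}
    model = XGBClassifier(**merged, random_state=seed)
    logger.debug("training XGBoost with params %s seed %d", merged, seed)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def feature_importance(model: XGBClassifier | Sequence[XGBClassifier],
                       feature_names: list[str]) -> pd.DataFrame:
    """Split-count feature importance, normalised to sum 1, sorted descending.

    A sequence of models (e.g. the k fold models of a CV run) pools split
    counts before normalising.
    """
    if isinstance(model, XGBClassifier):
        models = [model]
    elif isinstance(model, (list, tuple)):
        models = list(model)
    else:
        raise ValueError("model must be a fitted XGBClassifier or a sequence of them")
    counts = dict.fromkeys(feature_names, 0.0)
    for mdl in models:
        try:
            score = mdl.get_booster().get_score(importance_type="weight")
        except Exception as exc:
            raise ValueError("model must be a fitted XGBClassifier") from exc
        for key, val in score.items():
            # keys are f0, f1, ... in training-column order
            counts[feature_names[int(key[1:])]] += val
    total = sum(counts.values())
    rel = {k: (v / total if total else 0.0) for k, v in counts.items()}
    out = pd.DataFrame({
        "feature": list(counts), "split_count": list(counts.values()),
        "relative_importance": list(rel.values()),
    }).sort_values("relative_importance", ascending=False, ignore_index=True)
    return out


@dataclass
class ExperimentConfig:
    """Configuration of one cross-validated prediction experiment.

    ``mode`` is ``"long"`` (use the cohort as-is) or ``"short"``
    (under-sample controls to the case count first).  All randomness is
    governed by ``seed``, expanded deterministically into stage seeds for
    under-sampling, fold splitting, and the learner.
    """

    mode: str = "short"
    feature_set: str = "full"
    k: int = 5
    seed: int = 0
    xgb_params: dict = field(default_factory=dict)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3) % (2 ** 31)
        return {"undersample": int(state[0]), "fold": int(state[1]),
                "model": int(state[2])}


@dataclass
class ExperimentResult:
    report: CVReport
    importance: pd.DataFrame
    similarity: pd.DataFrame | None
    n_subjects: int
    config: ExperimentConfig


def run_experiment(features: pd.DataFrame, config: ExperimentConfig,
                   label_col: str = "cvd") -> ExperimentResult:
    """End-to-end CV experiment on a computed feature table.

    Short mode under-samples controls to the case count (similarity
    validated), then a stratified k-fold CV trains one boosted-tree model
    per fold; per-fold confusion matrices are aggregated into a
    :class:`CVReport` and split counts pooled over folds into an
    importance table.  Classification threshold is 0.5 on the predicted
    probability.
    """
    seeds = config.stage_seeds()
    names = _feature_names(config.feature_set)
    table = features
    similarity = None
    if config.mode == "short":
        n_cases = int((table[label_col] == 1).sum())
        subset, similarity = undersample_controls(
            table, n_cases, seed=seeds["undersample"], label_col=label_col)
        table = pd.concat([table[table[label_col] == 1], subset], ignore_index=True)
    elif config.mode != "long":
        raise ValueError(f"mode must be 'long' or 'short', got {config.mode!r}")

    X = table[names].to_numpy(dtype=float)
    y = table[label_col].to_numpy(dtype=int)
    confusions: list[ConfusionMatrix] = []
    models: list[XGBClassifier] = []
    for train_idx, test_idx in kfold_split(table, k=config.k, seed=seeds["fold"],
                                           label_col=label_col):
        model = train_classifier(X[train_idx], y[train_idx],
                                 params=config.xgb_params, seed=seeds["model"])
        prob = model.predict_proba(X[test_idx])[:, 1]
        confusions.append(ConfusionMatrix.from_predictions(y[test_idx], prob >= 0.5))
        models.append(model)
    report = cv_report(confusions, seed=config.seed)
    importance = feature_importance(models, names)
    return ExperimentResult(report=report, importance=importance,
                            similarity=similarity, n_subjects=len(table),
                            config=config)


def run_ablation(features: pd.DataFrame, config: ExperimentConfig,
                 label_col: str = "cvd") -> dict:
    """Run full vs clinical-only feature sets and report relative changes.

    Returns the two :class:`ExperimentResult` objects and the percent
    change of each averaged metric when HRV features are removed,
    relative to the full model.
    """
    full = run_experiment(features, ExperimentConfig(**{**config.__dict__,
                                                       "feature_set": "full"}),
                          label_col=label_col)
    clinical = run_experiment(features, ExperimentConfig(**{**config.__dict__,
                                                            "feature_set": "clinical_only"}),
                              label_col=label_col)
    deltas = {
        k: relative_change(clinical.report.average.as_dict()[k],
                           full.report.average.as_dict()[k])
        for k in ("acc", "tpr", "tnr", "ppv", "f1", "mcc")
        if full.report.average.as_dict()[k] != 0
    }
    return {"full": full, "clinical_only": clinical, "relative_changes": deltas}
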