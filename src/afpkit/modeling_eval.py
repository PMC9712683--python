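"""Model training and the evaluation protocol.

Three tree-ensemble classifiers are supported: random forest (RF),
extremely randomized trees (ERT) and leaf-wise gradient boosting (LXGB,
LightGBM). The boosting defaults follow the published configuration:
max depth 8, L1 penalty (alpha) 1, learning rate (eta) 0.1, L2 penalty
(lambda) 1, 500 estimators.

Evaluation follows the standard protocol for this benchmark: stratified
tenfold cross-validation with the confusion pooled over folds
(micro-average), threshold metrics at 0.5 (accuracy, sensitivity,
specificity, precision, recall, F-measure, MCC), and ROC / precision-recall
areas from the pooled out-of-fold scores. An imbalance ablation re-runs the
protocol on seeded subsamples at positive:negative ratios such as 1:1
(300:300), 1:2 (300:600) and 1:3 (300:900).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from lightgbm import LGBMClassifier

from .encoders import FeatureMatrix

MODEL_KINDS = ("RF", "ERT", "LXGB")

#: Subsample sizes of the imbalance ablation, positive:negative.
DEFAULT_ABLATION_RATIOS: dict[str, tuple[int, int]] = {
    "1:1": (300, 300),
    "1:2": (300, 600),
    "1:3": (300, 900),
}


@dataclass(frozen=True)
class ModelConfig:
    """Classifier kind plus the boosting hyperparameters.

    ``max_depth``, ``l1_penalty`` (alpha), ``learning_rate`` (eta) and
    ``l2_penalty`` (lambda) configure the LXGB booster; RF and ERT use only
    ``n_estimators`` and ``seed``.
    """

    kind: str = "LXGB"
    max_depth: int = 8
    l1_penalty: float = 1.0
    learning_rate: float = 0.1
    l2_penalty: float = 1.0
    n_estimators: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if self.n_estimators <= 0:
            raise ValueError("n_estimators must be positive")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")


def _build_estimator(config: ModelConfig):
    if config.kind == "RF":
        return RandomForestClassifier(
            n_estimators=config.n_estimators, random_state=config.seed, n_jobs=1
        )
    if config.kind == "ERT":
        return ExtraTreesClassifier(
            n_estimators=config.n_estimators, random_state=config.seed, n_jobs=1
        )
    return LGBMClassifier(
        max_depth=config.max_depth,
        reg_alpha=config.l1_penalty,
        learning_rate=config.learning_rate,
        reg_lambda=config.l2_penalty,
        n_estimators=config.n_estimators,
        random_state=config.seed,
        n_jobs=1,
        verbose=-1,
    )


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature names it was trained on."""

    config: ModelConfig
    feature_names: list[str]
    estimator: object
    training_fingerprint: str


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN of one binary experiment (positives = label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Threshold metrics, curve areas and the underlying confusion counts."""

    acc: float
    sn: float
    sp: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    confusion: ConfusionCounts
    auroc: float | None = None
    aupr: float | None = None
    fold_breakdown: list["EvalReport"] | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self, include_folds: bool = True) -> dict:
        out = {
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "metadata": dict(self.metadata),
        }
        if include_folds and self.fold_breakdown is not None:
            out["folds"] = [r.to_dict(include_folds=False) for r in self.fold_breakdown]
        return out


# ---------------------------------------------------------------------------
# Training and scoring

def train(matrix: FeatureMatrix, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit the configured classifier on a labeled feature matrix."""
    if matrix.labels is None:
        raise ValueError("training requires a labeled feature matrix")
    if len(np.unique(matrix.labels)) < 2:
        raise ValueError("training requires both classes to be present")
    if len(set(matrix.names)) != len(matrix.names):
        raise ValueError("duplicate feature names in training matrix")
    estimator = _build_estimator(config)
    X = matrix.values
    y = matrix.labels
    estimator.fit(pd.DataFrame(X, columns=matrix.names), y)
    fingerprint = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()[:16]
    return TrainedModel(
        config=config,
        feature_names=list(matrix.names),
        estimator=estimator,
        training_fingerprint=fingerprint,
    )


def predict_scores(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Probability-like score of the positive class, one per record.

    Columns are aligned by feature name (order-insensitive); a name-set
    mismatch is an error listing the difference. Thresholding at 0.5 gives
    hard labels.
    """
    if set(matrix.names) != set(model.feature_names):
        missing = sorted(set(model.feature_names) - set(matrix.names))
        extra = sorted(set(matrix.names) - set(model.feature_names))
        raise ValueError(
            f"feature-name mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
        )
    if matrix.n_records == 0:
        return np.empty(0)
    aligned = matrix.subset_columns(model.feature_names)
    proba = model.estimator.predict_proba(
        pd.DataFrame(aligned.values, columns=model.feature_names)
    )
    positive_col = list(model.estimator.classes_).index(1)
    return proba[:, positive_col]


# ---------------------------------------------------------------------------
# Metrics

def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold scores at ``threshold`` and tally the confusion counts."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    predicted = (scores >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((predicted == 1) & (labels == 1))),
        tn=int(np.sum((predicted == 0) & (labels == 0))),
        fp=int(np.sum((predicted == 1) & (labels == 0))),
        fn=int(np.sum((predicted == 0) & (labels == 1))),
    )


def compute_metrics(confusion: ConfusionCounts) -> EvalReport:
    """Threshold metrics from confusion counts.

    Acc = (TP+TN)/total; Sn = Recall = TP/(TP+FN); Sp = TN/(TN+FP);
    Precision = TP/(TP+FP); F-measure = harmonic mean of precision and
    recall; MCC = (TP*TN - FP*FN) / sqrt of the product of the four
    marginals, defined as 0 when any marginal is zero. Ratios with a zero
    denominator are reported as 0.
    """
    tp, tn, fp, fn = confusion.tp, confusion.tn, confusion.fp, confusion.fn
    total = confusion.total
    if total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion table")

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    acc = (tp + tn) / total
    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    recall = sn
    f_measure = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    marginals = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(marginals) if marginals else 0.0
    return EvalReport(
        acc=acc, sn=sn, sp=sp, precision=precision, recall=recall,
        f_measure=f_measure, mcc=mcc, confusion=confusion,
    )


@dataclass
class RocPrCurves:
    """ROC and precision-recall curve points with their areas."""

    fpr: np.ndarray
    tpr: np.ndarray
    pr_precision: np.ndarray
    pr_recall: np.ndarray
    auroc: float
    aupr: float


def roc_and_pr(scores: np.ndarray, labels: np.ndarray) -> RocPrCurves:
    """ROC (trapezoid area) and PR (step-wise area) from raw scores.

    Tied scores are grouped into single thresholds, so a constant score
    vector yields the chance diagonal and AuROC exactly 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/PR require both classes to be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return RocPrCurves(
        fpr=fpr,
        tpr=tpr,
        pr_precision=precision,
        pr_recall=recall,
        auroc=float(_trapezoid_auc(fpr, tpr)),
        aupr=float(average_precision_score(labels, scores)),
    )


# ---------------------------------------------------------------------------
# Cross-validation protocol

def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic fold assignment, one fold id per record.

    Stratified: per-fold class proportions are within one record of the
    global proportions. ``k`` equal to the number of records degenerates to
    leave-one-out.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k == n:
        return np.arange(n)
    counts = np.bincount(labels)
    smallest = counts[counts > 0].min()
    if smallest < k:
        raise ValueError(f"smallest class has {smallest} members, fewer than k={k} folds")
    assignment = np.empty(n, dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def cross_validate(
    matrix: FeatureMatrix,
    config: ModelConfig = ModelConfig(),
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold protocol with pooled confusion and pooled curves.

    Threshold metrics come from the confusion pooled over folds
    (micro-average); AuROC/AuPR come from the pooled out-of-fold scores.
    Per-fold reports are attached for folds containing both classes, and a
    macro-average of per-fold accuracies is recorded in the metadata.
    """
    if matrix.labels is None:
        raise ValueError("cross-validation requires labels")
    folds = stratified_kfold(matrix.labels, k=k, seed=seed)
    n = matrix.n_records
    oof_scores = np.empty(n)
    fold_reports: list[EvalReport] = []
    for fold in range(k):
        test_mask = folds == fold
        model = train(matrix.subset_rows(~test_mask), config)
        scores = predict_scores(model, matrix.subset_rows(test_mask))
        oof_scores[test_mask] = scores
        fold_labels = matrix.labels[test_mask]
        if len(np.unique(fold_labels)) == 2:
            report = compute_metrics(confusion_from_scores(scores, fold_labels))
            curves = roc_and_pr(scores, fold_labels)
            report.auroc, report.aupr = curves.auroc, curves.aupr
            fold_reports.append(report)
    pooled = compute_metrics(confusion_from_scores(oof_scores, matrix.labels))
    curves = roc_and_pr(oof_scores, matrix.labels)
    pooled.auroc, pooled.aupr = curves.auroc, curves.aupr
    pooled.fold_breakdown = fold_reports or None
    pooled.metadata = {
        "k": k,
        "seed": seed,
        "model": config.kind,
        "n_records": n,
        "macro_acc": float(np.mean([r.acc for r in fold_reports])) if fold_reports else None,
    }
    return pooled


def imbalance_ablation(
    matrix: FeatureMatrix,
    ratios: Mapping[str, tuple[int, int]] | None = None,
    config: ModelConfig = ModelConfig(),
    k: int = 10,
    seed: int = 0,
) -> dict[str, EvalReport]:
    """Re-run the CV protocol on seeded positive:negative subsamples.

    For each named ratio, the stated numbers of positives and negatives are
    drawn without replacement and :func:`cross_validate` is run on the
    draw. An insufficient pool is an error naming the shortfall.
    """
    if matrix.labels is None:
        raise ValueError("the imbalance ablation requires labels")
    ratios = dict(ratios) if ratios is not None else dict(DEFAULT_ABLATION_RATIOS)
    rng = np.random.default_rng(seed)
    pos_pool = np.flatnonzero(matrix.labels == 1)
    neg_pool = np.flatnonzero(matrix.labels == 0)
    reports: dict[str, EvalReport] = {}
    for name, (n_pos, n_neg) in ratios.items():
        if n_pos > len(pos_pool):
            raise ValueError(
                f"ratio {name}: requested {n_pos} positives but only "
                f"{len(pos_pool)} available"
            )
        if n_neg > len(neg_pool):
            raise ValueError(
                f"ratio {name}: requested {n_neg} negatives but only "
                f"{len(neg_pool)} available"
            )
        chosen = np.concatenate([
            rng.choice(pos_pool, size=n_pos, replace=False),
            rng.choice(neg_pool, size=n_neg, replace=False),
        ])
        report = cross_validate(matrix.subset_rows(np.sort(chosen)), config, k=k, seed=seed)
        report.metadata["ratio"] = name
        report.metadata["n_pos"], report.metadata["n_neg"] = n_pos, n_neg
        reports[name] = report
    return reports
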