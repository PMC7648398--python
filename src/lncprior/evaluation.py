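"""Repeated stratified cross-validation and the evaluation metric suite.

The labeled set is split into k stratified folds: each class is
shuffled independently and dealt round-robin, so per-fold class sizes
differ by at most one and every fold preserves the global
positive:negative ratio (1:2.6391 in the real study). Each fold is held
out in turn; count metrics (accuracy, sensitivity, specificity,
precision, MCC) use the fixed 0.5 probability threshold, ROC AUC uses
the trapezoidal rule over all thresholds, and PR AUC the step-wise
(right-continuous precision) rule. The random-guess PR baseline is the
positive prevalence, which the report carries alongside the AUCs.

Per repetition, metrics are averaged over the k folds; the report's
mean +/- sd is then taken across repetitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .classification import ModelConfig, predict_proba, train_model
from .io_formats import LabelSet

logger = logging.getLogger("lncprior")

METRIC_NAMES = ("roc_auc", "pr_auc", "accuracy", "sensitivity", "specificity",
                "precision", "mcc")


# ---------------------------------------------------------------------------
# Confusion counts and threshold metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass(frozen=True)
class MetricSet:
    """The five confusion-matrix metrics plus flags for degenerate denominators.

    A metric whose denominator is zero is NaN and flagged; MCC with a
    zero denominator is reported as 0 and flagged.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    flags: tuple = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "mcc": self.mcc,
        }


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision, MCC from raw counts.

    accuracy     = (TP + TN) / (TP + TN + FP + FN)
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (TN + FP)
    precision    = TP / (TP + FP)
    MCC          = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    flags = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return math.nan
        return num / den

    accuracy = (tp + tn) / counts.total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricSet(accuracy, sensitivity, specificity, precision, mcc, tuple(flags))


# ---------------------------------------------------------------------------
# Threshold-free curves
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (fpr, tpr) and its trapezoidal area.

    Thresholds sweep the unique scores; tied scores cross the threshold
    simultaneously. Equals the Mann-Whitney probability
    U / (n_pos * n_neg) with ties counted 1/2.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("ROC AUC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def pr_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and its step-wise area.

    The area uses the right-continuous (step) precision rule:
    sum over thresholds of (R_i - R_{i-1}) * P_i. For constant scores it
    equals the prevalence; the random-guess baseline is the prevalence,
    not 0.5.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise ValueError("PR AUC needs at least one positive")
    precision, recall, _ = precision_recall_curve(labels, scores)
    area = float(average_precision_score(labels, scores))
    return precision, recall, area


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------

def stratified_kfold_split(labels: LabelSet, k: int, seed: int) -> list[set]:
    """k disjoint gene-id subsets preserving the class ratio per fold.

    Each class is shuffled independently with the seed and dealt
    round-robin, so per-class fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[set] = [set() for _ in range(k)]
    for class_ids in (sorted(labels.positives), sorted(labels.negatives)):
        if len(class_ids) < k:
            raise ValueError(f"class of size {len(class_ids)} cannot fill {k} folds")
        order = rng.permutation(len(class_ids))
        for i, idx in enumerate(order):
            folds[i % k].add(class_ids[idx])
    return folds


# ---------------------------------------------------------------------------
# Repeated CV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Bundle of repeated-CV settings: model, folds, repetitions, seed."""

    model: ModelConfig = field(default_factory=ModelConfig)
    k: int = 10
    repetitions: int = 5
    seed: int = 0


@dataclass
class CVReport:
    """Per-repetition, per-fold metrics plus aggregate mean +/- sd.

    ``summary`` is a DataFrame indexed by metric with columns
    ``mean``/``sd`` (mean of fold-averaged values per repetition, then
    mean and sd across repetitions). ``prevalence`` is the positive
    fraction — the random-guess PR AUC baseline.
    """

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    fold_assignments: list
    seeds: list
    prevalence: float


def _evaluate_fold(model, features, labels, fold_ids, threshold=0.5) -> dict:
    fold_ids = sorted(fold_ids)
    probs = predict_proba(model, features.loc[fold_ids])
    y_true = labels.as_series(fold_ids).to_numpy()
    scores = probs.to_numpy()
    counts = confusion_from_predictions(y_true, scores >= threshold)
    metrics = compute_metrics(counts).as_dict()
    metrics["roc_auc"] = roc_auc(scores, y_true)[2]
    metrics["pr_auc"] = pr_auc(scores, y_true)[2]
    return metrics


def repeated_cv(
    features: pd.DataFrame,
    labels: LabelSet,
    config: CVConfig | ModelConfig,
    k: int = 10,
    repetitions: int = 5,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of one model config.

    Each repetition draws a fresh stratified split; for every fold the
    model is trained on the other k-1 folds (min-max scaling fit within
    the training rows) and evaluated on the held-out fold. Deterministic
    given the seed.
    """
    if isinstance(config, CVConfig):
        model_config, k, repetitions, seed = config.model, config.k, config.repetitions, config.seed
    else:
        model_config = config
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")

    split_seeds = [int(s) for s in
                   np.random.SeedSequence(seed).generate_state(repetitions) % (2**31)]
    rows = []
    assignments = []
    for rep, rep_seed in enumerate(split_seeds):
        folds = stratified_kfold_split(labels, k, rep_seed)
        assignments.append(folds)
        for fold_idx, held_out in enumerate(folds):
            train_labels = LabelSet(
                positives=labels.positives - held_out,
                negatives=labels.negatives - held_out,
            )
            fit_seed = (rep_seed + fold_idx) % (2**31)
            fold_model_config = ModelConfig(
                algorithm=model_config.algorithm,
                class_weight_neg_to_pos=model_config.class_weight_neg_to_pos,
                hyperparameters=model_config.hyperparameters,
                seed=fit_seed,
            )
            model = train_model(features, train_labels, fold_model_config)
            metrics = _evaluate_fold(model, features, labels, held_out)
            rows.append({"repetition": rep, "fold": fold_idx, **metrics})

    per_fold = pd.DataFrame(rows)
    per_rep = per_fold.groupby("repetition")[list(METRIC_NAMES)].mean()
    summary = pd.DataFrame(
        {"mean": per_rep.mean(axis=0), "sd": per_rep.std(axis=0, ddof=1) if repetitions > 1
         else pd.Series(0.0, index=per_rep.columns)}
    )
    prevalence = len(labels.positives) / len(labels.labeled)
    return CVReport(per_fold, summary, assignments, split_seeds, prevalence)
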