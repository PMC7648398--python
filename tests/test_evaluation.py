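"""Metric formulas, curve areas, stratified folds, repeated CV."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from lncprior.classification import ModelConfig
from lncprior.evaluation import (
    ConfusionCounts,
    CVConfig,
    compute_metrics,
    confusion_from_predictions,
    pr_auc,
    repeated_cv,
    roc_auc,
    stratified_kfold_split,
)
from lncprior.io_formats import LabelSet

# frozen by direct substitution into the five formulas for TP=50 TN=40 FP=10 FN=5
ORACLE_COUNTS = ConfusionCounts(TP=50, TN=40, FP=10, FN=5)
ORACLE_METRICS = {
    "accuracy": 0.8571428571428571,
    "sensitivity": 0.9090909090909091,
    "specificity": 0.8,
    "precision": 0.8333333333333334,
    "mcc": 0.7156264473321343,
}


def mann_whitney_auc(scores, labels):
    """Independent route: U statistic from midranks, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ranks = rankdata(scores)
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(10, 10, 0, 0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision, m.mcc) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_inverted_classifier(self):
        m = compute_metrics(ConfusionCounts(0, 0, 10, 10))
        assert m.accuracy == 0.0 and m.mcc == -1.0

    def test_formula_substitution_oracle(self):
        m = compute_metrics(ORACLE_COUNTS).as_dict()
        for name, expected in ORACLE_METRICS.items():
            assert m[name] == pytest.approx(expected, abs=1e-12)

    def test_zero_denominators_flagged(self):
        m = compute_metrics(ConfusionCounts(0, 5, 0, 0))
        assert math.isnan(m.sensitivity) and math.isnan(m.precision)
        assert m.mcc == 0.0
        assert set(m.flags) == {"sensitivity", "precision", "mcc"}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_metric_ranges(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12
        for value in (m.accuracy, m.sensitivity, m.specificity, m.precision):
            assert math.isnan(value) or 0.0 <= value <= 1.0

    def test_confusion_from_predictions_totals(self):
        counts = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (counts.TP, counts.FN, counts.TN, counts.FP) == (2, 1, 1, 1)


class TestRocAuc:
    def test_perfect_and_degenerate(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[2] == 1.0
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])[2] == 0.5

    def test_equals_mann_whitney_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(0, 1, n), 1)  # force ties
            assert roc_auc(scores, labels)[2] == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance_and_complement(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        auc = roc_auc(scores, labels)[2]
        assert roc_auc(np.exp(3 * scores), labels)[2] == pytest.approx(auc, abs=1e-12)
        assert roc_auc(-scores, labels)[2] == pytest.approx(1 - auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[2] == 1.0

    def test_hand_enumerated_four_threshold_case(self):
        # scores .9,.8,.7,.6 / labels 1,0,1,0: area = .5*1 + .5*(2/3)
        assert pr_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])[2] == pytest.approx(
            5 / 6, abs=1e-12)

    def test_constant_scores_give_prevalence(self):
        labels = [1] * 3 + [0] * 7
        assert pr_auc([0.4] * 10, labels)[2] == pytest.approx(0.3, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [0, 0])


class TestStratifiedFolds:
    def test_paper_scale_fold_sizes(self):
        labels = LabelSet(positives={f"p{i}" for i in range(604)},
                          negatives={f"n{i}" for i in range(1594)})
        folds = stratified_kfold_split(labels, k=10, seed=0)
        for fold in folds:
            n_pos = len(fold & labels.positives)
            n_neg = len(fold & labels.negatives)
            assert n_pos in (60, 61) and n_neg in (159, 160)
        union = set().union(*folds)
        assert union == labels.labeled
        assert sum(len(f) for f in folds) == len(union)  # pairwise disjoint

    def test_deterministic_given_seed(self):
        labels = LabelSet(positives={f"p{i}" for i in range(20)},
                          negatives={f"n{i}" for i in range(30)})
        assert stratified_kfold_split(labels, 5, 7) == stratified_kfold_split(labels, 5, 7)
        assert stratified_kfold_split(labels, 5, 7) != stratified_kfold_split(labels, 5, 8)

    def test_class_smaller_than_k_rejected(self):
        labels = LabelSet(positives={"a", "b"}, negatives={f"n{i}" for i in range(20)})
        with pytest.raises(ValueError):
            stratified_kfold_split(labels, 5, 0)


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(2)
    n = 120
    genes = [f"g{i}" for i in range(n)]
    signal = np.concatenate([rng.normal(1, 1, n // 3), rng.normal(0, 1, n - n // 3)])
    features = pd.DataFrame({"signal": signal, "noise": rng.normal(0, 1, n)},
                            index=genes)
    labels = LabelSet(positives=set(genes[: n // 3]), negatives=set(genes[n // 3:]))
    return features, labels


class TestRepeatedCV:
    def test_report_is_deterministic(self, small_problem):
        features, labels = small_problem
        cv = CVConfig(model=ModelConfig(algorithm="LR", seed=3), k=5,
                      repetitions=2, seed=3)
        a = repeated_cv(features, labels, cv)
        b = repeated_cv(features, labels, cv)
        assert a.per_fold.equals(b.per_fold)
        assert a.summary.equals(b.summary)

    def test_summary_aggregates_fold_means_and_reports_prevalence(self, small_problem):
        features, labels = small_problem
        cv = CVConfig(model=ModelConfig(algorithm="LR", seed=4), k=5,
                      repetitions=3, seed=4)
        report = repeated_cv(features, labels, cv)
        per_rep = report.per_fold.groupby("repetition")["roc_auc"].mean()
        assert report.summary.loc["roc_auc", "mean"] == pytest.approx(per_rep.mean())
        assert report.summary.loc["roc_auc", "sd"] == pytest.approx(per_rep.std(ddof=1))
        assert report.prevalence == pytest.approx(1 / 3)
        assert len(report.per_fold) == 15
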