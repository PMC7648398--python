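"""Transcript k-mer features and random-forest-based k-mer selection.

Each transcript is summarized by the frequencies of its overlapping
k-mers (final feature set: all 3- and 4-mers, 4^3 + 4^4 = 320 columns),
normalized by the full sequence length L — so the per-k frequencies of
an N-free sequence sum to (L - k + 1)/L exactly. Windows containing N
are skipped from the numerator while L keeps its full value.

Selection transfers the random forest's impurity-based importances: the
RF classifier is trained ``repetitions`` times (default 10) with
distinct sub-seeds on the min-max-scaled frequencies, per-feature
importances are averaged, and the top-m column subsets over a grid
(default 10..50 step 5) are compared by repeated-CV ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ModelConfig, make_class_weights, build_estimator
from .expression_features import minmax_normalize
from .io_formats import LabelSet, TranscriptSet

logger = logging.getLogger("lncprior")


@dataclass(frozen=True)
class KmerConfig:
    """k-mer lengths, selection grid and RF-averaging settings."""

    ks: tuple = (3, 4)
    top_m: int = 25
    rf_repetitions: int = 10
    selection_grid: tuple = tuple(range(10, 51, 5))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ks or any(k < 1 or k > 4 for k in self.ks):
            raise ValueError("ks must be a non-empty subset of {1,2,3,4}")
        total = sum(4**k for k in self.ks)
        if not 1 <= self.top_m <= total:
            raise ValueError(f"top_m must be in [1, {total}]")
        if self.rf_repetitions < 1:
            raise ValueError("rf_repetitions must be >= 1")


def kmer_names(ks) -> list[str]:
    """All k-mers for the given lengths: ks ascending, lexicographic within k."""
    names = []
    for k in sorted(set(ks)):
        names.extend("".join(p) for p in product("ACGT", repeat=k))
    return names


def count_kmer_frequencies(seqs: TranscriptSet, ks=(3, 4)) -> pd.DataFrame:
    """Length-normalized k-mer frequency table (genes x k-mers).

    frequency(w) = count of w as an overlapping substring / L, with L
    the full sequence length. Windows containing N contribute nothing
    to any numerator. Genes shorter than max(ks) are excluded with a
    warning.
    """
    ks = sorted(set(ks))
    names = kmer_names(ks)
    col_index = {w: j for j, w in enumerate(names)}
    max_k = max(ks)

    rows, kept_genes = [], []
    for gene, seq in seqs.items():
        if len(seq) < max_k:
            logger.warning("gene %s: sequence length %d < max k %d, excluded",
                           gene, len(seq), max_k)
            continue
        length = len(seq)
        counts = np.zeros(len(names))
        for k in ks:
            for i in range(length - k + 1):
                window = seq[i : i + k]
                j = col_index.get(window)
                if j is not None:  # windows containing N have no column
                    counts[j] += 1
        rows.append(counts / length)
        kept_genes.append(gene)
    if not rows:
        raise ValueError("no sequence long enough for k-mer counting")
    return pd.DataFrame(np.vstack(rows), index=kept_genes, columns=names)


def rank_kmers_by_rf_importance(
    table: pd.DataFrame,
    labels: LabelSet,
    repetitions: int = 10,
    seed: int = 0,
    model_config: ModelConfig | None = None,
) -> list[tuple[str, float]]:
    """Rank k-mers by impurity importance averaged over RF repetitions.

    The RF classifier (class-weighted, same configuration as the final
    model unless overridden) is fit ``repetitions`` times with distinct
    sub-seeds on the min-max-scaled labeled rows; per-feature mean
    decrease in impurity is averaged across fits and sorted descending,
    ties broken by lexicographic k-mer order. Deterministic given seed.
    """
    labeled = sorted(labels.positives) + sorted(labels.negatives)
    missing = [g for g in labeled if g not in table.index]
    if missing:
        raise ValueError(f"labeled genes missing from k-mer table: {missing[:10]}")
    # canonical column order: the forest's random feature draws depend on
    # column position, so sort by (k, name) to make the ranking invariant
    # to the caller's column permutation
    table = table[sorted(table.columns, key=lambda w: (len(w), w))]
    X, _ = minmax_normalize(table.loc[labeled])
    y = labels.as_series(labeled).to_numpy()
    if y.min() == y.max():
        raise ValueError("importance ranking needs both classes")
    w_neg, w_pos = make_class_weights(labels)

    sub_seeds = np.random.SeedSequence(seed).generate_state(repetitions) % (2**31)
    total = np.zeros(table.shape[1])
    base = model_config or ModelConfig(algorithm="RF")
    for sub_seed in sub_seeds:
        config = ModelConfig(algorithm="RF", hyperparameters=base.hyperparameters,
                             seed=int(sub_seed))
        rf = build_estimator(config, {0: w_neg, 1: w_pos})
        rf.fit(X.to_numpy(), y)
        total += rf.feature_importances_
    mean_importance = total / repetitions
    order = sorted(zip(table.columns, mean_importance), key=lambda t: (-t[1], t[0]))
    return [(kmer, float(imp)) for kmer, imp in order]


def select_top_kmers(
    ranked: list[tuple[str, float]],
    table: pd.DataFrame,
    labels: LabelSet,
    grid,
    cv_config,
) -> tuple[int, pd.DataFrame, pd.DataFrame]:
    """Pick the top-m cutoff by repeated-CV ROC AUC over a grid of m.

    Returns (chosen m, table restricted to the top-m columns, per-m AUC
    table). Ties go to the smaller m.
    """
    from .evaluation import repeated_cv  # local import to avoid a cycle

    grid = sorted(set(grid))
    if not grid:
        raise ValueError("empty selection grid")
    if grid[-1] > len(ranked):
        raise ValueError(f"grid max {grid[-1]} exceeds {len(ranked)} ranked k-mers")
    ranked_names = [kmer for kmer, _ in ranked]
    rows = []
    for m in grid:
        subset = table[ranked_names[:m]]
        report = repeated_cv(subset, labels, cv_config)
        auc = report.summary.loc["roc_auc", "mean"]
        rows.append({"m": m, "mean_roc_auc": auc})
        logger.info("top-%d k-mers: mean ROC AUC=%.4f", m, auc)
    auc_table = pd.DataFrame(rows).set_index("m")
    best = int(auc_table["mean_roc_auc"].idxmax())
    return best, table[ranked_names[:best]], auc_table


def welch_ttest_kmers(
    table: pd.DataFrame,
    labels: LabelSet,
    kmers=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Welch (unequal-variance) t-test per k-mer on raw frequencies.

    Uses Welch-Satterthwaite degrees of freedom; ``significant`` iff
    p < alpha with no multiplicity correction. A k-mer with zero
    variance in both classes is reported with t=0, p=1 and flagged.
    """
    if kmers is None:
        kmers = list(table.columns)
    pos = sorted(labels.positives & set(table.index))
    neg = sorted(labels.negatives & set(table.index))
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("both classes need >= 2 genes for the Welch t-test")
    rows = []
    for kmer in kmers:
        a = table.loc[pos, kmer].to_numpy()
        b = table.loc[neg, kmer].to_numpy()
        degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
        if degenerate:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"kmer": kmer, "t": float(t), "p": float(p),
                     "significant": bool(p < alpha), "zero_variance": degenerate})
    return pd.DataFrame(rows).set_index("kmer")
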