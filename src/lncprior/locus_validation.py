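"""Hypothetical-locus leave-one-out validation of the classifiers.

For each known risk gene, a hypothetical locus is formed from the N
genes centered on it (by start-coordinate order, strand-agnostic) on
the same chromosome (nominal N: 101, 201, 401). The model is retrained
with the target removed from the training labels, every locus member is
scored, and the target's percentile rank is

    percentile = L / N_actual * 100

where L counts members with probability strictly less than the
target's (ties do not count toward L, so 0 <= percentile < 100). For a
random ranker the expected percentile is (N_actual - 1) / (2 N_actual)
* 100, i.e. about 50; a useful model pushes known risk genes toward
100.

Near chromosome ends the window extends on the long side until N
members are collected or the chromosome is exhausted; N_actual records
the achieved size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import ModelConfig, predict_proba, train_model
from .io_formats import GeneRecord, LabelSet

logger = logging.getLogger("lncprior")


@dataclass
class HypotheticalLocus:
    target_gene: str
    members: list           # gene ids in coordinate order, includes target
    N_nominal: int
    probabilities: pd.Series | None = None

    @property
    def N_actual(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RankResult:
    target_gene: str
    N_nominal: int
    N_actual: int
    L: int
    percentile: float


def build_hypothetical_locus(
    target: str, annotation: list[GeneRecord], N: int
) -> HypotheticalLocus:
    """The N genes centered on ``target`` along its chromosome.

    Genes are ordered by (start, gene_id); (N-1)/2 are taken on each
    side, extending past a near chromosome end on the other side. If the
    chromosome holds fewer than N genes, all of them form the locus.
    """
    if N < 1 or N % 2 == 0:
        raise ValueError("N must be a positive odd integer")
    by_id = {rec.gene_id: rec for rec in annotation}
    if target not in by_id:
        raise ValueError(f"target gene {target!r} absent from annotation")
    chrom = by_id[target].chromosome
    chrom_genes = sorted(
        (rec for rec in annotation if rec.chromosome == chrom),
        key=lambda r: (r.start, r.gene_id),
    )
    ids = [rec.gene_id for rec in chrom_genes]
    idx = ids.index(target)
    total = len(ids)
    if total <= N:
        return HypotheticalLocus(target, ids, N)
    half = (N - 1) // 2
    left, right = idx - half, idx + half
    if left < 0:
        right += -left
        left = 0
    if right > total - 1:
        left -= right - (total - 1)
        right = total - 1
    return HypotheticalLocus(target, ids[left : right + 1], N)


def percentile_rank(locus: HypotheticalLocus) -> RankResult:
    """Percentile rank L / N_actual * 100 with a strictly-less count L."""
    if locus.probabilities is None:
        raise ValueError("locus has no probabilities assigned")
    probs = locus.probabilities
    missing = [m for m in locus.members if m not in probs.index]
    if missing:
        raise ValueError(f"members without probabilities: {missing[:5]}")
    target_p = probs[locus.target_gene]
    L = int(sum(probs[m] < target_p for m in locus.members))
    percentile = L / locus.N_actual * 100.0
    return RankResult(locus.target_gene, locus.N_nominal, locus.N_actual, L, percentile)


def leave_one_out_validate(
    features: pd.DataFrame,
    labels: LabelSet,
    annotation: list[GeneRecord],
    model_config: ModelConfig,
    N_list=(101, 201, 401),
    targets=None,
    max_targets: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out percentile ranks for every (risk gene, N).

    For each target risk gene the model is retrained once on the
    labeled set minus the target; all genes on the target's chromosome
    are scored with it (labeled members are scored like any candidate),
    and a RankResult is computed per N. Targets lacking feature rows are
    skipped with a warning; locus members lacking features are dropped
    from the locus (N_actual shrinks).

    Returns (per-target table, summary with the mean percentile per N).
    ``max_targets`` caps the number of targets for scaled-down runs.
    """
    if targets is None:
        targets = sorted(labels.positives)
    if max_targets is not None:
        targets = list(targets)[:max_targets]
    annotated = {rec.gene_id for rec in annotation}
    by_id = {rec.gene_id: rec for rec in annotation}

    rows = []
    for target in targets:
        if target not in features.index:
            logger.warning("target %s missing from features, skipped", target)
            continue
        if target not in annotated:
            raise ValueError(f"positive gene {target!r} absent from annotation")
        held_out_labels = LabelSet(
            positives=labels.positives - {target},
            negatives=labels.negatives,
        )
        model = train_model(features, held_out_labels, model_config)
        chrom = by_id[target].chromosome
        chrom_ids = [rec.gene_id for rec in annotation
                     if rec.chromosome == chrom and rec.gene_id in features.index]
        probs = predict_proba(model, features.loc[chrom_ids])
        for N in N_list:
            locus = build_hypothetical_locus(target, annotation, N)
            scored = [m for m in locus.members if m in probs.index]
            if len(scored) < len(locus.members):
                logger.warning("locus of %s: %d members lack features",
                               target, len(locus.members) - len(scored))
            locus = HypotheticalLocus(target, scored, N, probs)
            result = percentile_rank(locus)
            rows.append({
                "gene": target, "N": N, "N_actual": result.N_actual,
                "L": result.L, "percentile": result.percentile,
            })
    if not rows:
        raise ValueError("no validatable targets")
    table = pd.DataFrame(rows)
    summary = table.groupby("N")["percentile"].agg(["mean", "std", "count"])
    return table, summary


def percentile_histogram(percentiles, bins: int = 20) -> tuple[np.ndarray, float]:
    """Equal-width histogram of percentile ranks on [0, 100).

    Returns (per-bin counts, uniform reference count = n / bins) — the
    reference is the flat line a random ranker would produce.
    """
    percentiles = np.asarray(list(percentiles), dtype=float)
    if percentiles.size == 0:
        raise ValueError("no percentile ranks to histogram")
    counts, _ = np.histogram(percentiles, bins=bins, range=(0.0, 100.0))
    return counts, percentiles.size / bins
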