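"""Candidate lncRNA prioritization: consensus calls and annotations.

The three trained models (LR, SVM, RF) each emit a probability per
unlabeled candidate lncRNA. A candidate is called by a model when its
probability reaches the threshold (default 0.5); the consensus flag
requires all three. Candidates are ranked by the mean of the three
probabilities (ties broken by gene id).

Two annotations contextualize candidates against the known risk genes:
co-expression partners (protein-coding genes whose log2 expression
profile has Pearson correlation above a threshold, default 0.95, with
the candidate's) and genomic overlap (``same_locus`` when the
candidate's interval shares >= 1 base with a risk gene's on the same
chromosome; ``antisense`` when additionally on the opposite strand).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classification import TrainedModel, predict_proba
from .io_formats import ExpressionMatrix, GeneRecord

logger = logging.getLogger("lncprior")


def prioritize_candidates(
    models: dict[str, TrainedModel],
    candidate_features: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score candidates with all models; flag calls and the consensus.

    Returns a DataFrame indexed by gene id with per-model probabilities
    (``prob_<name>``), ``called_by`` (comma-joined model names whose
    probability >= threshold), ``n_called``, ``consensus_all`` (called
    by every model) and ``mean_prob``; sorted by mean_prob descending,
    ties by gene id.
    """
    if not models:
        raise ValueError("no models supplied")
    probs = pd.DataFrame(index=candidate_features.index)
    for name in sorted(models):
        probs[f"prob_{name}"] = predict_proba(models[name], candidate_features)
    prob_cols = list(probs.columns)
    called = probs[prob_cols] >= threshold
    result = probs.copy()
    result["called_by"] = called.apply(
        lambda row: ",".join(c.removeprefix("prob_") for c in prob_cols if row[c]), axis=1
    )
    result["n_called"] = called.sum(axis=1).astype(int)
    result["consensus_all"] = result["n_called"] == len(models)
    result["mean_prob"] = probs[prob_cols].mean(axis=1)
    result = result.reset_index(names="gene_id")
    result = result.sort_values(["mean_prob", "gene_id"], ascending=[False, True])
    return result.set_index("gene_id")


def format_fraction_percent(numerator: int, denominator: int) -> str:
    """Report-style 'x (y%) of z' percentage at 2 decimal places.

    420 of 1,124 formats as 37.37%; 1,124 of 9,463 as 11.88%.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return f"{100.0 * numerator / denominator:.2f}%"


def coexpression_partners(
    candidates,
    expression: ExpressionMatrix,
    annotation: list[GeneRecord],
    pcc_threshold: float = 0.95,
) -> dict[str, list[tuple[str, float]]]:
    """Protein-coding partners with Pearson correlation above threshold.

    Correlations are computed on the log2-scale expression vectors.
    Zero-variance vectors make the correlation undefined; such pairs
    are skipped with a logged flag.
    """
    if expression.transform_state != "log2":
        raise ValueError("co-expression uses the log2-transformed matrix")
    coding = [rec.gene_id for rec in annotation
              if rec.biotype == "protein_coding" and rec.gene_id in expression.data.index]
    candidates = [g for g in candidates if g in expression.data.index]

    data = expression.data
    cand_values = data.loc[candidates].to_numpy()
    coding_values = data.loc[coding].to_numpy()

    def standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = values - values.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        ok = sd > 0
        centered[ok] /= sd[ok, None]
        return centered, ok

    cand_std, cand_ok = standardize(cand_values)
    coding_std, coding_ok = standardize(coding_values)
    if (~cand_ok).any() or (~coding_ok).any():
        logger.warning("co-expression: %d zero-variance vectors skipped",
                       int((~cand_ok).sum() + (~coding_ok).sum()))
    n_samples = data.shape[1]
    pcc = cand_std @ coding_std.T / n_samples

    out: dict[str, list[tuple[str, float]]] = {}
    for i, cand in enumerate(candidates):
        partners = []
        if cand_ok[i]:
            for j, coding_gene in enumerate(coding):
                if coding_ok[j] and coding_gene != cand and pcc[i, j] > pcc_threshold:
                    partners.append((coding_gene, float(pcc[i, j])))
        partners.sort(key=lambda t: (-t[1], t[0]))
        out[cand] = partners
    return out


def annotate_genomic_overlap(
    candidates,
    risk_genes,
    annotation: list[GeneRecord],
) -> pd.Series:
    """Per-candidate overlap class: none / same_locus / antisense.

    ``same_locus``: the candidate's interval intersects a risk gene's
    (1-based inclusive, >= 1 shared base, same chromosome).
    ``antisense``: some intersecting risk gene lies on the opposite
    strand (takes precedence over same_locus).
    """
    by_id = {rec.gene_id: rec for rec in annotation}
    for gene in list(candidates) + list(risk_genes):
        if gene not in by_id:
            raise ValueError(f"gene {gene!r} absent from annotation")
    risk_by_chrom: dict[str, list[GeneRecord]] = {}
    for gene in risk_genes:
        rec = by_id[gene]
        risk_by_chrom.setdefault(rec.chromosome, []).append(rec)

    labels = {}
    for gene in candidates:
        rec = by_id[gene]
        label = "none"
        for risk in risk_by_chrom.get(rec.chromosome, ()):
            if rec.overlaps(risk):
                if risk.strand != rec.strand:
                    label = "antisense"
                    break
                label = "same_locus"
        labels[gene] = label
    return pd.Series(labels, name="overlap_annotation")
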