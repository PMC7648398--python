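"""Synthetic benchmark data with planted, recoverable signal.

The generator emulates the four inputs the pipeline consumes in real
mode — a BrainSpan-style RPKM matrix, transcript FASTA, a gene
annotation table, and positive/negative label lists — at a reduced,
desk-friendly scale that preserves the study's class imbalance
(positive:negative ~ 1:2.64).

Signal is planted in two independent channels so every downstream stage
has something to find:

* expression: positive genes (and a designated subset of unlabeled
  lncRNAs) have their class mean shifted by ``expr_effect`` on the
  log2(RPKM+1) scale in ``n_signal_samples`` of the columns;
* sequence: a list of informative 3-/4-mers is inserted into
  positive-class transcripts at ``kmer_enrichment`` times the uniform
  background rate.

The annotation lays genes out along synthetic chromosomes with
non-overlapping intervals, except for a configurable fraction of
unlabeled lncRNAs that are placed antisense-overlapping a positive
gene — the configuration the genomic-overlap annotator must detect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneRecord,
    LabelSet,
    TranscriptSet,
    write_annotation,
    write_expression_table,
    write_fasta,
    write_labels,
)

logger = logging.getLogger("lncprior")

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real study's shape at reduced scale: 150
    positive and 396 negative genes (1:2.64), 60 expression samples of
    which 20 carry the class signal, and five informative 4-mers planted
    at 5x the uniform background rate. ``realistic_scale()`` returns the
    full-size 604/1594/524 preset.
    """

    n_pos: int = 150
    n_neg: int = 396
    n_unlabeled: int = 100
    n_signal_unlabeled: int = 10
    n_samples: int = 60
    n_signal_samples: int = 20
    mu_base: float = 3.0
    expr_effect: float = 2.0
    expr_noise_sd: float = 0.5
    informative_kmers: tuple = ("CGCG", "TATA", "GGCC", "AATT", "CACA")
    kmer_enrichment: float = 5.0
    seq_len_range: tuple = (500, 3000)
    genes_per_chromosome: int = 50
    antisense_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_samples, self.genes_per_chromosome) < 1:
            raise ConfigError("counts must be >= 1")
        if self.n_unlabeled < 0 or self.n_signal_unlabeled < 0:
            raise ConfigError("unlabeled counts must be >= 0")
        if self.n_signal_unlabeled > self.n_unlabeled:
            raise ConfigError("n_signal_unlabeled > n_unlabeled")
        if self.n_signal_samples > self.n_samples:
            raise ConfigError("n_signal_samples > n_samples")
        if self.expr_noise_sd <= 0:
            raise ConfigError("expr_noise_sd must be > 0")
        if not 0 <= self.antisense_fraction <= 1:
            raise ConfigError("antisense_fraction must be in [0, 1]")
        for kmer in self.informative_kmers:
            if len(kmer) not in (3, 4) or set(kmer) - set("ACGT"):
                raise ConfigError(f"informative k-mer {kmer!r} must be 3/4-mer over ACGT")
        if self.kmer_enrichment > 0 and not self.informative_kmers:
            raise ConfigError("kmer_enrichment > 0 requires informative_kmers")
        lo, hi = self.seq_len_range
        if lo < 4 or hi < lo:
            raise ConfigError("seq_len_range must satisfy 4 <= min <= max")

    @classmethod
    def realistic_scale(cls, **overrides) -> "SimulationConfig":
        """Full-size preset: 604 positives, 1594 negatives, 524 samples."""
        params = dict(n_pos=604, n_neg=1594, n_unlabeled=500, n_samples=524,
                      n_signal_samples=150, genes_per_chromosome=120)
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Per-artifact child generator derived from the single global seed."""
    digest = hashlib.sha256(stream.encode()).digest()
    stream_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream_key]))


def gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    """Deterministic id lists (positives, negatives, unlabeled lncRNAs)."""
    pos = [f"pos_{i:04d}" for i in range(config.n_pos)]
    neg = [f"neg_{i:04d}" for i in range(config.n_neg)]
    lnc = [f"lnc_{i:04d}" for i in range(config.n_unlabeled)]
    return pos, neg, lnc


def signal_unlabeled_ids(config: SimulationConfig) -> list[str]:
    """Unlabeled lncRNAs that carry the full planted positive signal."""
    _, _, lnc = gene_ids(config)
    return lnc[: config.n_signal_unlabeled]


def make_labels(config: SimulationConfig) -> LabelSet:
    pos, neg, _ = gene_ids(config)
    return LabelSet(positives=frozenset(pos), negatives=frozenset(neg))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, LabelSet]:
    """RPKM-scale matrix whose log2(RPKM+1) values are Gaussian per class.

    The first ``n_signal_samples`` columns are the signal columns: there
    the positive class (and signal-carrying unlabeled lncRNAs) has mean
    ``mu_base + expr_effect`` instead of ``mu_base``. Values are mapped
    back to the RPKM scale via ``2**x - 1`` and clipped at 0.
    """
    rng = _rng_for(config, "expression")
    pos, neg, lnc = gene_ids(config)
    all_genes = pos + neg + lnc
    positive_like = set(pos) | set(signal_unlabeled_ids(config))

    n_genes = len(all_genes)
    log2 = rng.normal(config.mu_base, config.expr_noise_sd, size=(n_genes, config.n_samples))
    pos_rows = np.array([g in positive_like for g in all_genes])
    log2[np.ix_(pos_rows, np.arange(config.n_signal_samples))] += config.expr_effect
    rpkm = np.clip(np.exp2(log2) - 1.0, 0.0, None)

    samples = [f"sample_{j:03d}" for j in range(config.n_samples)]
    df = pd.DataFrame(rpkm, index=all_genes, columns=samples)
    return ExpressionMatrix(df, transform_state="rpkm"), make_labels(config)


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

def _plant_kmer(seq: np.ndarray, kmer: str, n_insert: int, rng: np.random.Generator) -> None:
    """Overwrite ``n_insert`` uniformly chosen windows with ``kmer`` in place."""
    k = len(kmer)
    kmer_codes = np.array([("ACGT").index(c) for c in kmer], dtype=np.int8)
    max_start = len(seq) - k
    if max_start < 0 or n_insert <= 0:
        return
    starts = rng.integers(0, max_start + 1, size=n_insert)
    for s in starts:
        seq[s : s + k] = kmer_codes


def simulate_transcripts(config: SimulationConfig, labels: LabelSet) -> TranscriptSet:
    """Uniform-random transcripts with informative k-mers planted in positives.

    Each sequence is i.i.d. uniform over {A,C,G,T}; its length is
    uniform over ``seq_len_range``. For each informative k-mer ``w`` of
    length k, positive-class sequences receive a Poisson number of extra
    insertions with mean ``(kmer_enrichment - 1) * (L - k + 1) / 4**k``
    (the excess over the uniform background count), each overwriting a
    uniformly chosen window, so sequence length is unchanged.
    Enrichment <= 1 plants nothing (null case).
    """
    rng = _rng_for(config, "transcripts")
    pos, neg, lnc = gene_ids(config)
    positive_like = set(labels.positives) | set(signal_unlabeled_ids(config))
    lo, hi = config.seq_len_range

    out: TranscriptSet = {}
    for gene in pos + neg + lnc:
        length = int(rng.integers(lo, hi + 1))
        codes = rng.integers(0, 4, size=length, dtype=np.int8)
        if gene in positive_like and config.kmer_enrichment > 1:
            for kmer in config.informative_kmers:
                k = len(kmer)
                background = (length - k + 1) / 4**k
                mean_extra = (config.kmer_enrichment - 1.0) * background
                n_insert = int(rng.poisson(mean_extra))
                _plant_kmer(codes, kmer, n_insert, rng)
        out[gene] = "".join(_BASES[codes])
    return out


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig, labels: LabelSet) -> list[GeneRecord]:
    """Ordered gene layout on synthetic chromosomes with planted antisense pairs.

    All genes are shuffled and chunked into chromosomes of
    ``genes_per_chromosome`` records each (last may hold fewer). Within
    a chromosome, genes occupy non-overlapping intervals separated by
    fixed gaps — except ``round(antisense_fraction * n_unlabeled)``
    unlabeled lncRNAs, each placed strictly inside a distinct positive
    gene's interval on the opposite strand.
    """
    rng = _rng_for(config, "annotation")
    pos, neg, lnc = gene_ids(config)
    all_genes = pos + neg + lnc
    order = list(np.array(all_genes)[rng.permutation(len(all_genes))])

    per_chrom = config.genes_per_chromosome
    chunks = [order[i : i + per_chrom] for i in range(0, len(order), per_chrom)]

    n_antisense = round(config.antisense_fraction * config.n_unlabeled)
    # pair lncRNAs with distinct positive genes on the same chromosome
    pairs: dict[str, str] = {}
    pos_set, lnc_set = set(pos), set(lnc)
    for chunk in chunks:
        if len(pairs) >= n_antisense:
            break
        chrom_pos = [g for g in chunk if g in pos_set]
        chrom_lnc = [g for g in chunk if g in lnc_set]
        for lnc_gene, partner in zip(chrom_lnc, chrom_pos):
            if len(pairs) >= n_antisense:
                break
            pairs[lnc_gene] = partner
    if len(pairs) < n_antisense:
        raise ConfigError(
            f"could only form {len(pairs)} of {n_antisense} antisense pairs; "
            "increase n_pos or genes_per_chromosome"
        )

    records: list[GeneRecord] = []
    gene_len, gap = 2000, 1000
    placed: dict[str, GeneRecord] = {}
    for c, chunk in enumerate(chunks):
        chrom = f"chr{c + 1}"
        cursor = 1
        for gene in chunk:
            if gene in pairs:
                continue  # placed inside its partner afterwards
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(gene_len, 2 * gene_len))
            biotype = "lncRNA" if gene in lnc_set else "protein_coding"
            rec = GeneRecord(gene, gene.upper(), chrom, cursor, cursor + length - 1,
                             strand, biotype)
            records.append(rec)
            placed[gene] = rec
            cursor += length + gap
        for gene in chunk:
            if gene not in pairs:
                continue
            partner = placed[pairs[gene]]
            strand = "-" if partner.strand == "+" else "+"
            rec = GeneRecord(gene, gene.upper(), chrom,
                             partner.start + 50, partner.end - 50, strand, "lncRNA")
            records.append(rec)
            placed[gene] = rec
    return sorted(records, key=lambda r: (r.chromosome, r.start, r.gene_id))


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    expression: ExpressionMatrix
    transcripts: TranscriptSet
    annotation: list = field(default_factory=list)
    labels: LabelSet | None = None

    @property
    def unlabeled_ids(self) -> list[str]:
        _, _, lnc = gene_ids(self.config)
        return lnc


def simulate_dataset(config: SimulationConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full bundle; optionally write it in io_formats dialects.

    When ``out_dir`` is given, writes expression.tsv, transcripts.fa,
    annotation.tsv, positives.txt, negatives.txt and a manifest.json
    recording the config and seed. Re-running with the manifest's config
    reproduces the files byte-identically.
    """
    expression, labels = simulate_expression(config)
    transcripts = simulate_transcripts(config, labels)
    annotation = simulate_annotation(config, labels)
    bundle = SyntheticDataset(config, expression, transcripts, annotation, labels)
    if out_dir is not None:
        write_dataset(bundle, out_dir)
    return bundle


def write_dataset(bundle: SyntheticDataset, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(bundle.expression, out / "expression.tsv")
    write_fasta(bundle.transcripts, out / "transcripts.fa")
    write_annotation(bundle.annotation, out / "annotation.tsv")
    write_labels(bundle.labels, out / "positives.txt", out / "negatives.txt")
    manifest = {
        "config": bundle.config.to_dict(),
        "seed": bundle.config.seed,
        "n_genes": len(bundle.expression.gene_ids),
        "signal_unlabeled": signal_unlabeled_ids(bundle.config),
        "files": ["expression.tsv", "transcripts.fa", "annotation.tsv",
                  "positives.txt", "negatives.txt"],
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    logger.info("wrote synthetic dataset (%d genes) to %s", manifest["n_genes"], out)
    return manifest
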