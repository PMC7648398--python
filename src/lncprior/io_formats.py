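"""Readers and writers for the file formats the pipeline touches.

Four kinds of artifact move through the pipeline: transcript FASTA, a
gene x sample expression TSV (BrainSpan-style RPKM), a gene annotation
table (GTF gene lines or a 7-column TSV), and plain-text label lists.
All coordinates follow the GTF convention: 1-based, inclusive on both
ends. The k-mer alphabet downstream is {A,C,G,T}; RNA FASTA (U) is
accepted and mapped to DNA on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lncprior")

VALID_BASES = frozenset("ACGTN")
KNOWN_BIOTYPES = frozenset({"protein_coding", "lncRNA", "other"})


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene from the annotation: locus coordinates plus biotype.

    Coordinates are 1-based inclusive (GTF convention); ``strand`` is
    '+' or '-'.
    """

    gene_id: str
    gene_symbol: str
    chromosome: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.biotype not in KNOWN_BIOTYPES:
            raise ParseError(f"gene {self.gene_id}: invalid biotype {self.biotype!r}")

    def overlaps(self, other: "GeneRecord") -> bool:
        """True iff the two intervals share >= 1 base on the same chromosome."""
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with its transform state.

    ``transform_state`` is one of ``rpkm`` (raw), ``log2`` (log2(RPKM+1))
    or ``minmax`` (per-feature scaled to [0,1]).
    """

    data: pd.DataFrame
    transform_state: str = "rpkm"

    def __post_init__(self) -> None:
        if self.transform_state not in ("rpkm", "log2", "minmax"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        if self.data.isna().any().any():
            raise ParseError("expression matrix contains missing values")
        values = self.data.to_numpy()
        if self.transform_state in ("rpkm", "log2") and (values < 0).any():
            raise ValueError(f"negative values in a {self.transform_state} matrix")
        if self.transform_state == "minmax" and (
            (values < 0).any() or (values > 1).any()
        ):
            raise ValueError("minmax matrix has values outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


# A TranscriptSet is simply gene_id -> DNA sequence over {A,C,G,T,N}.
TranscriptSet = dict


@dataclass(frozen=True)
class LabelSet:
    """Positive (risk gene) and negative (non-risk disease gene) id sets."""

    positives: frozenset = field(default_factory=frozenset)
    negatives: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        if not self.positives or not self.negatives:
            raise ValueError("both label classes must be non-empty")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {sorted(overlap)[:5]}")

    @property
    def labeled(self) -> frozenset:
        return self.positives | self.negatives

    def as_series(self, gene_ids: Iterable[str] | None = None) -> pd.Series:
        """Binary label vector (1 = positive) over ``gene_ids`` or all labeled genes."""
        if gene_ids is None:
            gene_ids = sorted(self.positives) + sorted(self.negatives)
        return pd.Series(
            [1 if g in self.positives else 0 for g in gene_ids],
            index=list(gene_ids),
            dtype=int,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _gene_id_from_header(header: str) -> tuple[str, str]:
    """Return (gene_id, transcript_id) from a FASTA id token.

    GENCODE-style pipe headers (``ENST...|ENSG...|...``) map the second
    field to the gene; otherwise the token itself is both ids.
    """
    token = header.split()[0]
    if "|" in token:
        fields = token.split("|")
        if len(fields) >= 2 and fields[1]:
            return fields[1], fields[0]
    return token, token


def read_fasta(
    path: str | Path,
    selection: str = "longest",
    invalid_chars: str = "error",
) -> TranscriptSet:
    """Read a transcript FASTA into a gene_id -> sequence mapping.

    Sequences are upper-cased and U is mapped to T. Characters outside
    {A,C,G,T,N} raise a :class:`ParseError` (``invalid_chars='error'``,
    default) or are masked to N (``'mask'``). When several records map
    to one gene, the longest transcript is kept; ties go to the
    lexicographically smallest transcript id, then input order.
    """
    if selection != "longest":
        raise ValueError(f"unknown transcript selection rule {selection!r}")
    if invalid_chars not in ("error", "mask"):
        raise ValueError("invalid_chars must be 'error' or 'mask'")

    best: dict[str, tuple[int, str, int, str]] = {}
    for order, record in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise ParseError(f"empty sequence for FASTA record {record.id!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            if invalid_chars == "error":
                raise ParseError(
                    f"record {record.id!r} has characters outside ACGTN: {sorted(bad)}"
                )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        gene_id, transcript_id = _gene_id_from_header(record.id)
        # keep the longest; tie -> smallest transcript id -> first seen
        key = (-len(seq), transcript_id, order)
        if gene_id not in best or key < best[gene_id][:3]:
            best[gene_id] = (key[0], key[1], key[2], seq)
    if not best:
        raise ParseError(f"no FASTA records found in {path}")
    return {g: rec[3] for g, rec in best.items()}


def write_fasta(transcripts: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in transcripts.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV (header = sample ids, first column = gene ids).

    Values must be dense and numeric; any non-numeric cell is an error
    naming its row and column. Duplicate gene ids are rejected. The
    result is tagged ``rpkm``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene ids in expression table: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        gene, sample = df.index[rows[0]], df.columns[cols[0]]
        raise ParseError(
            f"non-numeric expression value at gene {gene!r}, sample {sample!r}: "
            f"{df.iloc[rows[0], cols[0]]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric.astype(float), transform_state="rpkm")


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    # default float repr round-trips exactly, so write(read(f)) is lossless
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Annotation (GTF gene lines or 7-column TSV)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["gene_id", "gene_symbol", "chromosome", "start", "end", "strand", "biotype"]


def _normalize_biotype(raw: str, gene_id: str) -> str:
    if raw in ("protein_coding", "lncRNA"):
        return raw
    if raw != "other":
        logger.warning("gene %s: unknown biotype %r mapped to 'other'", gene_id, raw)
    return "other"


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _records_from_gtf(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            if fields[2] != "gene":
                continue
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: GTF gene line without gene_id")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", "other"))
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    gene_symbol=attrs.get("gene_name", gene_id),
                    chromosome=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                    biotype=_normalize_biotype(biotype, gene_id),
                )
            )
    return records


def _records_from_tsv(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 columns "
                    f"({', '.join(_TSV_COLUMNS)}), got {len(fields)}"
                )
            if lineno == 1 and fields[0] == "gene_id":
                continue  # optional header
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            records.append(
                GeneRecord(
                    gene_id=fields[0],
                    gene_symbol=fields[1],
                    chromosome=fields[2],
                    start=start,
                    end=end,
                    strand=fields[5],
                    biotype=_normalize_biotype(fields[6], fields[0]),
                )
            )
    return records


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read gene annotation from GTF (gene lines) or the 7-column TSV dialect.

    Output is sorted by (chromosome, start, gene_id). Duplicate gene ids
    are rejected; unknown biotypes are mapped to 'other' with a warning.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    is_gtf = first.startswith("#") or len(first.rstrip("\n").split("\t")) == 9
    records = _records_from_gtf(path) if is_gtf else _records_from_tsv(path)
    if not records:
        raise ParseError(f"no gene records found in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ParseError(f"duplicate gene_id in annotation: {rec.gene_id!r}")
        seen.add(rec.gene_id)
    return sorted(records, key=lambda r: (r.chromosome, r.start, r.gene_id))


def write_annotation(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_TSV_COLUMNS) + "\n")
        for rec in records:
            handle.write(
                f"{rec.gene_id}\t{rec.gene_symbol}\t{rec.chromosome}\t"
                f"{rec.start}\t{rec.end}\t{rec.strand}\t{rec.biotype}\n"
            )


# ---------------------------------------------------------------------------
# Label lists
# ---------------------------------------------------------------------------

def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as handle:
        ids = [line.strip() for line in handle if line.strip()]
    if not ids:
        raise ParseError(f"empty label list: {path}")
    return ids


def read_labels(positives_path: str | Path, negatives_path: str | Path) -> LabelSet:
    return LabelSet(
        positives=frozenset(_read_id_list(positives_path)),
        negatives=frozenset(_read_id_list(negatives_path)),
    )


def write_labels(labels: LabelSet, positives_path: str | Path, negatives_path: str | Path) -> None:
    for ids, path in ((labels.positives, positives_path), (labels.negatives, negatives_path)):
        with open(path, "w") as handle:
            for gene_id in sorted(ids):
                handle.write(gene_id + "\n")


def align_datasets(
    expression: ExpressionMatrix,
    transcripts: TranscriptSet,
    labels: LabelSet | None = None,
) -> tuple[ExpressionMatrix, TranscriptSet, LabelSet | None]:
    """Restrict all inputs to genes present in both expression and FASTA.

    Genes lacking either data source are dropped (and counted in a log
    message) rather than zero-filled.
    """
    common = [g for g in expression.gene_ids if g in transcripts]
    dropped = len(expression.gene_ids) - len(common) + len(
        set(transcripts) - set(expression.gene_ids)
    )
    if dropped:
        logger.info("align_datasets: dropped %d genes lacking expression or sequence", dropped)
    expr = ExpressionMatrix(expression.data.loc[common], expression.transform_state)
    seqs = {g: transcripts[g] for g in common}
    if labels is not None:
        kept = set(common)
        labels = LabelSet(labels.positives & kept, labels.negatives & kept)
    return expr, seqs, labels
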