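"""Readers and writers for the external formats the pipeline touches.

Conventions used throughout the package:

* coordinates are 0-based, half-open;
* sequences may contain ``A C G T U N`` (case-insensitive); ``U`` is kept as
  read, and :func:`dna` normalizes to DNA space for matching;
* tables are TSV with a single ``#``-prefixed header line, UTF-8, ``.``
  decimal — chosen so result files diff bit-exactly between runs.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from Bio import SeqIO, motifs

import numpy as np

VALID_SEQ_CHARS = frozenset("ACGTUN")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

PWM_ROWS = "ACGT"


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class FormatError(ValueError):
    """Raised for an unknown format tag (usage error)."""


def dna(seq: str) -> str:
    """Uppercase and map U->T: the internal DNA-space form used for matching."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U treated as T)."""
    return dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence, optionally with Sanger-scale per-base qualities."""

    id: str
    seq: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record has an empty id")
        if not self.seq:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq.upper()) - VALID_SEQ_CHARS
        if bad:
            raise ParseError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.seq)}"
            )


def _fasta_header_line(path: str, record_index: int) -> int:
    """Line number (1-based) of the ``record_index``-th FASTA header."""
    seen = -1
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                seen += 1
                if seen == record_index:
                    return lineno
    return 0


def read_sequences(path: str | os.PathLike, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA or FASTQ into validated :class:`SequenceRecord` objects.

    Order is preserved; ``U`` and ``T`` are both accepted and kept as read.
    An empty file yields an empty list.  Malformed records raise
    :class:`ParseError` naming the offending line.
    """
    if format not in ("fasta", "fastq"):
        raise FormatError(f"unknown sequence format {format!r}")
    records: list[SequenceRecord] = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), format)):
            quality = None
            if format == "fastq":
                quality = list(rec.letter_annotations["phred_quality"])
            try:
                records.append(SequenceRecord(rec.id, str(rec.seq), quality))
            except ParseError as exc:
                lineno = (
                    _fasta_header_line(str(path), idx)
                    if format == "fasta"
                    else idx * 4 + 1
                )
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    except ParseError:
        raise
    except ValueError as exc:  # biopython-level format violations
        raise ParseError(f"{path}: malformed {format}: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [40] * len(rec.seq)
            qline = "".join(chr(q + 33) for q in qual)
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")


@dataclass
class PositionWeightMatrix:
    """A 4xL position matrix (rows A, C, G, T), counts or frequencies."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray
    tf_family: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ParseError(f"motif {self.motif_id}: matrix must be 4xL")
        if self.width < 4:
            raise ParseError(f"motif {self.motif_id}: width {self.width} < 4")
        if (self.matrix < 0).any():
            raise ParseError(f"motif {self.motif_id}: negative matrix cell")
        sums = self.matrix.sum(axis=0)
        if self.looks_like_counts() and not np.allclose(sums, sums[0], atol=0.5):
            raise ParseError(
                f"motif {self.motif_id}: count columns sum unequally ({sums})"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def looks_like_counts(self) -> bool:
        return bool(np.allclose(self.matrix, np.round(self.matrix)) and self.matrix.max() > 1)

    def normalized(self, pseudocount: float = 0.0) -> "PositionWeightMatrix":
        """Column-stochastic copy (each column sums to 1) after adding
        ``pseudocount`` to every cell."""
        m = self.matrix + pseudocount
        m = m / m.sum(axis=0, keepdims=True)
        return PositionWeightMatrix(self.motif_id, self.tf_name, m, self.tf_family)

    def consensus(self) -> str:
        return "".join(PWM_ROWS[i] for i in self.matrix.argmax(axis=0))


def read_pwms(
    path: str | os.PathLike, family_table: str | os.PathLike | None = None
) -> list[PositionWeightMatrix]:
    """Read JASPAR-style PFM text into validated matrices.

    ``family_table`` is an optional TSV (``motif_id``, ``tf_family``) mapping
    each matrix to its TF family.
    """
    families: dict[str, str] = {}
    if family_table is not None:
        df = read_tsv(family_table)
        families = dict(zip(df["motif_id"], df["tf_family"]))
    out: list[PositionWeightMatrix] = []
    with open(path) as handle:
        try:
            parsed = motifs.parse(handle, "jaspar")
        except Exception as exc:  # biopython raises bare Exception on bad rows
            raise ParseError(f"{path}: malformed JASPAR file: {exc}") from exc
        for m in parsed:
            widths = {len(m.counts[b]) for b in PWM_ROWS}
            if len(widths) != 1:
                raise ParseError(
                    f"{path}: motif {m.matrix_id}: unequal row widths {sorted(widths)}"
                )
            matrix = np.array([list(m.counts[b]) for b in PWM_ROWS], dtype=float)
            motif_id = getattr(m, "matrix_id", None) or m.name
            out.append(
                PositionWeightMatrix(
                    motif_id=motif_id,
                    tf_name=m.name or motif_id,
                    matrix=matrix,
                    tf_family=families.get(motif_id, ""),
                )
            )
    return out


def write_pwms(pwms: list[PositionWeightMatrix], path: str | os.PathLike) -> None:
    """Write matrices in JASPAR PFM text (``>id name`` then A/C/G/T rows)."""
    with open(path, "w") as handle:
        for pwm in pwms:
            handle.write(f">{pwm.motif_id} {pwm.tf_name}\n")
            for row, base in zip(pwm.matrix, PWM_ROWS):
                cells = " ".join(
                    str(int(v)) if float(v).is_integer() else repr(float(v))
                    for v in row
                )
                handle.write(f"{base}  [ {cells} ]\n")


# ---------------------------------------------------------------------------
# TSV tables

def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as the canonical TSV dialect ('#'-prefixed header)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(handle, sep="\t", header=False, index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read the canonical TSV dialect written by :func:`write_tsv`."""
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}: missing '#'-prefixed header line")
        names = header[1:].rstrip("\n").split("\t")
        body = handle.read()
    if not body:
        return pd.DataFrame(columns=names)
    return pd.read_csv(io.StringIO(body), sep="\t", names=names)


@dataclass
class TssRecord:
    """BED-like TSS row: 0-based position of the pri-miRNA start."""

    chrom: str
    tss_pos: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(f"TSS {self.gene_id}: bad strand {self.strand!r}")
        if self.tss_pos < 0:
            raise ParseError(f"TSS {self.gene_id}: negative position")


def read_tss_table(path: str | os.PathLike) -> list[TssRecord]:
    df = read_tsv(path)
    return [
        TssRecord(str(r.chrom), int(r.tss_pos), str(r.strand), str(r.gene_id))
        for r in df.itertuples()
    ]


def write_tss_table(records: list[TssRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.tss_pos, r.strand, r.gene_id) for r in records],
        columns=["chrom", "tss_pos", "strand", "gene_id"],
    )
    write_tsv(df, path)


# ---------------------------------------------------------------------------
# Network interchange

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def write_network(graph: nx.DiGraph, path: str | os.PathLike, format: str = "sif") -> None:
    """Write a directed regulatory graph; edge ``kind`` is preserved.

    Duplicate edges cannot exist in a DiGraph, so output edge sets are
    deduplicated by construction.
    """
    if format not in NETWORK_FORMATS:
        raise FormatError(f"unknown network format {format!r}")
    if format == "graphml":
        nx.write_graphml(graph, str(path))
        return
    with open(path, "w") as handle:
        if format == "tsv":
            handle.write("#source\tkind\ttarget\n")
        for u, v, data in sorted(graph.edges(data=True)):
            kind = data.get("kind", "edge")
            handle.write(f"{u}\t{kind}\t{v}\n")
        if format == "sif":
            for node in sorted(graph.nodes):
                if graph.degree(node) == 0:
                    handle.write(f"{node}\n")


def read_network(path: str | os.PathLike, format: str = "sif") -> nx.DiGraph:
    if format not in NETWORK_FORMATS:
        raise FormatError(f"unknown network format {format!r}")
    if format == "graphml":
        g = nx.read_graphml(str(path))
        return nx.DiGraph(g)
    graph = nx.DiGraph()
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                graph.add_node(parts[0])
            elif len(parts) == 3:
                graph.add_edge(parts[0], parts[2], kind=parts[1])
            else:
                raise ParseError(f"{path}: bad network line {line!r}")
    return graph
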