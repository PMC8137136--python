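"""Genome sequences, TSS annotation, and the coordinate contract.

All coordinates exposed by this package are 1-based inclusive, matching the
GFF-style convention biologists expect. The TSS of a gene is the single
first-transcribed base; a gene on the minus strand transcribes toward
decreasing coordinates. Sequences are uppercase DNA over {A, C, G, T, N}.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_TSS_COLUMNS = ["gene_id", "seq_id", "strand", "tss"]


class FastaFormatError(ValueError):
    """Raised for empty, malformed, or duplicate-id FASTA input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


class TssTableError(ValueError):
    """Raised for malformed or out-of-bounds TSS annotation rows."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome/contig sequence, the protospacer search space."""

    seq_id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise FastaFormatError(f"sequence {self.seq_id!r} is empty")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise AlphabetError(
                f"sequence {self.seq_id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> str:
        """Return bases at 1-based inclusive [start, end] on the plus strand."""
        if not (1 <= start <= end <= len(self.bases)):
            raise IndexError(
                f"slice {start}..{end} out of bounds for {self.seq_id!r} "
                f"(length {len(self.bases)})"
            )
        return self.bases[start - 1 : end]


@dataclass(frozen=True)
class TssRecord:
    """A gene's strand and 1-based transcription start coordinate."""

    gene_id: str
    seq_id: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TssTableError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 1:
            raise TssTableError(
                f"gene {self.gene_id!r}: tss must be >= 1 (1-based), got {self.tss}"
            )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N.

    Raises AlphabetError for characters outside {A,C,G,T,N}.
    """
    bad = set(seq) - VALID_BASES
    if bad:
        raise AlphabetError(f"invalid characters in sequence: {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence objects.

    Bases are uppercased on read and record order is preserved. Raises
    FastaFormatError on an empty file or duplicate record ids, and
    AlphabetError on characters outside {A,C,G,T,N}.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(seq_id=rec.id, bases=str(rec.seq).upper()))
    return out


def write_fasta(genome: Iterable[GenomeSequence], path: str | Path) -> None:
    """Write sequences as FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for gs in genome:
            fh.write(f">{gs.seq_id}\n")
            for i in range(0, len(gs.bases), 60):
                fh.write(gs.bases[i : i + 60] + "\n")


def genome_by_id(genome: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    return {gs.seq_id: gs for gs in genome}


def read_tss_table(
    path: str | Path, genome: Sequence[GenomeSequence]
) -> list[TssRecord]:
    """Read a 4-column TSS annotation TSV validated against the genome.

    Expected header: gene_id, seq_id, strand, tss (tab-delimited, UTF-8;
    lines starting with '#' are skipped). tss is 1-based and must lie within
    the referenced sequence. One TSS per gene_id; duplicates are rejected.
    """
    lengths = {gs.seq_id: len(gs) for gs in genome}
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _TSS_COLUMNS if c not in df.columns]
    if missing:
        raise TssTableError(f"{path}: missing columns {missing}")

    records: list[TssRecord] = []
    seen_genes: set[str] = set()
    for row in df.itertuples(index=False):
        gene_id = str(row.gene_id)
        seq_id = str(row.seq_id)
        strand = str(row.strand)
        if gene_id in seen_genes:
            raise TssTableError(f"duplicate gene_id {gene_id!r}: one TSS per gene")
        seen_genes.add(gene_id)
        if seq_id not in lengths:
            raise TssTableError(
                f"gene {gene_id!r} references unknown sequence {seq_id!r}"
            )
        try:
            tss = int(row.tss)
        except (TypeError, ValueError) as exc:
            raise TssTableError(f"gene {gene_id!r}: non-integer tss {row.tss!r}") from exc
        rec = TssRecord(gene_id=gene_id, seq_id=seq_id, strand=strand, tss=tss)
        if rec.tss > lengths[seq_id]:
            raise TssTableError(
                f"gene {gene_id!r}: tss {rec.tss} beyond end of {seq_id!r} "
                f"(length {lengths[seq_id]})"
            )
        records.append(rec)
    return records


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    """Write TSS records as the 4-column TSV this package reads."""
    buf = io.StringIO()
    buf.write("\t".join(_TSS_COLUMNS) + "\n")
    for rec in records:
        buf.write(f"{rec.gene_id}\t{rec.seq_id}\t{rec.strand}\t{rec.tss}\n")
    Path(path).write_text(buf.getvalue())
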