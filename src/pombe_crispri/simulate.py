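"""Seeded synthetic fixtures: genomes with planted guide sites, and qPCR tables.

Two generators make every other module testable without any download:

* a genome simulator that lays down i.i.d. background sequence at a chosen GC
  fraction (default 0.36, fission-yeast-like) and plants 20-mer+NGG
  protospacer sites at prescribed TSS-relative offsets and orientations,
  with genome-wide uniqueness enforced by rejection sampling;
* a qPCR simulator that inverts the delta-Cq model: given true relative mRNA
  levels it emits reference and target Cq values (plus optional Gaussian Cq
  noise) such that the quantification chain recovers the levels exactly at
  zero noise.

Both are bit-reproducible for a fixed seed. An optional AT-rich promoter
mode lowers GC upstream of each TSS, mimicking the paucity of NGG PAMs in
fission-yeast promoter regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pombe_crispri.genome import GenomeSequence, TssRecord, reverse_complement
from pombe_crispri.repression import QPCR_CSV_COLUMNS, QpcrMeasurement

_BASES = np.array(list("ACGT"))
SPACER_LENGTH = 20
PROMOTER_SPAN = 200  # bp upstream of a TSS regenerated in AT-rich mode
MAX_PLANT_RETRIES = 1000


class PlacementError(RuntimeError):
    """A plant cannot be realized (bounds, overlap, or uniqueness retries)."""


@dataclass(frozen=True)
class PlantSpec:
    """A requested protospacer+PAM site relative to a gene's TSS."""

    gene_id: str
    orientation: str  # forward | reverse
    offset: float  # half-integer bp from TSS to protospacer center
    unique: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if (2 * self.offset) != int(2 * self.offset) or float(self.offset) == int(self.offset):
            raise ValueError(
                f"offset must be a half-integer (center of a 20-bp window), got {self.offset}"
            )


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _plant_coords(gene: TssRecord, spec: PlantSpec) -> tuple[str, int, int]:
    """Resolve (candidate strand, plus-strand start, end) for a plant."""
    center = gene.tss + spec.offset if gene.strand == "+" else gene.tss - spec.offset
    start = center - (SPACER_LENGTH - 1) / 2
    if start != int(start):
        raise PlacementError(f"offset {spec.offset} does not yield integer coordinates")
    start = int(start)
    end = start + SPACER_LENGTH - 1
    if spec.orientation == "forward":
        strand = gene.strand
    else:
        strand = "-" if gene.strand == "+" else "+"
    return strand, start, end


def _count_occurrences(chroms: dict[str, np.ndarray], spacer: str) -> int:
    """Exact substring occurrences of a 20-mer on both strands, genome-wide."""
    rc = reverse_complement(spacer)
    total = 0
    for arr in chroms.values():
        s = "".join(arr)
        for query in (spacer, rc):
            pos = s.find(query)
            while pos != -1:
                total += 1
                pos = s.find(query, pos + 1)
    return total


def generate_genome_fixture(
    n_chrom: int,
    length: int,
    genes: Sequence[TssRecord],
    plants: Sequence[PlantSpec],
    seed: int,
    gc: float = 0.36,
    promoter_gc: float | None = None,
) -> tuple[list[GenomeSequence], list[TssRecord], pd.DataFrame]:
    """Simulate a genome with planted protospacer+PAM sites.

    Chromosomes are named chr1..chrN, each `length` bp of i.i.d. background
    at GC fraction `gc`. If promoter_gc is given, the 200 bp upstream of each
    TSS (in transcription direction) is regenerated at that GC fraction.
    Each plant writes a random 20-mer plus an NGG PAM at the coordinates
    realizing its requested orientation and TSS offset; for unique plants the
    20-mer is rejection-sampled (up to 1000 tries) until it occurs exactly
    once in the whole genome. Plants must not overlap each other
    (PAM included) or fall outside their chromosome.

    Returns the genome, the (validated) TSS records, and a manifest frame
    with the expected guide attributes of every plant.
    """
    if length < 500:
        raise ValueError("chromosome length must be >= 500 bp")
    rng = np.random.default_rng(seed)
    chrom_ids = [f"chr{i + 1}" for i in range(n_chrom)]
    chroms: dict[str, np.ndarray] = {
        cid: _draw_bases(rng, length, gc) for cid in chrom_ids
    }

    gene_map: dict[str, TssRecord] = {}
    for gene in genes:
        if gene.seq_id not in chroms:
            raise ValueError(f"gene {gene.gene_id!r} references unknown {gene.seq_id!r}")
        if gene.tss > length:
            raise ValueError(f"gene {gene.gene_id!r}: tss {gene.tss} beyond chromosome end")
        if gene.gene_id in gene_map:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        gene_map[gene.gene_id] = gene

    if promoter_gc is not None:
        for gene in genes:
            if gene.strand == "+":
                lo, hi = max(1, gene.tss - PROMOTER_SPAN), gene.tss - 1
            else:
                lo, hi = gene.tss + 1, min(length, gene.tss + PROMOTER_SPAN)
            if lo <= hi:
                chroms[gene.seq_id][lo - 1 : hi] = _draw_bases(rng, hi - lo + 1, promoter_gc)

    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in chrom_ids}
    rows = []
    for spec in plants:
        if spec.gene_id not in gene_map:
            raise ValueError(f"plant references unknown gene {spec.gene_id!r}")
        gene = gene_map[spec.gene_id]
        strand, start, end = _plant_coords(gene, spec)
        # footprint includes the 3-bp PAM on whichever side it falls
        foot_lo = start - 3 if strand == "-" else start
        foot_hi = end + 3 if strand == "+" else end
        if foot_lo < 1 or foot_hi > length:
            raise PlacementError(
                f"plant for {spec.gene_id!r} at offset {spec.offset} falls outside "
                f"{gene.seq_id!r} ({foot_lo}..{foot_hi} vs 1..{length})"
            )
        for lo, hi in occupied[gene.seq_id]:
            if foot_lo <= hi and lo <= foot_hi:
                raise PlacementError(
                    f"plant for {spec.gene_id!r} overlaps a previous plant on {gene.seq_id!r}"
                )

        arr = chroms[gene.seq_id]
        pam_n = str(rng.choice(_BASES))
        pam = pam_n + "GG"
        spacer = None
        for _ in range(MAX_PLANT_RETRIES):
            trial = "".join(rng.choice(_BASES, size=SPACER_LENGTH))
            if strand == "+":
                arr[start - 1 : end] = list(trial)
                arr[end : end + 3] = list(pam)
            else:
                arr[start - 1 : end] = list(reverse_complement(trial))
                arr[start - 4 : start - 1] = list(reverse_complement(pam))
            if not spec.unique or _count_occurrences(chroms, trial) == 1:
                spacer = trial
                break
        if spacer is None:
            raise PlacementError(
                f"could not realize a unique plant for {spec.gene_id!r} after "
                f"{MAX_PLANT_RETRIES} tries"
            )
        occupied[gene.seq_id].append((foot_lo, foot_hi))
        rows.append(
            {
                "gene_id": spec.gene_id,
                "seq_id": gene.seq_id,
                "strand": strand,
                "start": start,
                "end": end,
                "protospacer": spacer,
                "pam": pam,
                "orientation": spec.orientation,
                "offset": float(spec.offset),
                "unique": spec.unique,
            }
        )

    genome = [GenomeSequence(cid, "".join(chroms[cid])) for cid in chrom_ids]
    manifest = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "seq_id", "strand", "start", "end", "protospacer",
            "pam", "orientation", "offset", "unique",
        ],
    )
    return genome, list(genes), manifest


def generate_qpcr_fixture(
    true_levels: dict[str, float],
    n_replicates: int = 3,
    cq_noise_sd: float = 0.0,
    efficiency: float = 2.0,
    seed: int = 0,
    reference_cq: float = 15.0,
    control_scale: float = 0.05,
) -> list[QpcrMeasurement]:
    """Simulate qPCR Cq measurements encoding known relative mRNA levels.

    For guide g with true level L_g, each replicate draws a reference Cq near
    `reference_cq` and a target Cq of reference_cq - log_E(L_g * control_scale),
    each perturbed by independent Gaussian noise of SD `cq_noise_sd` cycles.
    control_scale is the target:reference abundance ratio at the unrepressed
    baseline; it cancels in the normalization chain, so at zero noise
    summarize_repression recovers the planted levels exactly (relative to the
    guide whose level is 1.0).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if cq_noise_sd < 0:
        raise ValueError("cq_noise_sd must be >= 0")
    for gid, level in true_levels.items():
        if level <= 0:
            raise ValueError(f"true level for {gid!r} must be > 0, got {level}")
    rng = np.random.default_rng(seed)
    log_e = float(np.log(efficiency))
    out: list[QpcrMeasurement] = []
    for gid in sorted(true_levels):
        base_target = reference_cq - np.log(true_levels[gid] * control_scale) / log_e
        for rep in range(1, n_replicates + 1):
            ref_cq = reference_cq + rng.normal(0.0, cq_noise_sd) if cq_noise_sd else reference_cq
            tgt_cq = base_target + rng.normal(0.0, cq_noise_sd) if cq_noise_sd else base_target
            out.append(
                QpcrMeasurement(gid, gid, "reference", rep, float(ref_cq))
            )
            out.append(
                QpcrMeasurement(gid, gid, "target", rep, float(tgt_cq))
            )
    return out


def write_qpcr_csv(measurements: Iterable[QpcrMeasurement], path: str | Path) -> None:
    df = pd.DataFrame([m.__dict__ for m in measurements])[QPCR_CSV_COLUMNS]
    df.to_csv(path, index=False)


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)
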