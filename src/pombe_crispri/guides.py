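"""Enumeration, classification, and efficacy scoring of CRISPRi guide candidates.

A candidate is a 20-nt protospacer with an immediately 3'-adjacent NGG PAM on
either genomic strand. Relative to a target gene it has an *orientation*
(forward = the protospacer reads as the non-template strand, i.e. it lies on
the gene's own strand; the sgRNA then base-pairs with the template strand)
and an *offset*: the signed distance from the TSS to the protospacer center,
positive downstream in the direction of transcription. Because the window is
20 bp (even), the center — and hence the offset — is always a half-integer.

Efficacy in fission yeast CRISPRi peaks in two places: forward guides
~60–120 bp downstream of the TSS (peak near +90) and reverse guides
overlapping the TSS (narrow peak near −5). The scoring model codifies this
as tiers with a small linear distance penalty, so ranking is deterministic:

    tier A: (forward and 60 <= offset <= 120) or (reverse and -30 <= offset <= 15)
    tier B: otherwise, if -30 <= offset <= 100 (the broadly preferred region)
    tier C: everything else
    score  = base(tier) - 1e-4 * |offset - peak(orientation)|, floored at 0.01
             with base A/B/C = 1.0/0.5/0.1 and peak forward/reverse = +90/-5

Base levels are spaced so every tier-A score exceeds every tier-B score,
which exceeds every tier-C score, for any offset a genomic window can produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import TYPE_CHECKING, Iterable, Sequence

from pombe_crispri.genome import (
    GenomeSequence,
    TssRecord,
    genome_by_id,
    reverse_complement,
)

if TYPE_CHECKING:  # pragma: no cover
    from pombe_crispri.offtarget import SiteIndex

logger = logging.getLogger(__name__)

SPACER_LENGTH_DEFAULT = 20
PAM_LENGTH = 3


@dataclass(frozen=True)
class ScoringRules:
    """Tunable constants of the tier/score model (all offsets in bp from TSS)."""

    forward_a_min: float = 60.0
    forward_a_max: float = 120.0
    reverse_a_min: float = -30.0
    reverse_a_max: float = 15.0
    b_min: float = -30.0
    b_max: float = 100.0
    peak_forward: float = 90.0
    peak_reverse: float = -5.0
    base_a: float = 1.0
    base_b: float = 0.5
    base_c: float = 0.1
    distance_penalty: float = 1e-4
    score_floor: float = 0.01

    def peak(self, orientation: str) -> float:
        return self.peak_forward if orientation == "forward" else self.peak_reverse


@dataclass(frozen=True)
class RawCandidate:
    """A protospacer+PAM hit before gene-relative classification.

    start/end are 1-based inclusive plus-strand coordinates of the
    protospacer (PAM excluded) regardless of which strand carries it.
    """

    seq_id: str
    protospacer: str
    pam: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class GuideCandidate:
    """A classified, scored, off-target-annotated guide candidate."""

    gene_id: str
    seq_id: str
    protospacer: str
    pam: str
    strand: str
    start: int
    end: int
    orientation: str
    offset: float
    tier: str = "C"
    score: float = 0.0
    n20: int = 0
    n12: int = 0

    @property
    def unique(self) -> bool:
        return self.n20 == 1


def _pam_ok(pam: str) -> bool:
    return len(pam) == PAM_LENGTH and pam[1:] == "GG" and pam[0] in "ACGT"


def _clean(s: str) -> bool:
    return "N" not in s


def scan_pams(
    seq: GenomeSequence,
    window_start: int,
    window_end: int,
    spacer_length: int = SPACER_LENGTH_DEFAULT,
) -> list[RawCandidate]:
    """Enumerate every protospacer+NGG site whose center lies in the window.

    Both strands are scanned. The window is 1-based inclusive and constrains
    the protospacer *center*: candidates may extend past the window edges
    (the PAM always may). Windows containing N in the protospacer or PAM are
    excluded. Output is sorted by (start, strand) with '+' before '-'.

    Raises IndexError if the window lies outside the sequence.
    """
    n = len(seq.bases)
    if not (1 <= window_start <= window_end <= n):
        raise IndexError(
            f"window {window_start}..{window_end} out of bounds for "
            f"{seq.seq_id!r} (length {n})"
        )
    bases = seq.bases
    k = spacer_length
    out: list[RawCandidate] = []
    # A protospacer at plus coords [s, s+k-1] has center s + (k-1)/2.
    # Constrain the center to [window_start, window_end].
    for s in range(1, n - k + 1 + 1):
        e = s + k - 1
        center2 = s + e  # 2 * center, integer arithmetic to avoid fp issues
        if center2 < 2 * window_start or center2 > 2 * window_end:
            continue
        spacer_plus = bases[s - 1 : e]
        # Plus strand: PAM immediately 3' on plus = [e+1, e+3].
        if e + PAM_LENGTH <= n:
            pam = bases[e : e + PAM_LENGTH]
            if _pam_ok(pam) and _clean(spacer_plus):
                out.append(
                    RawCandidate(seq.seq_id, spacer_plus, pam, "+", s, e)
                )
        # Minus strand: protospacer is revcomp of [s, e]; its 3' PAM sits at
        # plus coords [s-3, s-1], read as the reverse complement.
        if s - PAM_LENGTH >= 1:
            pam_plus = bases[s - PAM_LENGTH - 1 : s - 1]
            if _clean(spacer_plus) and _clean(pam_plus):
                pam_minus = reverse_complement(pam_plus)
                if _pam_ok(pam_minus):
                    out.append(
                        RawCandidate(
                            seq.seq_id,
                            reverse_complement(spacer_plus),
                            pam_minus,
                            "-",
                            s,
                            e,
                        )
                    )
    out.sort(key=lambda c: (c.start, c.strand))
    return out


def classify_candidate(cand: RawCandidate, gene: TssRecord) -> GuideCandidate:
    """Fill in orientation and TSS offset for a candidate relative to a gene.

    forward <=> candidate strand equals the gene strand (protospacer is the
    non-template strand). Offset = center - tss for a plus-strand gene and
    tss - center for a minus-strand gene, so positive is always downstream
    in the direction of transcription.
    """
    if cand.seq_id != gene.seq_id:
        raise ValueError(
            f"candidate on {cand.seq_id!r} cannot be classified against gene "
            f"{gene.gene_id!r} on {gene.seq_id!r}"
        )
    orientation = "forward" if cand.strand == gene.strand else "reverse"
    center = Fraction(cand.start + cand.end, 2)
    offset = center - gene.tss if gene.strand == "+" else gene.tss - center
    return GuideCandidate(
        gene_id=gene.gene_id,
        seq_id=cand.seq_id,
        protospacer=cand.protospacer,
        pam=cand.pam,
        strand=cand.strand,
        start=cand.start,
        end=cand.end,
        orientation=orientation,
        offset=float(offset),
    )


def score_candidate(
    orientation: str, offset: float, rules: ScoringRules | None = None
) -> tuple[str, float]:
    """Assign an efficacy tier and deterministic score to (orientation, offset)."""
    r = rules or ScoringRules()
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    in_a = (
        orientation == "forward" and r.forward_a_min <= offset <= r.forward_a_max
    ) or (orientation == "reverse" and r.reverse_a_min <= offset <= r.reverse_a_max)
    if in_a:
        tier, base = "A", r.base_a
    elif r.b_min <= offset <= r.b_max:
        tier, base = "B", r.base_b
    else:
        tier, base = "C", r.base_c
    score = base - r.distance_penalty * abs(offset - r.peak(orientation))
    return tier, max(score, r.score_floor)


def annotate_offtargets(
    cand: GuideCandidate, index: "SiteIndex"
) -> GuideCandidate:
    from pombe_crispri.offtarget import count_matches

    n20, n12 = count_matches(cand.protospacer, index)
    return replace(cand, n20=n20, n12=n12)


_TIER_ORDER = {"A": 0, "B": 1, "C": 2}


def rank_key(cand: GuideCandidate, rules: ScoringRules) -> tuple:
    """Deterministic ranking: tier, score desc, peak distance, start, '+' first."""
    return (
        _TIER_ORDER[cand.tier],
        -cand.score,
        abs(cand.offset - rules.peak(cand.orientation)),
        cand.start,
        0 if cand.strand == "+" else 1,
    )


def design_guides(
    genome: Sequence[GenomeSequence],
    tss_table: Iterable[TssRecord],
    gene_id: str,
    upstream: int = 200,
    downstream: int = 300,
    top_n: int | None = None,
    unique_only: bool = False,
    rules: ScoringRules | None = None,
    spacer_length: int = SPACER_LENGTH_DEFAULT,
    site_index: "SiteIndex | None" = None,
) -> list[GuideCandidate]:
    """Design ranked guide candidates for one gene.

    The scan window spans [tss - upstream, tss + downstream] in the direction
    of transcription (for a minus-strand gene: plus coordinates
    [tss - downstream, tss + upstream]), clamped to the sequence. Candidates
    are classified, scored, annotated with genome-wide exact-match counts,
    optionally filtered to genome-unique spacers (n20 == 1), sorted by
    (tier, score desc, |offset - peak| asc, start asc, '+' before '-') and
    truncated to top_n. Deterministic for fixed inputs.
    """
    from pombe_crispri.offtarget import build_site_index

    rules = rules or ScoringRules()
    if spacer_length != SPACER_LENGTH_DEFAULT:
        if not (18 <= spacer_length <= 25):
            raise ValueError(f"spacer length must be 18-25, got {spacer_length}")
        logger.warning(
            "spacer length %d != 20; efficacy rules were established for 20-nt spacers",
            spacer_length,
        )
    genes = {rec.gene_id: rec for rec in tss_table}
    if gene_id not in genes:
        raise KeyError(f"gene {gene_id!r} not present in the TSS table")
    gene = genes[gene_id]
    seqs = genome_by_id(genome)
    if gene.seq_id not in seqs:
        raise KeyError(f"gene {gene_id!r} references unknown sequence {gene.seq_id!r}")
    seq = seqs[gene.seq_id]

    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    lo, hi = max(lo, 1), min(hi, len(seq))
    if lo > hi:
        logger.warning("empty scan window for gene %r; no candidates", gene_id)
        return []

    raw = scan_pams(seq, lo, hi, spacer_length=spacer_length)
    if not raw:
        logger.warning("no protospacer+NGG sites in window for gene %r", gene_id)
        return []

    if site_index is None:
        site_index = build_site_index(genome, spacer_length=spacer_length)

    candidates: list[GuideCandidate] = []
    for rc in raw:
        cand = classify_candidate(rc, gene)
        tier, score = score_candidate(cand.orientation, cand.offset, rules)
        cand = replace(cand, tier=tier, score=score)
        cand = annotate_offtargets(cand, site_index)
        candidates.append(cand)

    if unique_only:
        candidates = [c for c in candidates if c.unique]
    candidates.sort(key=lambda c: rank_key(c, rules))
    if top_n is not None:
        candidates = candidates[:top_n]
    return candidates


GUIDE_TSV_COLUMNS = [
    "gene_id",
    "seq_id",
    "strand",
    "start",
    "end",
    "protospacer",
    "pam",
    "orientation",
    "offset",
    "tier",
    "score",
    "n20",
    "n12",
    "unique",
]


def guides_to_tsv(candidates: Sequence[GuideCandidate]) -> str:
    """Render candidates as the package's guide-report TSV (offset 1 decimal)."""
    lines = ["\t".join(GUIDE_TSV_COLUMNS)]
    for c in candidates:
        lines.append(
            "\t".join(
                [
                    c.gene_id,
                    c.seq_id,
                    c.strand,
                    str(c.start),
                    str(c.end),
                    c.protospacer,
                    c.pam,
                    c.orientation,
                    f"{c.offset:.1f}",
                    c.tier,
                    f"{c.score:.4f}",
                    str(c.n20),
                    str(c.n12),
                    str(c.unique),
                ]
            )
        )
    return "\n".join(lines) + "\n"
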