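"""Genome-wide exact-match counting for guide uniqueness screening.

Specificity is operationalized as exact matching: a guide is *unique* when
its 20-mer occurs exactly once in the genome with an NGG PAM immediately 3'
(both strands considered; the N of the PAM is not compared). A stricter
secondary count uses only the PAM-proximal 12-nt seed, the region where
mismatches are least tolerated by Cas9. Mismatch-scored off-target models
are deliberately out of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pombe_crispri.genome import GenomeSequence, reverse_complement

SEED_LENGTH = 12


@dataclass
class SiteIndex:
    """Exact-match index over every protospacer+NGG site in a genome set.

    sites20 maps each 20-mer (as it would appear in an sgRNA, 5'->3') to the
    list of its genomic occurrences (seq_id, strand, start, end); seeds12
    counts occurrences of each PAM-proximal 12-mer.
    """

    spacer_length: int = 20
    sites20: dict[str, list[tuple[str, str, int, int]]] = field(default_factory=dict)
    seeds12: Counter = field(default_factory=Counter)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites20.values())


def build_site_index(
    genome: Sequence[GenomeSequence], spacer_length: int = 20
) -> SiteIndex:
    """Index every k-mer window with an NGG 3' context on both strands.

    Windows containing N (in the protospacer or the GG of the PAM) are
    excluded, matching the scanner's semantics.
    """
    if not genome:
        raise ValueError("genome set is empty")
    k = spacer_length
    index = SiteIndex(spacer_length=k)
    for gs in genome:
        bases = gs.bases
        n = len(bases)
        for s in range(1, n - k + 2):
            e = s + k - 1
            window = bases[s - 1 : e]
            if "N" in window:
                continue
            # plus strand: NGG at [e+1, e+3]; only the GG is compared
            if e + 3 <= n and bases[e + 1 : e + 3] == "GG" and bases[e] != "N":
                _add_site(index, window, (gs.seq_id, "+", s, e))
            # minus strand: plus-coords [s-3, s-1] must read CCN
            if s - 3 >= 1 and bases[s - 4 : s - 2] == "CC" and bases[s - 2] != "N":
                _add_site(index, reverse_complement(window), (gs.seq_id, "-", s, e))
    return index


def _add_site(index: SiteIndex, spacer: str, loc: tuple[str, str, int, int]) -> None:
    index.sites20.setdefault(spacer, []).append(loc)
    index.seeds12[spacer[-SEED_LENGTH:]] += 1


def count_matches(protospacer: str, index: SiteIndex) -> tuple[int, int]:
    """Count genomic sites matching the full spacer (n20) and its 12-nt seed (n12).

    The seed is the 3'-most (PAM-proximal) 12 nt of the protospacer, so
    n12 >= n20 always. Raises ValueError on N in the query or a length
    mismatch with the index.
    """
    if len(protospacer) != index.spacer_length:
        raise ValueError(
            f"query length {len(protospacer)} != index k-mer length {index.spacer_length}"
        )
    if "N" in protospacer:
        raise ValueError("query protospacer must not contain N")
    n20 = len(index.sites20.get(protospacer, ()))
    n12 = index.seeds12.get(protospacer[-SEED_LENGTH:], 0)
    return n20, n12


def offtarget_report_tsv(
    protospacers: Iterable[str], index: SiteIndex
) -> str:
    """Standalone match-count report: protospacer, n20, n12, unique."""
    lines = ["protospacer\tn20\tn12\tunique"]
    for sp in protospacers:
        n20, n12 = count_matches(sp, index)
        lines.append(f"{sp}\t{n20}\t{n12}\t{n20 == 1}")
    return "\n".join(lines) + "\n"
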