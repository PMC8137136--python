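import pytest

from pombe_crispri.genome import TssRecord
from pombe_crispri.simulate import PlantSpec, generate_genome_fixture

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    """Independent reverse complement via an explicit lookup table."""
    return "".join(_COMP[b] for b in reversed(seq))


def naive_scan(bases: str, k: int = 20):
    """Brute-force enumeration of all k-mer+NGG sites on both strands.

    Returns a set of (protospacer, pam, strand, start, end) with 1-based
    inclusive plus-strand coordinates, N-containing windows excluded.
    """
    hits = set()
    n = len(bases)
    for s in range(1, n - k + 2):
        e = s + k - 1
        window = bases[s - 1 : e]
        if "N" in window:
            continue
        if e + 3 <= n:
            pam = bases[e : e + 3]
            if "N" not in pam and pam.endswith("GG"):
                hits.add((window, pam, "+", s, e))
        if s - 3 >= 1:
            pam_plus = bases[s - 4 : s - 1]
            if "N" not in pam_plus:
                pam = naive_revcomp(pam_plus)
                if pam.endswith("GG"):
                    hits.add((naive_revcomp(window), pam, "-", s, e))
    return hits


@pytest.fixture
def planted_fixture():
    """One chromosome with a plus-strand gene, three planted sites."""
    genes = [TssRecord("g1", "chr1", "+", 1000)]
    plants = [
        PlantSpec("g1", "forward", 90.5, unique=True),
        PlantSpec("g1", "reverse", -5.5, unique=True),
        PlantSpec("g1", "forward", 250.5, unique=True),  # tier C, far downstream
    ]
    genome, tss, manifest = generate_genome_fixture(
        n_chrom=1, length=3000, genes=genes, plants=plants, seed=11
    )
    return genome, tss, manifest


@pytest.fixture
def minus_gene_fixture():
    """A minus-strand gene with forward and reverse plants."""
    genes = [TssRecord("g2", "chr1", "-", 2000)]
    plants = [
        PlantSpec("g2", "forward", 79.5, unique=True),
        PlantSpec("g2", "reverse", 0.5, unique=True),
    ]
    genome, tss, manifest = generate_genome_fixture(
        n_chrom=1, length=3000, genes=genes, plants=plants, seed=23
    )
    return genome, tss, manifest
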