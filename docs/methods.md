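# Methods

## Coordinate and strand conventions

All external files and reports use 1-based inclusive coordinates. A gene's
TSS is the single first-transcribed base; no TSS intervals are supported,
and duplicate gene ids in the TSS table are rejected rather than resolved.
A guide candidate's `start`/`end` are always plus-strand coordinates of the
protospacer (PAM excluded), whichever strand carries it. The TSS *offset* of
a candidate is the signed distance from the TSS to the protospacer center,
positive downstream in the direction of transcription; because the spacer is
20 bp (even), the center is a half-integer and offsets are reported with one
decimal, never rounded. Orientation is defined by strand identity: a guide
is *forward* exactly when the protospacer lies on the gene's own strand
(i.e. reads as the non-template strand, so the sgRNA base-pairs with the
template strand), *reverse* otherwise.

## PAM scanning

`scan_pams` enumerates every 20-nt window whose immediately 3'-adjacent
trinucleotide is NGG, on both strands (a minus-strand site at plus
coordinates [s, e] requires plus-strand CCN at [s−3, s−1]). The scan window
constrains the protospacer *center*, so candidates may extend past the
window edges. Any window containing N in the protospacer or PAM is skipped:
N bases are kept in the genome but poison matching, which keeps exact-match
semantics unambiguous. The scanner is verified in the test suite against an
independent brute-force enumeration written with a separate complement
table.

## Efficacy model

The empirical picture in fission yeast CRISPRi is qualitative: two efficacy
peaks (forward guides ~60–120 bp downstream of the TSS; reverse guides
overlapping the TSS, narrow peak near −5 bp), a broadly preferred
−30..+100 bp region, and mixed directionality evidence very close to the
TSS (−30..+15 bp). The package codifies this as a deterministic tier + score
model rather than attempting a fitted response curve:

- tier A: (forward and 60 ≤ offset ≤ 120) or (reverse and −30 ≤ offset ≤ 15)
- tier B: otherwise, −30 ≤ offset ≤ 100
- tier C: everything else
- score  = base(tier) − 10⁻⁴ · |offset − peak(orientation)|, floored at
  0.01, with base A/B/C = 1.0/0.5/0.1 and peak(forward)/peak(reverse) =
  +90/−5.

The two rules deliberately overlap rather than being reconciled: a reverse
guide at +80 is inside the broadly preferred region (tier B) but outside
both tier-A peaks. Giving tier A to reverse-only guides near the TSS follows
the final design guideline even though individual near-TSS data points go
both ways. The base levels and the 10⁻⁴ penalty are spaced so that tier
strictly dominates score for any offset a genomic window can produce (the
tests assert strict A > B > C separation over offsets −500..+500); within a
tier the penalty is a pure tie-break by peak distance. All window constants
and peaks live in `ScoringRules` and can be overridden via the YAML config.

Default scan window: 200 bp upstream to 300 bp downstream of the TSS, which
covers the empirically probed offsets with margin. Spacer length is fixed at
20 nt (longer spacers gave no improvement in the underlying experiments);
18–25 are accepted with a warning. Remaining ranking ties are broken by
(start coordinate, then '+' strand first) for run-to-run determinism.

## Off-target counting

Specificity is operationalized as exact matching, mirroring the uniqueness
notion of genome-wide guide-design tools: `n20` counts genomic sites whose
20-mer equals the spacer with any NGG PAM (the N is not compared), `n12`
counts sites matching only the PAM-proximal 12-nt seed — the region where
Cas9 tolerates mismatches least — so n12 ≥ n20 always. "Unique" means
n20 = 1. Mismatch-scored off-target models are intentionally out of scope;
the index is a plain hash of both-strand k-mers and is cross-checked against
naive full-genome string scans in the tests.

## Oligo construction and annealing

Top oligo = `CACC` + spacer, bottom oligo = `AAAC` + reverse complement of
the spacer (both written 5'→3'); annealed, the duplex presents 4-nt 5'
overhangs complementary to the BbsI-cut sgRNA vector. The overhangs are
configuration values — a differently digested vector needs different ones.
Spacer Tm defaults to the Wallace rule, 2·(A+T) + 4·(G+C), the standard
quick estimate for 20-mers; a nearest-neighbor thermodynamic option is
available via config. The annealing program is 95 °C for 2 min, a −2 °C/min
ramp to Tm, 5 min at Tm, and a −2 °C/min ramp to 25 °C; the final ramp rate
reuses −2 °C/min for symmetry (the protocol's "gradual cooling" does not pin
it down). Zero-duration ramps at the Tm = 95 °C boundary are kept as no-op
steps so the schedule shape is invariant. Oligo grade, concentrations and
ligation quantities are emitted as static protocol notes, not computed.

## Repression statistics

Relative quantity uses the ΔCq model, E^(Cq_ref − Cq_target), with
amplification efficiency E ∈ (1, 2.2], default 2.0 (perfect doubling);
standard-curve quantification is out of scope. Relative mRNA levels divide
each replicate by the mean of the nonsense-control group (per-replicate
division, as the definition reads literally, rather than a ratio of means).
The repression index is the reciprocal, R = 1/rel_mRNA, and
%R_i = (R_i − mean(R_ns)) / (mean(R_max) − mean(R_ns)) × 100. Two identities
follow for any positive inputs and are asserted exactly in the tests: the
control group averages 0% and the designated R_max group averages 100%. The
statistic is invariant under common positive rescaling of all inputs and
monotone in decreasing relative mRNA. SDs are sample SDs (n−1); the
convention for reported "mean ± SD" summaries does not specify the
denominator, so the unbiased-variance choice is made here. R_max is either
an explicit guide id (reproducing designated-anchor analyses) or "auto" (the
guide with the highest mean index). Groups with fewer than three biological
replicates are summarized but flagged `low_replicate`, not rejected.
Degenerate normalization (mean R_max = mean R_ns) is an error.

## Synthetic fixtures

The genome simulator draws i.i.d. bases at a configurable GC fraction
(default 0.36, fission-yeast-like) and plants 20-mer + NGG sites at exact
requested orientations and half-integer TSS offsets; for unique plants the
20-mer is rejection-sampled (cap 1000 tries, failure is an error) until it
occurs exactly once genome-wide as a substring on either strand — a
sufficient condition for n20 = 1. Plants may not overlap one another (PAM
footprint included) or run off the chromosome. An optional AT-rich promoter
mode regenerates the 200 bp upstream of each TSS at a lower GC fraction
(0.25 suggested), emulating the PAM scarcity of real fission-yeast
promoters. The qPCR simulator inverts the ΔCq model around a reference
baseline of Cq 15 and a target:reference abundance ratio of 0.05 at the
unrepressed level; both constants cancel in the normalization chain, so
recovery of planted levels is exact at zero Cq noise, which the tests
exploit as a round-trip oracle. Gaussian noise of chosen SD (in cycles) is
added independently to every measurement.

What the simulators do *not* emulate: real promoter sequence composition
beyond GC content, nucleosome positioning or any chromatin effect on
efficacy, dCas9 binding kinetics, amplification-curve artifacts, or
between-replicate biological variance structure (noise is i.i.d. Gaussian on
the Cq scale). Passing tests therefore demonstrate correctness of the
computational chain — enumeration, classification, counting, and the
statistic — not predictive accuracy of the efficacy tiers on real genes.

## Problem sizes and determinism

Tests and the acceptance script run on kilobase-scale simulated genomes
(≤ 5 kb random sequences for the brute-force oracle comparisons, 20 genomes
per check) and replicate counts of 3 (100 for the noisy-recovery check),
which exercise every code path at desk scale. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); fixture generation is
byte-reproducible for a fixed seed, and design/quantify runs contain no
randomness at all.
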