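# pombe-crispri

Guide-RNA design and repression quantification for dCas9-mediated CRISPRi in
the fission yeast *Schizosaccharomyces pombe*.

CRISPRi represses a gene by parking a catalytically dead Cas9 (dCas9) on its
DNA, guided by the 20-nt targeting (spacer) sequence of an sgRNA. In fission
yeast, where a guide binds matters enormously: repression efficiency as a
function of distance from the transcription start site (TSS) shows two
peaks — **forward** guides (spacer identical to the non-template strand)
work best ~60–120 bp downstream of the TSS, and **reverse** guides (spacer
identical to the template strand) work best overlapping the TSS, peaking
near −5 bp. This package is for bench scientists planning CRISPRi
experiments in *S. pombe*: it turns a genome FASTA and a TSS table into a
ranked list of cloning-ready guides, and turns RT-qPCR Cq tables into
repression statistics.

## What it does

- **Design** — scan a window around a gene's TSS for 20-nt protospacers with
  an immediately 3'-adjacent NGG PAM on either strand, classify each by
  orientation and signed TSS offset (to the spacer center, positive
  downstream), and rank them by a deterministic tiered score:
  tier A = (forward, offset 60–120) or (reverse, offset −30..+15);
  tier B = otherwise inside the broadly preferred −30..+100 region;
  tier C = the rest. Within a tier, score = base − 10⁻⁴·|offset − peak|
  with peaks at +90 (forward) and −5 (reverse).
- **Off-target screen** — exact-match counts over the whole genome:
  `n20` (full spacer + NGG) and `n12` (PAM-proximal 12-nt seed + NGG);
  a guide is *unique* when n20 = 1.
- **Oligos** — the two annealing oligos for Golden-Gate insertion into a
  BbsI-cut sgRNA vector (`CACC` + spacer / `AAAC` + reverse complement),
  the spacer Tm (Wallace rule by default), and the annealing program
  (95 °C 2 min → −2 °C/min to Tm → Tm 5 min → −2 °C/min to 25 °C).
- **Quantify** — the RT-qPCR chain: ΔCq relative quantity vs a reference
  gene (act1⁺), normalization to the nonsense-control mean, repression
  index R = 1/rel_mRNA, and

  ```
  %Repression = (R_x − mean(R_ns)) / (mean(R_max) − mean(R_ns)) × 100
  ```

  so the non-targeting control averages exactly 0% and the designated
  strongest guide exactly 100%, with mean ± SD over biological replicates.
- **Simulate** — seeded synthetic genomes with protospacer+PAM sites planted
  at prescribed TSS offsets/orientations, and qPCR Cq tables encoding known
  true repression, so everything above is testable without downloads.

## Worked example

```sh
python examples/quantify_repression.py
```

builds a noiseless Cq table encoding relative mRNA levels of 1.0 (nonsense
control), 0.14 (guide a4) and 0.13 (guide a5) and prints:

```
guide_id  n  rel_mrna_mean  rel_mrna_sd  r_mean  pct_repression_mean  pct_repression_sd  pct_reduction  flags
a4        3  0.14           0            7.143   91.79                0                  86
a5        3  0.13           0            7.692   100                  0                  87
nonsense  3  1              0            1       0                    0                  0
```

Reading the a5 row: its mRNA level is 13% of the control, i.e. an 87%
reduction; its repression index is 1/0.13 ≈ 7.69; and as the designated
R_max guide it sits at exactly 100% on the %Repression scale, while the
control anchors 0%. See `examples/` for guide design, off-target screening,
and oligo ordering; the same operations are available from the shell:

```sh
pombe-crispri design --genome genome.fa --tss tss.tsv --gene ade6 --top 5 --unique-only
pombe-crispri oligos --spacer a5=ATGTTGGATTACTTCGTTAA
pombe-crispri quantify --qpcr cq.csv --control nonsense --rmax a5
pombe-crispri simulate genome --seed 7 --gene ade6:chr1:+:1000 --plant ade6:forward:90.5 --out-prefix fix
```

## Input formats

- Genome: multi-record FASTA (uppercased on read; only A/C/G/T/N accepted).
- TSS table: tab-separated with header `gene_id  seq_id  strand  tss`
  (1-based TSS of the first transcribed base; `#` comment lines skipped;
  one TSS per gene).
- qPCR table: CSV with columns `sample_id, guide_id, gene_role, replicate,
  cq` where `gene_role` is `target` or `reference`.

All coordinates in inputs and reports are 1-based inclusive.

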