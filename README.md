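# gseseq

A toolkit for droplet-barcoded **single-entity long-read sequencing** of
microbial communities — the computational side of experiments in which single
viruses or bacteria are encapsulated in droplets, whole-genome amplified,
fragmented, tagged with a droplet-specific DNA barcode, and sequenced as
HiFi-like long reads. It is aimed at microbiome and viromics researchers who
want to demultiplex such libraries into single amplified genomes (SAGs),
compare assembly strategies, and validate pipelines on simulated mock
communities with full ground truth.

## What it does

* **Barcode-pool statistics** (`gseseq.poolstats`). A cassette of two PCR
  handles flanking `L` random bases spans `4^L` sequences (for `L = 19`,
  exactly 274,877,906,944 ≈ 2.7 × 10¹¹). Drawing a pool of `n` barcodes
  uniformly with replacement, the expected fraction of non-unique barcodes is

  `f(n, N) = 1 − N·(1 − (1 − 1/N)^n)/n`, with `N = 4^L`,

  which for `n = 5 × 10⁹` gives ≈ 0.90 % — i.e. a billion-scale pool from a
  19-mer space is >99 % collision-free. A Monte-Carlo sampler and a
  Levenshtein pairwise-distance profiler cross-check the closed form.
* **Simulator with ground truth** (`gseseq.simulate`). Mock communities
  (random genomes, related strains, or user FASTA), Poisson droplet loading
  (doublets included), log-normal per-window amplification bias standing in
  for MDA, log-normal read lengths calibrated to a target N50 (default
  1.7 kb), HiFi-like error rates, barcode corruption, and ambient
  contamination — with per-read and per-droplet truth tables.
* **Demultiplexing** (`gseseq.readparse`, `gseseq.cluster`). Fuzzy
  semi-global anchor alignment finds the cassette in either orientation;
  observed barcodes are clustered into canonical droplet barcodes by greedy
  abundance-descending sphere clustering (Levenshtein radius `d = 2`,
  abundance ratio 5, starcode-style), and every read is assigned to a SAG.
* **Assembly strategies** (`gseseq.assemble`). A deterministic greedy
  overlap-layout assembler plus the three partitioning strategies: direct
  assembly (DA, all reads pooled), barcode-clustered assembly (BCA, one
  assembly per barcode cluster), and SAG binning (SAGb, per-cluster assembly
  with one genome bin per cluster). External assemblers plug in via a
  command template.
* **Evaluation** (`gseseq.evaluate`). Canonical 21-mer containment assigns
  reads to references; per SAG it reports mapping ratio, purity (fraction of
  assigned reads on the majority reference), external contamination
  (1 − purity), reference-based completeness, and a quality tier
  (complete = 100 %, high > 90 %, medium 50–90 % with quality score
  completeness − 5 × contamination ≥ 10, draft 10–50 %, else low).

## Worked example

Run the built-in mixed-strain demo — three strains of a 12 kb viral genome at
~1 % pairwise divergence, 64 droplets sequenced to ~4× each — and compare
assembly strategies:

```bash
gse run --outdir demo --seed 1
```

or from Python:

```python
from gseseq import strategy_demo_config, run_pipeline
report = run_pipeline(strategy_demo_config(outdir="demo", seed=1))
print(report["stages"]["assemble"])
```

which prints (seed 1):

```
DA   {'n_contigs': 6,   'max_len': 12004, 'total_len': 16087,  'n50': 12004, 'count_gt_2kb': 1,   'count_gt_10kb': 1}
BCA  {'n_contigs': 143, 'max_len': 12006, 'total_len': 760673, 'n50': 8320,  'count_gt_2kb': 103, 'count_gt_10kb': 24}
SAGb {'n_contigs': 143, 'max_len': 12006, 'total_len': 760673, 'n50': 8320,  'count_gt_2kb': 103, 'count_gt_10kb': 24}
```

Read this as: pooled assembly (DA) collapses the three strains into a single
consensus mosaic — one long contig and almost nothing else — while the
barcode-aware strategies reconstruct a genome per droplet: 103 contigs over
2 kb (a 103× gain here) and 24 single-droplet genomes over 10 kb, at the
same maximum contig length. The run directory contains the simulated reads,
truth tables, barcode calls, cluster table, per-SAG FASTA, contigs per
strategy, per-SAG metrics, and `report.json` with the fold-change table.

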