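# capiso

Targeted full-length isoform capture analysis, at desk scale.

Most protein-coding genes express several transcript isoforms, but their
abundances span six or more orders of magnitude, so bulk long-read
sequencing spends nearly all of its depth on a handful of abundant
transcripts. Hybridization capture with probes synthesized from a single
ORF clone per gene concentrates sequencing on the genes of interest;
because isoforms of one gene share most of their exonic sequence, one
probe template suffices to pull down the whole isoform family. `capiso`
implements the computational side of such an experiment — probe coverage
estimation, full-length (FL) read processing with dual-barcode PCR-chimera
detection, SQANTI-style structural classification, functional feature
annotation with orthogonal short-read validation, and enrichment and
saturation statistics — together with a fully seeded synthetic-experiment
generator with known ground truth, so every estimator can be checked
against the parameters that generated its input.

It is aimed at method developers and analysts who want a small, testable,
dependency-light reimplementation of this analysis stack rather than a
production aligner pipeline: alignment, consensus polishing and
quantification are upstream and out of scope; the package consumes (or
simulates) aligned exon structures.

## The quantities it computes

- **Probe capture coverage.** For each gene with representative
  (template) isoform *r*, an isoform *t* is covered when the exonic
  overlap |exons(r) ∩ exons(t)| ≥ 50 bp. The coverage fraction is the
  number of covered isoforms over all coding, `basic`-tagged isoforms;
  the template is the APPRIS principal isoform, a random isoform, or
  user-specified.
- **Full-length reads and chimeras.** A read is FL iff it carries the 5′
  primer, the 3′ primer, and a polyA tail preceding the 3′ primer.
  Molecules synthesized with matched 5′/3′ inner barcode pairs reveal
  PCR chimeras as swapped (discordant) pairings; an isoform is called
  non-chimeric when a strict majority of its resolved FL reads are
  concordant.
- **Structural categories.** Collapsing FL reads on identical junction
  chains, each isoform is FSM (chain equals a reference chain), ISM
  (consecutive sub-chain), NIC (all junctions, or all splice sites,
  annotated), NNC (≥ 1 novel splice site), or a mono-exon category.
  Novel junctions must be supported by ≥ 3 orthogonal short reads for an
  isoform to survive validation.
- **Enrichment.** On-target rate = Σ_{g ∈ targets} f_g where f_g is the
  gene's fraction of total abundance (TPM) or of FL reads; fold
  enrichment = on-target(capturant) / on-target(input). Per-isoform
  capture efficiency = capturant depth / input depth.
- **Saturation-discovery.** Subsampling the FL read pool without
  replacement, the mean number of unique genes/isoforms per depth
  (100 iterations), with the hypergeometric closed form
  E[unique] = Σ_i (1 − C(N−n_i, d)/C(N, d)) as analytic reference.

The synthetic generator models capture with a piecewise-linear efficiency
curve in template overlap — background below 35 nt, full efficiency from
45 nt up — reflecting spike-in measurements that show capture efficiency
flat from 45 to 2500 nt of overlap and collapsing at 35 nt.

## Worked example

```bash
capiso run --seed 1 --out runs/demo
cat runs/demo/summary.txt
```

```
[enrichment]
on_target_input      0.3200
on_target_capturant  0.9792
fold_enrichment      3.06

[chimeras]
read_level_chimera_rate  0.0196
nonchimeric_rate_all     0.9700
nonchimeric_rate_novel   0.9412

[classification]
n_isoforms  100
  FSM                79
  ISM                4
  NIC                7
  NNC                10
novel_isoform_fraction      0.1700
novel_junction_fraction     0.0627
novel_splice_site_fraction  0.0229
intron_retention_fraction   0.0500
```

Reading this: the 15 targeted genes held 32% of input abundance and 98%
after simulated capture (3.1-fold enrichment — modest here only because a
desk-scale transcriptome of 50 genes leaves the targets already abundant).
The dual-barcode estimate of the chimera rate, 0.0196, recovers the 0.02
the simulation injected; 97% of collapsed isoforms are called
non-chimeric. Of 100 distinct isoforms, 17% are novel relative to the
reference catalog (a quarter of alternative isoforms are deliberately
withheld from the reference), and — as in real capture data — novelty
amplifies from splice sites (2.3%) through junctions (6.3%) to whole
isoforms (17%), because one novel site makes an entire transcript novel.
5% of isoforms carry an intron retention event.

The run directory also contains the simulated genome/annotation/reads,
per-read labels, classification and feature tables, a recovery table,
rank-abundance and saturation-curve TSVs, and a manifest; two runs with
the same config are byte-identical.

Library use mirrors the CLI:

```python
from capiso import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(seed=1), outdir="runs/demo")
bundle["enrichment"].fold_enrichment   # 3.06...
```

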