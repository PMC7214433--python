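# Methods

This note documents the models implemented in `capiso`, the conventions
chosen where several were defensible, and what the synthetic generator
does and does not emulate.

## Coordinate and identity conventions

All intervals are 0-based half-open on the forward genomic strand; GTF
(1-based closed) converts at the boundary. A transcript's *junction
chain* — its ordered intron coordinates — is stored in ascending genomic
order on both strands, with strand as metadata, so chain equality is a
plain tuple comparison and is strand-safe. A splice site is keyed by
(contig, strand, boundary coordinate, side): on `+` the left intron
boundary is the donor, on `-` the right one. A donor at a coordinate
annotated only as an acceptor is therefore novel, which is the
biologically meaningful reading.

## Probe capture coverage

Probes are synthesized from one template isoform per gene; a probe set
captures any cDNA sharing enough sequence with the template. Overlap is
counted as exonic bp (intersection of the two exon-interval unions),
because probes derive from spliced transcript sequence; a genomic-span
variant (`span_overlap`) is provided for comparison and can only report
more overlap. The covered/uncovered threshold defaults to 50 bp.
Conventions: the template always covers itself even when shorter than the
threshold (a probe trivially captures its own template);
strand-mismatched overlap is 0; genes lacking an APPRIS tag are skipped
by default (count reported) with `longest`/`error` policies available.
The analysis denominator is restricted to protein-coding transcripts
carrying the `basic` tag, applied by the caller via
`filter_coding_basic`.

## Capture model

Capture efficiency is piecewise linear in template overlap:

    e(t) = p_bg                          overlap < 35 nt
         = p_on                          overlap ≥ 45 nt
         = linear interpolation          between

with defaults p_on = 0.5, p_bg = 0.005. The flat-above-45 / floor-at-35
shape is the simplest curve consistent with spike-in measurements of
per-isoform capture efficiency versus overlap; no functional form between
those anchors is empirically constrained, so linear is used. Background
retention is constant by default; an optional knob
(`k_offtarget_abundance`) scales it with log10 relative abundance to
mimic abundance-dependent non-specific bead binding, but its magnitude is
not empirically constrained, so the default is 0. The baseline capture
step is deterministic: post-capture abundance ∝ pre-capture × e(t),
renormalized to 1e6 TPM. Stochasticity enters downstream through read
sampling.

## Synthetic experiment generator

The generator defines the study conditions; its defaults are fixed and
the tests run against them.

* **Annotation/genome.** One contig per gene (default 50 genes), a
  principal transcript of 3–12 exons (80–300 nt) separated by introns of
  60–500 nt, plus up to 7 alternative isoforms derived by exon skipping,
  3–30 nt donor/acceptor shifts, intron retention, and alternative first
  exons. Sense splice dinucleotides are GT..AG by construction (genomic
  CT..AC for minus-strand genes). Duplicate chains and conflicting
  dinucleotide placements are discarded.
* **Expression.** Per-gene abundance is log-uniform over 6 orders of
  magnitude (the dynamic range of a mammalian transcriptome), split
  across isoforms by a symmetric Dirichlet with concentration 1
  (uninformative — no empirical isoform-usage prior is imposed), then
  normalized to 1e6.
* **Reads.** 30 000 long reads drawn proportional to post-capture
  abundance; 90% are full length, the rest drop exactly one of
  {5′ primer, 3′ primer, polyA} uniformly — the minimal model that
  exercises the FL filter. Each molecule carries one of 96 matched dual
  inner-barcode pairs and one of 7 sample barcodes. With probability 0.02
  a read is a PCR chimera joining the 5′ portion of molecule A to the 3′
  portion of an independently drawn molecule B: its inner barcodes come
  from two molecules and its aligned blocks are those of the 5′ molecule.
  A chimera whose two molecules drew the same pair (≈ 1/96 of them) is
  undetectable, exactly as in the real assay; the resulting bias is far
  inside the binomial sampling error at these read counts.
* **Reference vs truth.** 25% of alternative (never principal, never
  template) isoforms are withheld from the reference catalog while
  remaining expressed. Discovery of these held-out isoforms is what
  produces ISM/NIC/NNC calls, novel junctions for the validation filter,
  and a defined "novel isoform" stratum for chimera rates — emulating a
  catalog that lags the transcriptome.
* **Short-read junction support.** Counts are Poisson with mean
  (depth × relative abundance mass of transcripts containing the
  junction), depth 50× by default.
* **Not modeled.** Sequencing errors and quality values, consensus
  accuracy, 5′/3′ truncation heterogeneity, fragment-length loading
  bias, and literal nucleotide read sequences (an optional FASTA emitter
  exists for interface tests; classification operates on exon blocks).
  Passing tests therefore demonstrate correctness of the estimators
  under clean alignments, not robustness to alignment noise.

## Read processing and chimera calls

FL = 5′ primer ∧ 3′ primer ∧ polyA. Demultiplexing assigns only FL reads;
unknown barcodes go to an `unassigned` bin. Dual-barcode concordance is
`concordant` when the 5′/3′ inner barcodes form a known pair,
`discordant` when both are present but mismatched, `unresolved` when
either is missing. Per-isoform calls use a strict majority of resolved
member reads; unresolved reads are excluded from the denominator, and a
tie is called chimeric — "majority" is read strictly, which is the
conservative direction for novel-isoform claims. The read-level chimera
rate estimator is the discordant fraction among resolved reads.

## Collapse and classification

Multi-exon FL reads collapse on identical (contig, strand, junction
chain); representative exons span the extreme 5′/3′ ends among members,
and per-sample FL counts are summed — 5′/3′ end variation within a chain
is ignored (TSS/TES clustering is out of scope). Mono-exon reads collapse
by single-linkage interval overlap per contig and strand.

Classification order for multi-exon isoforms: FSM (exact chain match) →
ISM (consecutive intron run of a longer reference chain, the standard
SQANTI convention) → NIC, subcategorized as a recombination of known
junctions or a novel junction between known sites → NNC (≥ 1 novel
site). Mono-exon isoforms are known when contained in a reference exon,
novel when overlapping a gene footprint, else intergenic. Gene assignment
maximizes shared junctions, then exonic overlap, then lexicographic gene
id — fully deterministic. Intron retention is flagged when an observed
exon completely contains a reference intron of the matched gene while
overlapping both flanking exons. Canonical splice dinucleotides are
{GT-AG, GC-AG, AT-AC}. Alignment-quality filtering keeps isoforms with
coverage ≥ 0.99 and identity ≥ 0.95, inclusive.

## Functional features and validation

* **CAGE.** The 5′ end (strand-aware) is compared with peak intervals:
  reported are the signed distance to the nearest peak center (integer
  midpoint; negative = 5′ end upstream of the center in transcript
  orientation — the sign convention is ours, stated because none is
  standard) and containment in [peak start, peak end).
* **PolyA motif.** AATAAA/ATTAAA (DNA sense) searched in the window
  whose bases lie 5–25 nt upstream of the 3′ end, motif fully contained;
  offsets are measured to the motif's last base (the offset to its first
  base is also emitted, since either reading of "5–25 nt upstream" is
  defensible); the match nearest the 3′ end wins; windows truncate at
  contig boundaries. Minus-strand lookups reverse-complement the genomic
  window.
* **Splice-site conservation.** Per junction, the donor trinucleotide is
  the last exonic base plus the first two intronic bases and the acceptor
  trinucleotide the last two intronic bases plus the first exonic base,
  strand-aware; per-base scores come from a bedGraph track, and missing
  positions propagate as missing, never 0 — 0 is a meaningful
  conservation score.
* **Validation.** An isoform is validated iff every one of its novel
  junctions has short-read support ≥ 3 (junctions absent from the table
  count 0); isoforms with no novel junctions pass vacuously, and the
  filtered set drops unvalidated novel isoforms. The filter is monotone
  in the threshold.

## Enrichment and saturation

On-target rate supports both TPM-weighted and FL-read-count denominators.
Fold × input = capturant holds as an algebraic identity and is asserted
in tests at 1e-12. Saturation curves subsample the finite FL pool without
replacement (matching how a finite sequencing run is rarefied), 100
iterations per depth, arithmetic means with no smoothing; the
hypergeometric expectation E[unique] = Σ_i (1 − C(N−n_i, d)/C(N, d)) is
implemented in log-gamma space and doubles as the analytic oracle in
tests (exactly verified against exhaustive subset enumeration on tiny
pools, and within 3 standard errors of sampled means at scale).
Rank-abundance tables sort descending with lexicographic tie-breaks.

## Pipeline and reproducibility

A single global seed expands through `numpy.random.SeedSequence.spawn`
into independent per-stage substreams, so any stage rerun in isolation
reproduces its in-pipeline output and two runs with one config are
byte-identical. The config is YAML with a schema version and round-trips
losslessly. Default problem sizes (50 genes, 30 000 reads, 100 saturation
iterations) keep a full run in seconds while leaving all statistical
checks well-powered at 3-standard-error tolerances.

## Known limitations

Exonic overlap of transcripts on *different* genes is not modeled
(overlapping loci, read-through); the generator places each gene on its
own contig. ISM detection does not distinguish 5′ from 3′ truncation.
Chimeric reads inherit the full exon chain of their 5′ molecule rather
than a truncated hybrid alignment, so chimera detection rests entirely on
barcode discordance, as in the assay itself. The probe-coverage estimate
on synthetic annotations is near 1.0 by construction (isoform families
share most exons); the interesting behavior there is the ordering between
template modes and the monotone response to the overlap threshold, both
of which are tested.
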