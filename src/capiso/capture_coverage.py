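"""Probe capture-coverage estimation.

Hybridization probes synthesized from a single representative isoform per
gene ("one ORF per gene") are expected to capture every isoform sharing
enough sequence with that template. This module estimates, for an
annotation, the fraction of isoforms with at least ``min_overlap`` exonic
bp in common with their gene's representative — the quantity that decides
whether a one-template-per-gene probe design suffices.

Overlap counts exonic bp (intersection of the two exon-interval unions),
because probes derive from spliced transcript sequence; a genomic-span
reading is also provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .genomic_model import AnnotationSet, TranscriptModel


def _merge(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total bp shared by the exon-interval unions of two transcripts.

    Zero when the transcripts sit on different contigs or strands —
    capture hybridization is sequence (strand) specific.
    """
    if a.contig != b.contig or a.strand != b.strand:
        return 0
    xs, ys = _merge(a.exons), _merge(b.exons)
    i = j = total = 0
    while i < len(xs) and j < len(ys):
        lo = max(xs[i][0], ys[j][0])
        hi = min(xs[i][1], ys[j][1])
        if lo < hi:
            total += hi - lo
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return total


def span_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Genomic-span intersection (start..end, introns included)."""
    if a.contig != b.contig or a.strand != b.strand:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def filter_coding_basic(annotation: AnnotationSet) -> AnnotationSet:
    """Keep protein-coding transcripts carrying the 'basic' tag (the core set)."""
    keep = [
        tid
        for tid, t in annotation.transcripts.items()
        if t.coding and "basic" in t.tags
    ]
    return annotation.subset(keep)


def select_representative(
    annotation: AnnotationSet,
    mode: str = "appris",
    seed: Optional[int] = None,
    overrides: Optional[Mapping[str, str]] = None,
    missing_appris: str = "skip",
) -> dict[str, str]:
    """Pick one template transcript per gene.

    mode='appris' takes the appris_principal-tagged transcript (ties broken
    by longest exonic length then id); 'random' draws uniformly over the
    gene's transcripts (deterministic under seed); 'specified' uses
    ``overrides``. Genes without an APPRIS tag follow ``missing_appris``:
    'skip' (default, with a count available to callers), 'longest', or
    'error'.
    """
    if mode not in ("appris", "random", "specified"):
        raise ValueError(f"unknown mode {mode!r}")
    reps: dict[str, str] = {}
    if mode == "specified":
        if overrides is None:
            raise ValueError("mode='specified' requires overrides")
        for gene_id, tids in annotation.genes.items():
            if gene_id not in overrides:
                raise ValueError(f"no override for gene {gene_id!r}")
            tid = overrides[gene_id]
            if tid not in tids:
                raise ValueError(f"override {tid!r} does not belong to gene {gene_id!r}")
            reps[gene_id] = tid
        return reps
    if mode == "random":
        rng = np.random.default_rng(seed)
        for gene_id in sorted(annotation.genes):
            tids = sorted(annotation.genes[gene_id])
            reps[gene_id] = tids[int(rng.integers(len(tids)))]
        return reps
    # appris
    for gene_id in sorted(annotation.genes):
        tids = sorted(annotation.genes[gene_id])
        tagged = [
            tid
            for tid in tids
            if "appris_principal" in annotation.transcripts[tid].tags
        ]
        if tagged:
            tagged.sort(
                key=lambda tid: (-annotation.transcripts[tid].exonic_length, tid)
            )
            reps[gene_id] = tagged[0]
        elif missing_appris == "longest":
            reps[gene_id] = min(
                tids,
                key=lambda tid: (-annotation.transcripts[tid].exonic_length, tid),
            )
        elif missing_appris == "error":
            raise ValueError(f"gene {gene_id!r} has no appris_principal transcript")
        # 'skip': gene omitted from the map
    return reps


@dataclass
class CoverageReport:
    n_genes: int
    n_isoforms: int
    n_covered: int
    fraction_covered: float
    per_gene: dict[str, tuple[str, int, int]]  # gene -> (rep, covered, total)
    min_overlap: int
    mode: str
    n_genes_skipped: int = 0


def coverage_estimate(
    annotation: AnnotationSet,
    representatives: Mapping[str, str],
    min_overlap: int = 50,
    mode: str = "specified",
    overlap_fn=exonic_overlap,
) -> CoverageReport:
    """Count isoforms sharing >= min_overlap bp with their gene's representative.

    The representative itself always counts as covered: a probe trivially
    captures its own template, even if the template is shorter than the
    threshold. Genes absent from ``representatives`` are skipped and
    counted in ``n_genes_skipped``. Any coding/basic filtering is applied
    by the caller beforehand.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    per_gene: dict[str, tuple[str, int, int]] = {}
    n_isoforms = n_covered = 0
    n_skipped = 0
    for gene_id in sorted(annotation.genes):
        tids = annotation.genes[gene_id]
        rep_id = representatives.get(gene_id)
        if rep_id is None:
            n_skipped += 1
            continue
        rep = annotation.transcripts[rep_id]
        covered = 0
        for tid in tids:
            if tid == rep_id or overlap_fn(rep, annotation.transcripts[tid]) >= min_overlap:
                covered += 1
        per_gene[gene_id] = (rep_id, covered, len(tids))
        n_isoforms += len(tids)
        n_covered += covered
    fraction = n_covered / n_isoforms if n_isoforms else float("nan")
    return CoverageReport(
        n_genes=len(per_gene),
        n_isoforms=n_isoforms,
        n_covered=n_covered,
        fraction_covered=fraction,
        per_gene=per_gene,
        min_overlap=min_overlap,
        mode=mode,
        n_genes_skipped=n_skipped,
    )
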