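"""Synthetic targeted full-length cDNA capture experiment with known truth.

Generates, under one seed: a small genome with multi-isoform gene models
(exon skipping, alternative donors/acceptors, intron retention,
alternative first exons; GT..AG sense dinucleotides by construction),
per-transcript expression spanning a configurable dynamic range,
overlap-dependent capture enrichment with constant off-target background,
barcoded full-length long reads with a controllable PCR-chimera rate and
non-full-length fraction, and Poisson short-read junction coverage.

Capture efficiency is piecewise-linear in template overlap: flat at
``p_on`` above ``overlap_full`` (default 45 nt), at background ``p_bg``
below ``overlap_floor`` (default 35 nt), linear in between — the simplest
curve consistent with spike-in measurements showing full efficiency from
45 nt up and a sharp decline at 35 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .capture_coverage import exonic_overlap, select_representative
from .genomic_model import (
    AnnotationSet,
    GenomeRef,
    Interval,
    TranscriptModel,
)

TOTAL_TPM = 1e6


@dataclass
class ExpressionProfile:
    """TPM-like transcript abundances, normalized to 1e6."""

    abundance: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.fromiter(self.abundance.values(), dtype=float)
        if (vals < 0).any():
            raise ValueError("abundances must be non-negative")
        total = vals.sum()
        if abs(total - TOTAL_TPM) > 1e-9 * TOTAL_TPM:
            raise ValueError(f"abundances must sum to 1e6, got {total}")

    @classmethod
    def normalize(cls, raw: dict[str, float]) -> "ExpressionProfile":
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("total abundance must be positive")
        return cls({k: v * TOTAL_TPM / total for k, v in raw.items()})


@dataclass
class CaptureDesign:
    """Targeted genes, one probe-template transcript per gene, and the
    probe-set representation (TPM-like) of each target."""

    targets: set[str]
    template: dict[str, str]
    probe_tpm: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.template) != set(self.targets):
            raise ValueError("every target needs exactly one template")
        if not set(self.probe_tpm) <= set(self.targets):
            raise ValueError("probe_tpm keys must be targets")


@dataclass
class CaptureModel:
    """Overlap-dependent retention model.

    p_on: retention probability for fully-overlapping targets.
    p_bg: off-target (background) retention probability.
    Efficiency is p_on at >= overlap_full nt of template overlap, p_bg
    below overlap_floor, linear between. k_offtarget_abundance optionally
    scales background with log10 relative abundance (default 0: constant
    background).
    """

    p_on: float = 0.5
    p_bg: float = 0.005
    overlap_full: int = 45
    overlap_floor: int = 35
    k_offtarget_abundance: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.p_on <= 1:
            raise ValueError("p_on must be in (0, 1]")
        if not 0 <= self.p_bg < 1:
            raise ValueError("p_bg must be in [0, 1)")
        if self.p_bg > self.p_on:
            raise ValueError("p_bg must not exceed p_on")
        if self.overlap_floor >= self.overlap_full:
            raise ValueError("overlap_floor must be < overlap_full")

    def efficiency(self, overlap_nt: int) -> float:
        if overlap_nt >= self.overlap_full:
            return self.p_on
        if overlap_nt < self.overlap_floor:
            return self.p_bg
        frac = (overlap_nt - self.overlap_floor) / (
            self.overlap_full - self.overlap_floor
        )
        return self.p_bg + (self.p_on - self.p_bg) * frac


@dataclass
class LongReadRecord:
    read_id: str
    sample_barcode: Optional[str]
    has_5p_primer: bool
    has_3p_primer: bool
    has_polyA: bool
    inner_5p_barcode: Optional[str]
    inner_3p_barcode: Optional[str]
    contig: Optional[str]
    strand: Optional[str]
    blocks: Optional[tuple[Interval, ...]]
    truth_transcript_id: str
    truth_chimera: bool
    truth_partner_id: Optional[str] = None


# ---------------------------------------------------------------------------
# Annotation / genome generation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _alt_isoforms(
    principal_exons: list[Interval],
    n_alts: int,
    rng: np.random.Generator,
    intron_len_range: tuple[int, int],
) -> list[tuple[str, list[Interval]]]:
    """Derive alternative exon structures from a principal transcript.

    Variant classes: exon skipping, alternative donor/acceptor (3-30 nt
    shifts), intron retention, alternative first exon. Duplicate chains
    are discarded.
    """
    variants: list[tuple[str, list[Interval]]] = []
    seen_chains = {tuple((principal_exons[i][1], principal_exons[i + 1][0])
                         for i in range(len(principal_exons) - 1))}
    attempts = 0
    while len(variants) < n_alts and attempts < n_alts * 20:
        attempts += 1
        exons = [list(e) for e in principal_exons]
        kinds = ["skip", "alt_donor", "alt_acceptor", "retention", "alt_first"]
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "skip" and len(exons) >= 3:
            i = 1 + int(rng.integers(len(exons) - 2))
            del exons[i]
        elif kind == "alt_donor" and len(exons) >= 2:
            i = int(rng.integers(len(exons) - 1))  # exon whose end is a donor
            delta = int(rng.integers(3, 31)) * (1 if rng.random() < 0.5 else -1)
            new_end = exons[i][1] + delta
            intron_len = exons[i + 1][0] - new_end
            if new_end - exons[i][0] < 10 or intron_len < max(10, intron_len_range[0] // 2):
                continue
            exons[i][1] = new_end
        elif kind == "alt_acceptor" and len(exons) >= 2:
            i = 1 + int(rng.integers(len(exons) - 1))  # exon whose start is an acceptor
            delta = int(rng.integers(3, 31)) * (1 if rng.random() < 0.5 else -1)
            new_start = exons[i][0] + delta
            intron_len = new_start - exons[i - 1][1]
            if exons[i][1] - new_start < 10 or intron_len < max(10, intron_len_range[0] // 2):
                continue
            exons[i][0] = new_start
        elif kind == "retention" and len(exons) >= 2:
            i = int(rng.integers(len(exons) - 1))
            exons[i][1] = exons[i + 1][1]
            del exons[i + 1]
        elif kind == "alt_first" and len(exons) >= 2:
            # new first exon upstream of the original, spliced to exon 2
            gap = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
            length = int(rng.integers(50, 151))
            new_end = exons[0][0] - gap
            new_start = new_end - length
            if new_start < 1:
                continue
            exons[0] = [new_start, new_end]
        else:
            continue
        chain = tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))
        if chain in seen_chains:
            continue
        seen_chains.add(chain)
        variants.append((kind, [tuple(e) for e in exons]))
    return variants


def simulate_annotation(
    n_genes: int = 20,
    isoforms_per_gene_range: tuple[int, int] = (1, 8),
    exons_per_transcript_range: tuple[int, int] = (3, 12),
    exon_len_range: tuple[int, int] = (80, 300),
    intron_len_range: tuple[int, int] = (60, 500),
    seed: int = 0,
) -> tuple[GenomeRef, AnnotationSet]:
    """Generate one contig per gene with a principal transcript plus derived
    alternative isoforms; sense splice dinucleotides are GT..AG by
    construction (CT..AC on the genomic plus strand for minus-strand genes).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi in (
        isoforms_per_gene_range,
        exons_per_transcript_range,
        exon_len_range,
        intron_len_range,
    ):
        if lo < 1 or hi < lo:
            raise ValueError("ranges must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    flank = 400
    models: list[TranscriptModel] = []
    contigs: dict[str, str] = {}
    for g in range(n_genes):
        gene_id = f"G{g:04d}"
        contig = f"ctg{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(exons_per_transcript_range[0],
                                   exons_per_transcript_range[1] + 1))
        pos = flank
        exons: list[Interval] = []
        for i in range(n_exons):
            elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                pos += int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        n_iso = int(rng.integers(isoforms_per_gene_range[0],
                                 isoforms_per_gene_range[1] + 1))
        alts = _alt_isoforms(exons, n_iso - 1, rng, intron_len_range)
        tx_structs = [("principal", exons)] + alts
        contig_len = max(e for ex in tx_structs for _, e in ex[1]) + flank
        seq = _BASES[rng.integers(0, 4, size=contig_len)].copy()
        # stamp splice dinucleotides for every intron of every isoform
        ok_structs = []
        writes: dict[int, int] = {}
        for kind, ex in tx_structs:
            introns = [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]
            planned: list[tuple[int, int]] = []
            for s, e in introns:
                dinucs = ((s, b"GT"), (e - 2, b"AG")) if strand == "+" else (
                    (s, b"CT"), (e - 2, b"AC"))
                for p0, pair in dinucs:
                    planned.append((p0, pair[0]))
                    planned.append((p0 + 1, pair[1]))
            conflict = any(p in writes and writes[p] != b for p, b in planned)
            if conflict:
                continue
            for p, b in planned:
                writes[p] = b
            ok_structs.append((kind, ex))
        for p, b in writes.items():
            seq[p] = b
        contigs[contig] = seq.tobytes().decode("ascii")
        for k, (kind, ex) in enumerate(ok_structs):
            tid = f"{gene_id}.T{k:02d}"
            tags = {"basic"}
            if kind == "principal":
                tags.add("appris_principal")
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    contig=contig,
                    strand=strand,
                    exons=tuple(ex),
                    tags=frozenset(tags),
                    tsl=int(rng.integers(1, 6)),
                    coding=True,
                )
            )
    return GenomeRef(contigs), AnnotationSet.build(models)


def simulate_expression(
    annotation: AnnotationSet,
    log10_range: float = 6.0,
    seed: int = 0,
) -> ExpressionProfile:
    """Per-gene abundances log-uniform over ``log10_range`` orders of
    magnitude, split across isoforms by a flat Dirichlet, normalized to 1e6."""
    if log10_range <= 0:
        raise ValueError("log10_range must be positive")
    if not annotation.transcripts:
        raise ValueError("annotation is empty")
    rng = np.random.default_rng(seed)
    raw: dict[str, float] = {}
    for gene_id in sorted(annotation.genes):
        tids = sorted(annotation.genes[gene_id])
        gene_ab = 10.0 ** rng.uniform(0.0, log10_range)
        split = rng.dirichlet(np.ones(len(tids)))
        for tid, frac in zip(tids, split):
            raw[tid] = gene_ab * float(frac)
    return ExpressionProfile.normalize(raw)


def design_capture(
    annotation: AnnotationSet,
    targets: Optional[Iterable[str]] = None,
    n_targets: Optional[int] = None,
    probe_tpm_log10_range: tuple[float, float] = (-1.0, 2.0),
    seed: int = 0,
) -> CaptureDesign:
    """Build a one-template-per-gene capture design.

    Targets default to a random subset of ``n_targets`` genes. The template
    is the APPRIS principal transcript (longest as fallback). Probe
    representation is log-uniform over ``probe_tpm_log10_range``.
    """
    rng = np.random.default_rng(seed)
    all_genes = sorted(annotation.genes)
    if targets is None:
        if n_targets is None:
            raise ValueError("give either targets or n_targets")
        if n_targets > len(all_genes):
            raise ValueError("n_targets exceeds gene count")
        targets = [all_genes[i] for i in sorted(
            rng.choice(len(all_genes), size=n_targets, replace=False))]
    targets = sorted(set(targets))
    missing = [g for g in targets if g not in annotation.genes]
    if missing:
        raise ValueError(f"targets not in annotation: {missing}")
    reps = select_representative(annotation, mode="appris", missing_appris="longest")
    template = {g: reps[g] for g in targets}
    lo, hi = probe_tpm_log10_range
    probe_tpm = {g: float(10.0 ** rng.uniform(lo, hi)) for g in targets}
    return CaptureDesign(targets=set(targets), template=template, probe_tpm=probe_tpm)


def transcript_efficiencies(
    design: CaptureDesign,
    model: CaptureModel,
    annotation: AnnotationSet,
) -> dict[str, float]:
    """Deterministic capture efficiency of every annotated transcript."""
    eff: dict[str, float] = {}
    for tid, t in annotation.transcripts.items():
        if t.gene_id in design.targets:
            template_id = design.template[t.gene_id]
            if template_id not in annotation.transcripts:
                raise ValueError(f"template {template_id!r} absent from annotation")
            ov = exonic_overlap(annotation.transcripts[template_id], t)
            eff[tid] = model.efficiency(ov)
        else:
            eff[tid] = model.p_bg
    return eff


def simulate_capture(
    profile: ExpressionProfile,
    design: CaptureDesign,
    model: CaptureModel,
    annotation: AnnotationSet,
    seed: int = 0,
) -> ExpressionProfile:
    """Apply the overlap-dependent retention model to an expression profile.

    The baseline model is deterministic (the seed is reserved for optional
    noise extensions): post-capture abundance is proportional to
    pre-capture abundance times efficiency, renormalized to 1e6. The
    optional ``k_offtarget_abundance`` knob scales background retention
    with log10 relative abundance.
    """
    eff = transcript_efficiencies(design, model, annotation)
    k = model.k_offtarget_abundance
    raw: dict[str, float] = {}
    for tid, ab in profile.abundance.items():
        e = eff.get(tid, model.p_bg)
        if k != 0.0 and annotation.transcripts[tid].gene_id not in design.targets:
            rel = max(ab, 1e-12) / TOTAL_TPM
            e = max(0.0, e * (1.0 + k * np.log10(rel * len(profile.abundance))))
        raw[tid] = ab * e
    return ExpressionProfile.normalize(raw)


def simulate_long_reads(
    profile: ExpressionProfile,
    annotation: AnnotationSet,
    n_reads: int = 10000,
    fl_rate: float = 0.9,
    chimera_rate: float = 0.02,
    sample_barcodes: Sequence[str] = ("bc01",),
    dual_barcode_pairs: Optional[Sequence[tuple[str, str]]] = None,
    seed: int = 0,
) -> list[LongReadRecord]:
    """Draw barcoded long reads proportional to abundance.

    A chimera (probability ``chimera_rate``) joins the 5' portion of
    molecule A to the 3' portion of an independently drawn molecule B, so
    its inner barcodes come from two molecules; its aligned blocks are
    those of the 5' molecule. A non-full-length read (probability
    ``1 - fl_rate``) drops exactly one of {5' primer, 3' primer, polyA}.
    """
    if not 0 <= fl_rate <= 1 or not 0 <= chimera_rate <= 1:
        raise ValueError("fl_rate and chimera_rate must be in [0, 1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not sample_barcodes:
        raise ValueError("sample_barcodes must be non-empty")
    if dual_barcode_pairs is not None and len(dual_barcode_pairs) == 0:
        raise ValueError("dual barcoding requested with empty pair list")
    rng = np.random.default_rng(seed)
    tids = sorted(profile.abundance)
    p = np.array([profile.abundance[t] for t in tids], dtype=float)
    p /= p.sum()
    src = rng.choice(len(tids), size=n_reads, p=p)
    partner = rng.choice(len(tids), size=n_reads, p=p)
    is_chim = rng.random(n_reads) < chimera_rate
    samples = rng.integers(0, len(sample_barcodes), size=n_reads)
    is_fl = rng.random(n_reads) < fl_rate
    dropped = rng.integers(0, 3, size=n_reads)
    if dual_barcode_pairs is not None:
        pair_a = rng.integers(0, len(dual_barcode_pairs), size=n_reads)
        pair_b = rng.integers(0, len(dual_barcode_pairs), size=n_reads)
    reads: list[LongReadRecord] = []
    for i in range(n_reads):
        tid = tids[src[i]]
        t = annotation.transcripts[tid]
        chim = bool(is_chim[i])
        partner_id = tids[partner[i]] if chim else None
        flags = [True, True, True]  # 5p, 3p, polyA
        if not is_fl[i]:
            flags[dropped[i]] = False
        if dual_barcode_pairs is not None:
            b5 = dual_barcode_pairs[pair_a[i]][0]
            b3 = dual_barcode_pairs[pair_b[i] if chim else pair_a[i]][1]
        else:
            b5 = b3 = None
        reads.append(
            LongReadRecord(
                read_id=f"read{i:07d}",
                sample_barcode=sample_barcodes[samples[i]],
                has_5p_primer=flags[0],
                has_3p_primer=flags[1],
                has_polyA=flags[2],
                inner_5p_barcode=b5,
                inner_3p_barcode=b3,
                contig=t.contig,
                strand=t.strand,
                blocks=t.exons,
                truth_transcript_id=tid,
                truth_chimera=chim,
                truth_partner_id=partner_id,
            )
        )
    return reads


def simulate_short_read_junction_counts(
    profile: ExpressionProfile,
    annotation: AnnotationSet,
    mean_depth: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson junction coverage: count_j ~ Poisson(mean_depth * mass_j)
    where mass_j is the relative abundance of transcripts containing j."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    mass: dict[tuple, float] = {j: 0.0 for j in annotation.junction_catalog}
    for tid, t in annotation.transcripts.items():
        ab = profile.abundance.get(tid, 0.0)
        for s, e in t.introns():
            mass[(t.contig, t.strand, s, e)] += ab / TOTAL_TPM
    rows = []
    for j in sorted(mass):
        lam = mean_depth * mass[j]
        count = int(rng.poisson(lam)) if lam > 0 else 0
        rows.append({"contig": j[0], "start": j[2], "end": j[3],
                     "strand": j[1], "count": count})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "count"])


# ---------------------------------------------------------------------------
# Table I/O for the simulated objects

_READ_COLUMNS = [
    "read_id", "sample_barcode", "has_5p_primer", "has_3p_primer", "has_polyA",
    "inner_5p_barcode", "inner_3p_barcode", "contig", "strand", "blocks",
    "truth_transcript_id", "truth_chimera", "truth_partner_id",
]


def _blocks_to_str(blocks: Optional[tuple[Interval, ...]]) -> str:
    if blocks is None:
        return "."
    return ";".join(f"{s}-{e}" for s, e in blocks)


def _blocks_from_str(s: str) -> Optional[tuple[Interval, ...]]:
    if s in (".", "", "nan"):
        return None
    return tuple(tuple(map(int, part.split("-"))) for part in s.split(";"))


def write_reads_tsv(reads: Sequence[LongReadRecord], path) -> None:
    rows = []
    for r in reads:
        rows.append({
            "read_id": r.read_id,
            "sample_barcode": r.sample_barcode or ".",
            "has_5p_primer": int(r.has_5p_primer),
            "has_3p_primer": int(r.has_3p_primer),
            "has_polyA": int(r.has_polyA),
            "inner_5p_barcode": r.inner_5p_barcode or ".",
            "inner_3p_barcode": r.inner_3p_barcode or ".",
            "contig": r.contig or ".",
            "strand": r.strand or ".",
            "blocks": _blocks_to_str(r.blocks),
            "truth_transcript_id": r.truth_transcript_id,
            "truth_chimera": int(r.truth_chimera),
            "truth_partner_id": r.truth_partner_id or ".",
        })
    pd.DataFrame(rows, columns=_READ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> list[LongReadRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    reads = []
    for row in df.itertuples(index=False):
        reads.append(LongReadRecord(
            read_id=row.read_id,
            sample_barcode=None if row.sample_barcode == "." else row.sample_barcode,
            has_5p_primer=bool(int(row.has_5p_primer)),
            has_3p_primer=bool(int(row.has_3p_primer)),
            has_polyA=bool(int(row.has_polyA)),
            inner_5p_barcode=None if row.inner_5p_barcode == "." else row.inner_5p_barcode,
            inner_3p_barcode=None if row.inner_3p_barcode == "." else row.inner_3p_barcode,
            contig=None if row.contig == "." else row.contig,
            strand=None if row.strand == "." else row.strand,
            blocks=_blocks_from_str(row.blocks),
            truth_transcript_id=row.truth_transcript_id,
            truth_chimera=bool(int(row.truth_chimera)),
            truth_partner_id=None if row.truth_partner_id == "." else row.truth_partner_id,
        ))
    return reads


def write_expression_tsv(profile: ExpressionProfile, path) -> None:
    pd.DataFrame(
        sorted(profile.abundance.items()), columns=["transcript_id", "tpm"]
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ExpressionProfile.normalize(dict(zip(df["transcript_id"], df["tpm"])))


def write_junction_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_junction_counts_tsv(path) -> dict[tuple[str, int, int, str], int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        (r.contig, int(r.start), int(r.end), r.strand): int(r.count)
        for r in df.itertuples(index=False)
    }


DEFAULT_5P_PRIMER = "AAGCAGTGGTATCAACGCAGAGTACATGGG"  # SMARTer-style with ATGGG overhang
DEFAULT_3P_PRIMER = "GTACTCTGCGTTGATACCACTGCTT"


def emit_read_fasta(
    reads: Sequence[LongReadRecord],
    genome: GenomeRef,
    path,
    polya_len: int = 30,
) -> None:
    """Optional literal-sequence emitter: primer + barcode + spliced
    transcript sequence + polyA tail, honoring the per-read flag anatomy.
    Classification operates on exon blocks; this exists for interface tests."""
    from .genomic_model import reverse_complement

    with open(path, "w") as fh:
        for r in reads:
            if r.blocks is None:
                continue
            parts = []
            if r.has_5p_primer:
                parts.append(DEFAULT_5P_PRIMER)
            if r.inner_5p_barcode:
                parts.append(r.inner_5p_barcode)
            body = "".join(genome.fetch(r.contig, s, e) for s, e in r.blocks)
            if r.strand == "-":
                body = reverse_complement(body)
            parts.append(body)
            if r.inner_3p_barcode:
                parts.append(r.inner_3p_barcode)
            if r.has_polyA:
                parts.append("A" * polya_len)
            if r.has_3p_primer:
                parts.append((r.sample_barcode or "") + DEFAULT_3P_PRIMER)
            fh.write(f">{r.read_id}\n{''.join(parts)}\n")


def default_dual_barcode_pairs(n_pairs: int = 96) -> list[tuple[str, str]]:
    """Deterministic matched 5'/3' inner barcode pairs (dbc00..)."""
    return [(f"dbc{i:02d}F", f"dbc{i:02d}R") for i in range(n_pairs)]


def holdout_novel_isoforms(
    annotation: AnnotationSet,
    fraction: float = 0.25,
    seed: int = 0,
    protect: Optional[set[str]] = None,
) -> tuple[AnnotationSet, set[str]]:
    """Split truth from reference: remove a fraction of alternative
    (non-principal) isoforms from the reference catalog while they remain
    expressed, emulating transcripts the annotation has not yet caught up
    with. Principal isoforms and ids in ``protect`` are never held out.
    Returns (reference annotation, held-out transcript ids)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    protect = protect or set()
    rng = np.random.default_rng(seed)
    candidates = sorted(
        tid
        for tid, t in annotation.transcripts.items()
        if "appris_principal" not in t.tags and tid not in protect
    )
    n_hold = int(round(fraction * len(candidates)))
    heldout = set(
        candidates[i]
        for i in rng.choice(len(candidates), size=n_hold, replace=False)
    ) if n_hold else set()
    reference = annotation.subset(
        tid for tid in annotation.transcripts if tid not in heldout
    )
    return reference, heldout


def simulate_cage_peaks(
    annotation: AnnotationSet, halfwidth: int = 25
) -> dict[str, list[Interval]]:
    """CAGE-like TSS peaks: one interval of +/- halfwidth around each
    annotated transcript 5' end (merged per contig by the consumer)."""
    peaks: dict[str, list[Interval]] = {}
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        tss = t.five_prime
        peaks.setdefault(t.contig, []).append(
            (max(0, tss - halfwidth), tss + halfwidth + 1)
        )
    return {c: sorted(set(ivs)) for c, ivs in peaks.items()}


def simulate_conservation_track(
    annotation: AnnotationSet, halfwidth: int = 10, score: float = 1.5
) -> dict[str, list[tuple[int, int, float]]]:
    """Conservation-like coverage: constant elevated score in +/- halfwidth
    windows around every annotated splice-site boundary; positions outside
    the windows are uncovered (missing), mirroring sparse score tracks."""
    ivs: dict[str, set[tuple[int, int, float]]] = {}
    for contig, _strand, s, e in annotation.junction_catalog:
        for pos in (s, e):
            ivs.setdefault(contig, set()).add(
                (max(0, pos - halfwidth), pos + halfwidth, score)
            )
    merged: dict[str, list[tuple[int, int, float]]] = {}
    for contig, entries in ivs.items():
        out: list[list] = []
        for s, e, v in sorted(entries):
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e, v])
        merged[contig] = [(s, e, v) for s, e, v in out]
    return merged
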