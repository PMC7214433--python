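"""Collapse aligned full-length reads into isoforms and classify them
against a reference annotation, SQANTI-style.

Multi-exon decision order: FSM (chain identical to a reference chain),
ISM (consecutive sub-chain of a reference chain), NIC (all junctions
annotated, or all splice sites annotated with >=1 novel junction), NNC
(>=1 novel splice site). Mono-exonic isoforms are matched by exon
containment (known) or gene-footprint overlap (novel); otherwise
intergenic. Splice-site novelty is position+side+strand specific: a donor
at a coordinate annotated only as an acceptor counts as novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .capture_coverage import exonic_overlap
from .genomic_model import (
    AnnotationSet,
    GenomeRef,
    Interval,
    TranscriptModel,
    reverse_complement,
    splice_sites_of_intron,
)
from .synthetic_data import ExpressionProfile, LongReadRecord

FSM = "FSM"
ISM = "ISM"
NIC = "NIC"
NNC = "NNC"
MONO_KNOWN = "mono-exon-known"
MONO_NOVEL = "mono-exon-novel"
INTERGENIC = "intergenic"

NOVEL_CATEGORIES = frozenset({NIC, NNC, MONO_NOVEL, INTERGENIC})

CANONICAL_DINUCS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})


@dataclass
class AlignedIsoform:
    isoform_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    fl_counts: dict[str, int] = field(default_factory=dict)
    member_reads: list[str] = field(default_factory=list)
    coverage: float = 1.0
    identity: float = 1.0

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def total_fl_count(self) -> int:
        return sum(self.fl_counts.values())

    def as_transcript(self) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=self.isoform_id,
            gene_id=self.isoform_id,
            contig=self.contig,
            strand=self.strand,
            exons=self.exons,
        )


@dataclass
class ClassificationRecord:
    isoform_id: str
    category: str
    subcategory: Optional[str] = None
    matched_transcript_id: Optional[str] = None
    matched_gene_id: Optional[str] = None
    novel_junctions: list[tuple[int, int]] = field(default_factory=list)
    novel_splice_sites: list[tuple[int, str]] = field(default_factory=list)
    intron_retention: bool = False
    all_canonical: Optional[bool] = None

    @property
    def is_novel(self) -> bool:
        return self.category in NOVEL_CATEGORIES


# ---------------------------------------------------------------------------
# Filtering and collapsing


def filter_alignments(
    isoforms: Iterable[AlignedIsoform],
    min_coverage: float = 0.99,
    min_identity: float = 0.95,
    target_regions: Optional[Mapping[str, Sequence[Interval]]] = None,
) -> list[AlignedIsoform]:
    """Keep isoforms aligned with >= min_coverage of the query and
    >= min_identity matches (inclusive thresholds), optionally restricted
    to those whose exonic footprint intersects ``target_regions``."""
    for name, v in (("min_coverage", min_coverage), ("min_identity", min_identity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    kept = []
    for iso in isoforms:
        if iso.coverage < min_coverage or iso.identity < min_identity:
            continue
        if target_regions is not None:
            regions = target_regions.get(iso.contig, ())
            hit = any(
                max(s, rs) < min(e, re_)
                for s, e in iso.exons
                for rs, re_ in regions
            )
            if not hit:
                continue
        kept.append(iso)
    return kept


def collapse_reads(reads: Iterable[LongReadRecord]) -> list[AlignedIsoform]:
    """Group aligned FL reads into distinct isoforms.

    Multi-exon reads collapse on identical (contig, strand, junction
    chain); the representative exons span the 5'-most start and 3'-most
    end among members (genomically: min start / max end). Mono-exon reads
    collapse by single-linkage interval overlap on the same contig and
    strand. FL counts tally per sample barcode.
    """
    multi: dict[tuple, list[LongReadRecord]] = {}
    mono: dict[tuple[str, str], list[LongReadRecord]] = {}
    for r in reads:
        if r.blocks is None:
            continue
        if len(r.blocks) > 1:
            chain = tuple(
                (r.blocks[i][1], r.blocks[i + 1][0])
                for i in range(len(r.blocks) - 1)
            )
            multi.setdefault((r.contig, r.strand, chain), []).append(r)
        else:
            mono.setdefault((r.contig, r.strand), []).append(r)

    out: list[AlignedIsoform] = []
    idx = 0
    for (contig, strand, chain) in sorted(multi, key=lambda k: (k[0], k[1], k[2])):
        members = multi[(contig, strand, chain)]
        start = min(r.blocks[0][0] for r in members)
        end = max(r.blocks[-1][1] for r in members)
        bounds = [start] + [x for intron in chain for x in intron] + [end]
        exons = tuple(
            (bounds[2 * i], bounds[2 * i + 1]) for i in range(len(bounds) // 2)
        )
        out.append(_make_isoform(f"ISO{idx:05d}", contig, strand, exons, members))
        idx += 1
    for (contig, strand) in sorted(mono):
        group = sorted(mono[(contig, strand)], key=lambda r: r.blocks[0])
        cluster: list[LongReadRecord] = []
        cluster_end = None
        for r in group:
            s, e = r.blocks[0]
            if cluster and s >= cluster_end:
                out.append(_mono_isoform(f"ISO{idx:05d}", contig, strand, cluster))
                idx += 1
                cluster = []
                cluster_end = None
            cluster.append(r)
            cluster_end = e if cluster_end is None else max(cluster_end, e)
        if cluster:
            out.append(_mono_isoform(f"ISO{idx:05d}", contig, strand, cluster))
            idx += 1
    return out


def _make_isoform(iso_id, contig, strand, exons, members) -> AlignedIsoform:
    fl_counts: dict[str, int] = {}
    for r in members:
        key = r.sample_barcode or "sample"
        fl_counts[key] = fl_counts.get(key, 0) + 1
    return AlignedIsoform(
        isoform_id=iso_id,
        contig=contig,
        strand=strand,
        exons=exons,
        fl_counts=fl_counts,
        member_reads=[r.read_id for r in members],
    )


def _mono_isoform(iso_id, contig, strand, members) -> AlignedIsoform:
    start = min(r.blocks[0][0] for r in members)
    end = max(r.blocks[0][1] for r in members)
    return _make_isoform(iso_id, contig, strand, ((start, end),), members)


# ---------------------------------------------------------------------------
# Classification


class ReferenceIndex:
    """Precomputed lookups over an AnnotationSet for classification."""

    def __init__(self, annotation: AnnotationSet):
        self.annotation = annotation
        self.chain_to_tx: dict[tuple, list[str]] = {}
        self.gene_junctions: dict[str, set[tuple[int, int]]] = {}
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            chain = (t.contig, t.strand, t.introns())
            self.chain_to_tx.setdefault(chain, []).append(tid)
            self.gene_junctions.setdefault(t.gene_id, set()).update(t.introns())

    def find_fsm(self, contig: str, strand: str, chain: tuple) -> Optional[str]:
        hits = self.chain_to_tx.get((contig, strand, chain))
        return hits[0] if hits else None

    def find_ism(self, contig: str, strand: str, chain: tuple) -> Optional[str]:
        n = len(chain)
        best = None
        for (c, s, ref_chain), tids in self.chain_to_tx.items():
            if c != contig or s != strand or len(ref_chain) <= n:
                continue
            for i in range(len(ref_chain) - n + 1):
                if ref_chain[i:i + n] == chain:
                    cand = tids[0]
                    if best is None or cand < best:
                        best = cand
                    break
        return best


def _assign_gene(
    iso: AlignedIsoform, annotation: AnnotationSet
) -> Optional[str]:
    """Gene with maximal shared junctions; ties broken by exonic overlap,
    then lexicographic gene_id."""
    iso_tx = iso.as_transcript()
    iso_junc = set(iso.introns())
    best = None
    best_key = None
    for gene_id in sorted(annotation.genes):
        shared = 0
        overlap = 0
        for tid in annotation.genes[gene_id]:
            t = annotation.transcripts[tid]
            if t.contig != iso.contig or t.strand != iso.strand:
                continue
            shared = max(shared, len(iso_junc & set(t.introns())))
            overlap = max(overlap, exonic_overlap(iso_tx, t))
        if shared == 0 and overlap == 0:
            continue
        key = (-shared, -overlap, gene_id)
        if best_key is None or key < best_key:
            best_key = key
            best = gene_id
    return best


def classify_isoform(
    iso: AlignedIsoform,
    annotation: AnnotationSet,
    index: Optional[ReferenceIndex] = None,
    genome: Optional[GenomeRef] = None,
) -> ClassificationRecord:
    """Assign the structural category of one aligned isoform."""
    if index is None:
        index = ReferenceIndex(annotation)
    chain = iso.introns()
    matched_gene = _assign_gene(iso, annotation)

    if len(iso.exons) == 1:
        rec = _classify_mono(iso, annotation, matched_gene)
    else:
        rec = _classify_multi(iso, annotation, index, chain, matched_gene)

    if matched_gene is not None and rec.category != FSM:
        rec.intron_retention = detect_intron_retention(iso, annotation, matched_gene)
    if genome is not None and chain:
        rec.all_canonical = all(
            _dinucs(iso.contig, iso.strand, j, genome) in CANONICAL_DINUCS
            for j in chain
        )
    return rec


def _classify_multi(iso, annotation, index, chain, matched_gene):
    fsm = index.find_fsm(iso.contig, iso.strand, chain)
    if fsm is not None:
        return ClassificationRecord(
            isoform_id=iso.isoform_id,
            category=FSM,
            matched_transcript_id=fsm,
            matched_gene_id=annotation.transcripts[fsm].gene_id,
        )
    ism = index.find_ism(iso.contig, iso.strand, chain)
    if ism is not None:
        return ClassificationRecord(
            isoform_id=iso.isoform_id,
            category=ISM,
            matched_transcript_id=ism,
            matched_gene_id=annotation.transcripts[ism].gene_id,
        )
    novel_junctions = [
        j
        for j in chain
        if (iso.contig, iso.strand, j[0], j[1]) not in annotation.junction_catalog
    ]
    novel_sites: list[tuple[int, str]] = []
    for j in chain:
        donor, acceptor = splice_sites_of_intron(iso.contig, iso.strand, j)
        for site in (donor, acceptor):
            if site not in annotation.splice_site_catalog:
                novel_sites.append((site[2], site[3]))
    if not novel_junctions:
        cat, sub = NIC, "combination_of_known_junctions"
    elif not novel_sites:
        cat, sub = NIC, "novel_junction_from_known_sites"
    else:
        cat, sub = NNC, "novel_splice_site"
    return ClassificationRecord(
        isoform_id=iso.isoform_id,
        category=cat,
        subcategory=sub,
        matched_gene_id=matched_gene,
        novel_junctions=novel_junctions,
        novel_splice_sites=sorted(set(novel_sites)),
    )


def _classify_mono(iso, annotation, matched_gene):
    s, e = iso.exons[0]
    contained = None
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        if t.contig != iso.contig or t.strand != iso.strand:
            continue
        if any(es <= s and e <= ee for es, ee in t.exons):
            contained = tid
            break
    if contained is not None:
        return ClassificationRecord(
            isoform_id=iso.isoform_id,
            category=MONO_KNOWN,
            matched_transcript_id=contained,
            matched_gene_id=annotation.transcripts[contained].gene_id,
        )
    overlapping = matched_gene is not None
    if not overlapping:
        # gene footprint overlap on either strand still rescues from intergenic
        for gene_id in sorted(annotation.genes):
            for tid in annotation.genes[gene_id]:
                t = annotation.transcripts[tid]
                if t.contig == iso.contig and max(s, t.start) < min(e, t.end):
                    overlapping = True
                    matched_gene = gene_id
                    break
            if overlapping:
                break
    return ClassificationRecord(
        isoform_id=iso.isoform_id,
        category=MONO_NOVEL if overlapping else INTERGENIC,
        matched_gene_id=matched_gene if overlapping else None,
    )


def _dinucs(contig, strand, intron, genome: GenomeRef) -> tuple[str, str]:
    s, e = intron
    left = genome.fetch(contig, s, s + 2)
    right = genome.fetch(contig, e - 2, e)
    if strand == "+":
        return left, right
    return reverse_complement(right), reverse_complement(left)


def detect_intron_retention(
    iso: AlignedIsoform, annotation: AnnotationSet, gene_id: str
) -> bool:
    """True iff some exon of the isoform completely contains an annotated
    intron of the matched gene, overlapping both flanking reference exons."""
    for tid in annotation.genes.get(gene_id, []):
        t = annotation.transcripts[tid]
        if t.contig != iso.contig or t.strand != iso.strand:
            continue
        for i in range(len(t.exons) - 1):
            istart, iend = t.exons[i][1], t.exons[i + 1][0]
            for a, b in iso.exons:
                if a < istart and b > iend:
                    return True
    return False


# ---------------------------------------------------------------------------
# Reports


def recovery_statistics(
    records: Sequence[ClassificationRecord],
    isoforms: Mapping[str, AlignedIsoform],
    annotation: AnnotationSet,
    probe_tpm: Optional[Mapping[str, float]] = None,
    expression: Optional[ExpressionProfile] = None,
    probe_min: float = 1.0,
    expr_min: float = 10.0,
) -> pd.DataFrame:
    """Gene / isoform recovery fractions, optionally stratified.

    A gene is detected iff >= 1 FL read is assigned to the locus; a
    reference isoform is detected iff some observed isoform is an FSM to
    it. Strata: all genes, genes with probe representation >= probe_min,
    genes with expression >= expr_min (gene TPM = sum over transcripts),
    and the intersection of both.
    """
    detected_genes: set[str] = set()
    detected_tx: set[str] = set()
    for rec in records:
        iso = isoforms.get(rec.isoform_id)
        # an isoform without tallied per-sample counts still represents
        # at least the one read it was built from
        n_fl = iso.total_fl_count or 1 if iso is not None else 1
        if rec.matched_gene_id is not None and n_fl >= 1:
            detected_genes.add(rec.matched_gene_id)
        if rec.category == FSM and rec.matched_transcript_id is not None:
            detected_tx.add(rec.matched_transcript_id)

    gene_expr: dict[str, float] = {}
    if expression is not None:
        # expression of transcripts absent from the reference catalog
        # (unannotated isoforms) cannot be assigned to a locus; skipped
        for tid, ab in expression.abundance.items():
            t = annotation.transcripts.get(tid)
            if t is None:
                continue
            gene_expr[t.gene_id] = gene_expr.get(t.gene_id, 0.0) + ab

    def stratum(genes: set[str], name: str) -> dict:
        txs = [tid for g in genes for tid in annotation.genes[g]]
        n_gene_det = sum(1 for g in genes if g in detected_genes)
        n_tx_det = sum(1 for tid in txs if tid in detected_tx)
        return {
            "stratum": name,
            "n_genes": len(genes),
            "n_genes_detected": n_gene_det,
            "gene_recovery": n_gene_det / len(genes) if genes else float("nan"),
            "n_isoforms": len(txs),
            "n_isoforms_detected": n_tx_det,
            "isoform_recovery": n_tx_det / len(txs) if txs else float("nan"),
        }

    all_genes = set(annotation.genes)
    rows = [stratum(all_genes, "all")]
    if probe_tpm is not None:
        probe_ok = {g for g in all_genes if probe_tpm.get(g, 0.0) >= probe_min}
        rows.append(stratum(probe_ok, f"probe_tpm>={probe_min:g}"))
    if expression is not None:
        expr_ok = {g for g in all_genes if gene_expr.get(g, 0.0) >= expr_min}
        rows.append(stratum(expr_ok, f"expression>={expr_min:g}"))
    if probe_tpm is not None and expression is not None:
        rows.append(stratum(probe_ok & expr_ok, "probe_and_expression"))
    return pd.DataFrame(rows)


def novelty_summary(
    records: Sequence[ClassificationRecord],
    isoforms: Optional[Mapping[str, AlignedIsoform]] = None,
    annotation: Optional[AnnotationSet] = None,
) -> dict:
    """Distinct-element novelty fractions and category proportions.

    Splice sites and junctions are counted once each across all observed
    multi-exon isoforms; a site/junction is novel when absent from the
    reference catalogs. Isoform novelty = category not in
    {FSM, ISM, mono-exon-known}.
    """
    n = len(records)
    cats: dict[str, int] = {}
    subcats: dict[str, int] = {}
    n_ir = 0
    for rec in records:
        cats[rec.category] = cats.get(rec.category, 0) + 1
        if rec.subcategory:
            subcats[rec.subcategory] = subcats.get(rec.subcategory, 0) + 1
        if rec.intron_retention:
            n_ir += 1
    out = {
        "n_isoforms": n,
        "category_counts": cats,
        "category_proportions": {k: v / n for k, v in cats.items()} if n else {},
        "subcategory_counts": subcats,
        "novel_isoform_fraction": (
            sum(1 for r in records if r.is_novel) / n if n else float("nan")
        ),
        "intron_retention_fraction": n_ir / n if n else float("nan"),
    }
    if isoforms is not None and annotation is not None:
        all_junc: set[tuple] = set()
        all_sites: set[tuple] = set()
        for rec in records:
            iso = isoforms[rec.isoform_id]
            for j in iso.introns():
                all_junc.add((iso.contig, iso.strand, j[0], j[1]))
                d, a = splice_sites_of_intron(iso.contig, iso.strand, j)
                all_sites.add(d)
                all_sites.add(a)
        novel_junc = {j for j in all_junc if j not in annotation.junction_catalog}
        novel_sites = {s for s in all_sites if s not in annotation.splice_site_catalog}
        out["n_distinct_junctions"] = len(all_junc)
        out["n_distinct_splice_sites"] = len(all_sites)
        out["novel_junction_fraction"] = (
            len(novel_junc) / len(all_junc) if all_junc else float("nan")
        )
        out["novel_splice_site_fraction"] = (
            len(novel_sites) / len(all_sites) if all_sites else float("nan")
        )
        # TSL confirmation: FSM-matched reference models by support level
        tsl_counts: dict[int, int] = {}
        for rec in records:
            if rec.category == FSM and rec.matched_transcript_id:
                tsl = annotation.transcripts[rec.matched_transcript_id].tsl
                if tsl is not None:
                    tsl_counts[tsl] = tsl_counts.get(tsl, 0) + 1
        out["tsl_confirmations"] = tsl_counts
        out["tsl_2_to_5_confirmed"] = sum(
            v for k, v in tsl_counts.items() if k >= 2
        )
    return out


def classification_table(records: Sequence[ClassificationRecord],
                         isoforms: Mapping[str, AlignedIsoform]) -> pd.DataFrame:
    rows = []
    for rec in records:
        iso = isoforms[rec.isoform_id]
        rows.append({
            "isoform_id": rec.isoform_id,
            "contig": iso.contig,
            "strand": iso.strand,
            "n_exons": len(iso.exons),
            "category": rec.category,
            "subcategory": rec.subcategory or ".",
            "matched_transcript_id": rec.matched_transcript_id or ".",
            "matched_gene_id": rec.matched_gene_id or ".",
            "n_novel_junctions": len(rec.novel_junctions),
            "n_novel_splice_sites": len(rec.novel_splice_sites),
            "intron_retention": int(rec.intron_retention),
            "all_canonical": "." if rec.all_canonical is None else int(rec.all_canonical),
            "fl_count_total": iso.total_fl_count,
        })
    return pd.DataFrame(rows)
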