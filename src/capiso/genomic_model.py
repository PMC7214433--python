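"""Core genomic data types and flat-file I/O.

Coordinate convention: every interval in memory is 0-based, half-open
``(start, end)`` on the forward genomic strand. GTF (1-based, closed)
converts on read/write; BED-family formats are already half-open.
Junction chains are kept in ascending genomic order for both strands —
strand is metadata, which makes chain equality strand-safe.

Splice-site convention: a site is the genomic boundary coordinate of an
intron in half-open terms (left boundary = intron start, right boundary =
intron end). On '+' the left boundary is the donor, on '-' the right
boundary is.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Malformed GTF input; message names the offending line number."""


class Bed12ParseError(ValueError):
    """Malformed BED12 input (e.g. block sums inconsistent with blockCount)."""


class TrackError(ValueError):
    """bedGraph intervals overlap with conflicting values."""


def _check_exons(exons: Sequence[Interval]) -> tuple[Interval, ...]:
    if not exons:
        raise ValueError("transcript must have at least one exon")
    out = tuple((int(s), int(e)) for s, e in exons)
    prev_end = None
    for s, e in out:
        if s >= e:
            raise ValueError(f"empty or inverted exon ({s}, {e})")
        if prev_end is not None and s < prev_end:
            raise ValueError("exons must be disjoint and ascending")
        prev_end = e
    return out


@dataclass
class GenomeRef:
    """Reference sequences: contig name -> uppercase DNA (ACGTN)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the forward-strand sequence of [start, end), clipped to the contig."""
        seq = self.contigs[contig]
        return seq[max(0, start): max(0, end)]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    tags: frozenset[str] = frozenset()
    tsl: Optional[int] = None
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = _check_exons(self.exons)
        self.tags = frozenset(self.tags)
        if self.tsl is not None and not 1 <= int(self.tsl) <= 5:
            raise ValueError(f"tsl must be in 1..5, got {self.tsl}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def five_prime(self) -> int:
        """Genomic position (0-based) of the 5'-most transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic position (0-based) of the 3'-most transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class JunctionChain:
    """Ordered intron coordinates of a transcript; the splicing-level identity key.

    Empty for mono-exonic transcripts. Introns are ascending genomic order
    regardless of strand.
    """

    contig: str
    strand: str
    introns: tuple[Interval, ...]

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.introns:
            if s >= e:
                raise ValueError(f"empty or inverted intron ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("introns must be disjoint and ascending")
            prev_end = e

    def __len__(self) -> int:
        return len(self.introns)


def junction_chain(t: TranscriptModel) -> JunctionChain:
    """Derive the intron chain (gaps between consecutive exons) of a transcript."""
    return JunctionChain(contig=t.contig, strand=t.strand, introns=t.introns())


SpliceSite = tuple[str, str, int, str]  # (contig, strand, position, side)


def splice_sites_of_intron(
    contig: str, strand: str, intron: Interval
) -> tuple[SpliceSite, SpliceSite]:
    """Donor and acceptor site keys of one intron (strand-aware)."""
    s, e = intron
    if strand == "+":
        return (contig, strand, s, "donor"), (contig, strand, e, "acceptor")
    return (contig, strand, e, "donor"), (contig, strand, s, "acceptor")


Junction = tuple[str, str, int, int]  # (contig, strand, start, end)


@dataclass
class AnnotationSet:
    """A set of transcript models with derived junction / splice-site catalogs.

    The catalogs are exactly the union over member transcripts; they are
    rebuilt whenever the set is constructed via :meth:`build`.
    """

    transcripts: dict[str, TranscriptModel]
    genes: dict[str, list[str]]
    junction_catalog: set[Junction]
    splice_site_catalog: set[SpliceSite]

    @classmethod
    def build(cls, transcripts: Iterable[TranscriptModel]) -> "AnnotationSet":
        tdict: dict[str, TranscriptModel] = {}
        genes: dict[str, list[str]] = {}
        junctions: set[Junction] = set()
        sites: set[SpliceSite] = set()
        for t in transcripts:
            if t.transcript_id in tdict:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            tdict[t.transcript_id] = t
            genes.setdefault(t.gene_id, []).append(t.transcript_id)
            for intron in t.introns():
                junctions.add((t.contig, t.strand, intron[0], intron[1]))
                d, a = splice_sites_of_intron(t.contig, t.strand, intron)
                sites.add(d)
                sites.add(a)
        return cls(tdict, genes, junctions, sites)

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(transcript_ids)
        return AnnotationSet.build(
            t for tid, t in self.transcripts.items() if tid in keep
        )

    def __len__(self) -> int:
        return len(self.transcripts)


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_KNOWN_TAGS = ("basic", "appris_principal")


def _parse_attributes(attr_field: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for key, value in _ATTR_RE.findall(attr_field):
        out.setdefault(key, []).append(value)
    return out


def _normalize_tags(raw_tags: Iterable[str]) -> set[str]:
    # Accepts repeated `tag "..."` values and comma lists; APPRIS levels
    # (appris_principal_1..5) collapse to the plain tag.
    tags: set[str] = set()
    for entry in raw_tags:
        for tok in entry.split(","):
            tok = tok.strip()
            if tok == "basic":
                tags.add("basic")
            elif tok.startswith("appris_principal"):
                tags.add("appris_principal")
    return tags


def read_gtf(path: str | Path) -> AnnotationSet:
    """Parse exon features of a GENCODE-dialect GTF into an AnnotationSet.

    1-based closed coordinates convert to 0-based half-open. ``tag``
    attributes and ``transcript_support_level`` are picked up when present;
    TSL values outside 1-5 (``NA`` etc.) parse as absent. ``transcript_type``
    other than protein_coding marks the transcript non-coding; if the
    attribute is missing the transcript is assumed coding.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame = fields[:8]
            if feature != "exon":
                continue
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(fields[8])
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon without transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon without gene_id")
            tid = attrs["transcript_id"][0]
            rec = per_tx.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"][0],
                    "contig": contig,
                    "strand": strand,
                    "exons": [],
                    "tags": set(),
                    "tsl": None,
                    "coding": None,
                },
            )
            rec["exons"].append((start - 1, end))
            rec["tags"] |= _normalize_tags(attrs.get("tag", []))
            for tsl_raw in attrs.get("transcript_support_level", []):
                tsl_tok = tsl_raw.strip().split()[0] if tsl_raw.strip() else ""
                if tsl_tok.isdigit() and 1 <= int(tsl_tok) <= 5:
                    rec["tsl"] = int(tsl_tok)
            ttype = attrs.get("transcript_type", attrs.get("transcript_biotype", []))
            if ttype:
                rec["coding"] = ttype[0] == "protein_coding"

    models = []
    for tid, rec in per_tx.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                contig=rec["contig"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                tags=frozenset(rec["tags"]),
                tsl=rec["tsl"],
                coding=True if rec["coding"] is None else rec["coding"],
            )
        )
    return AnnotationSet.build(models)


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    """Write exon features (plus transcript lines) in GENCODE-dialect GTF."""
    with open(path, "w") as fh:
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            attrs += f' transcript_type "{"protein_coding" if t.coding else "processed_transcript"}";'
            for tag in sorted(t.tags):
                attrs += f' tag "{tag}";'
            if t.tsl is not None:
                attrs += f' transcript_support_level "{t.tsl}";'
            fh.write(
                f"{t.contig}\tcapiso\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\tcapiso\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED12


def _bed12_line(name: str, contig: str, strand: str, exons: Sequence[Interval]) -> str:
    start = exons[0][0]
    end = exons[-1][1]
    sizes = ",".join(str(e - s) for s, e in exons)
    starts = ",".join(str(s - start) for s, e in exons)
    return (
        f"{contig}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}\t0\t"
        f"{len(exons)}\t{sizes},\t{starts},"
    )


def write_bed12(models: Iterable, path: str | Path) -> None:
    """Write TranscriptModel-like objects (anything with contig/strand/exons
    and a transcript_id or isoform_id) as BED12."""
    with open(path, "w") as fh:
        for m in models:
            name = getattr(m, "transcript_id", None) or getattr(m, "isoform_id")
            fh.write(_bed12_line(name, m.contig, m.strand, m.exons) + "\n")


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read BED12 into TranscriptModels (gene_id mirrors the name field)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise Bed12ParseError(f"line {lineno}: expected 12 fields, got {len(f)}")
            contig, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            offsets = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise Bed12ParseError(
                    f"line {lineno}: blockCount {n_blocks} inconsistent with "
                    f"{len(sizes)} sizes / {len(offsets)} starts"
                )
            exons = tuple(
                (start + off, start + off + sz) for off, sz in zip(offsets, sizes)
            )
            if exons[-1][1] != _end:
                raise Bed12ParseError(
                    f"line {lineno}: block sum inconsistent with chromEnd"
                )
            out.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    contig=contig,
                    strand=strand,
                    exons=exons,
                )
            )
    return out


# ---------------------------------------------------------------------------
# bedGraph score track


class ScoreTrack:
    """Per-base score lookup backed by sorted bedGraph intervals.

    Positions not covered return None (missing), never 0 — 0 is a
    meaningful score value. At an abutting half-open boundary the
    right-hand interval wins.
    """

    def __init__(self, intervals: Mapping[str, list[tuple[int, int, float]]]):
        self._data: dict[str, tuple[list[int], list[int], list[float]]] = {}
        for contig, ivs in intervals.items():
            ivs = sorted(ivs)
            prev_end = None
            prev_val = None
            for s, e, v in ivs:
                if prev_end is not None and s < prev_end and v != prev_val:
                    raise TrackError(
                        f"overlapping intervals with conflicting values on {contig} at {s}"
                    )
                prev_end, prev_val = e, v
            self._data[contig] = (
                [s for s, _, _ in ivs],
                [e for _, e, _ in ivs],
                [v for _, _, v in ivs],
            )

    def get(self, contig: str, position: int) -> Optional[float]:
        if contig not in self._data:
            return None
        starts, ends, values = self._data[contig]
        i = bisect_right(starts, position) - 1
        if i >= 0 and position < ends[i]:
            return values[i]
        return None


def read_track(path: str | Path) -> ScoreTrack:
    """Read a bedGraph (0-based half-open) into a ScoreTrack."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, s, e, v = line.split("\t")[:4]
            intervals.setdefault(contig, []).append((int(s), int(e), float(v)))
    return ScoreTrack(intervals)


def write_track(intervals: Mapping[str, list[tuple[int, int, float]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(intervals):
            for s, e, v in sorted(intervals[contig]):
                fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeRef:
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GenomeRef(contigs)


def write_fasta(genome: GenomeRef, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.contigs):
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
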