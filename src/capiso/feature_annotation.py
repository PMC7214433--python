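"""Functional features of observed isoforms and the orthogonal
short-read validation filter.

Features mirror standard long-read QC practice: CAGE support of the 5'
end (distance to the nearest peak center, and containment in a peak),
presence of a canonical polyA hexamer (AATAAA/ATTAAA in DNA) 5-25 nt
upstream of the 3' end, and per-splice-site trinucleotide conservation
scores (last exonic base + first two intronic bases for donors; last two
intronic bases + first exonic base for acceptors, strand-aware).

The validation filter requires every NOVEL junction of an isoform to be
supported by at least ``min_support`` short reads; isoforms with no
novel junctions pass vacuously.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genomic_model import GenomeRef, reverse_complement
from .isoform_classification import AlignedIsoform, ClassificationRecord

POLYA_MOTIFS = ("AATAAA", "ATTAAA")


@dataclass
class FeatureRecord:
    isoform_id: str
    cage_distance: Optional[int] = None
    within_cage: bool = False
    polya_motif_found: bool = False
    polya_motif: Optional[str] = None
    polya_motif_offset: Optional[int] = None  # 3' end to motif's last base
    polya_motif_offset_start: Optional[int] = None  # 3' end to motif's first base
    donor_scores: list[tuple] = field(default_factory=list)
    acceptor_scores: list[tuple] = field(default_factory=list)
    donor_dinucs: list[str] = field(default_factory=list)
    acceptor_dinucs: list[str] = field(default_factory=list)
    validated: bool = True


class CagePeaks:
    """CAGE peak intervals per contig, sorted, with centers precomputed.

    The peak center is the integer midpoint (start+end)//2.
    """

    def __init__(self, peaks: Mapping[str, Sequence[tuple[int, int]]]):
        self._peaks: dict[str, list[tuple[int, int]]] = {}
        self._centers: dict[str, list[int]] = {}
        for contig, ivs in peaks.items():
            sorted_ivs = sorted(ivs)
            self._peaks[contig] = sorted_ivs
            self._centers[contig] = sorted((s + e) // 2 for s, e in sorted_ivs)

    @classmethod
    def from_bed(cls, path: str | Path) -> "CagePeaks":
        peaks: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                peaks.setdefault(f[0], []).append((int(f[1]), int(f[2])))
        return cls(peaks)

    def nearest_center(self, contig: str, position: int) -> Optional[int]:
        centers = self._centers.get(contig)
        if not centers:
            return None
        i = bisect_left(centers, position)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(centers):
                if best is None or abs(centers[j] - position) < abs(best - position):
                    best = centers[j]
        return best

    def contains(self, contig: str, position: int) -> bool:
        for s, e in self._peaks.get(contig, ()):
            if s <= position < e:
                return True
            if s > position:
                break
        return False


def cage_annotate(
    iso: AlignedIsoform, peaks: CagePeaks
) -> tuple[Optional[int], bool]:
    """Distance from the isoform 5' end to the nearest CAGE peak center,
    signed in transcript orientation (negative = 5' end upstream of the
    center), and whether the 5' end lies within [peak start, peak end)."""
    tss = iso.exons[0][0] if iso.strand == "+" else iso.exons[-1][1] - 1
    center = peaks.nearest_center(iso.contig, tss)
    within = peaks.contains(iso.contig, tss)
    if center is None:
        return None, within
    distance = tss - center if iso.strand == "+" else center - tss
    return distance, within


def polya_motif_scan(
    iso: AlignedIsoform, genome: GenomeRef
) -> tuple[bool, Optional[str], Optional[int]]:
    """Scan for a canonical polyA hexamer fully contained in the window
    5-25 nt upstream of the 3' end (transcript sense; reverse-complement
    lookup on the minus strand). Offsets are measured from the 3' end to
    the motif's last base; the match nearest the 3' end is reported.
    A window running past the contig start is truncated, not an error.
    """
    if iso.strand == "+":
        t = iso.exons[-1][1] - 1  # 3'-most base
        win_lo = max(0, t - 25)
        win_hi = max(0, t - 4)  # slice end, positions t-25..t-5
        window = genome.fetch(iso.contig, win_lo, win_hi)
        # window is already in sense order; offset of window index i's last
        # base: last window index maps to offset 5
        offsets_last = list(range(win_hi - 1 - win_lo, -1, -1))  # index -> distance-5
        base_offset = 5
    else:
        t = iso.exons[0][0]
        contig_len = len(genome.contigs[iso.contig])
        win_lo = min(contig_len, t + 5)
        win_hi = min(contig_len, t + 26)  # positions t+5..t+25
        window = reverse_complement(genome.fetch(iso.contig, win_lo, win_hi))
        base_offset = 5
    # In sense order, window[-1] sits 5 nt upstream of the 3' end and
    # window[0] sits (len(window)+4) nt upstream.
    best = None  # (offset_last, motif)
    n = len(window)
    for motif in POLYA_MOTIFS:
        idx = window.find(motif)
        while idx != -1:
            offset_last = base_offset + (n - (idx + len(motif)))
            if best is None or offset_last < best[0]:
                best = (offset_last, motif)
            idx = window.find(motif, idx + 1)
    if best is None:
        return False, None, None
    return True, best[1], best[0]


def junction_conservation(
    iso: AlignedIsoform,
    track,
    genome: Optional[GenomeRef] = None,
) -> tuple[list[tuple], list[tuple], list[str], list[str]]:
    """Per-junction donor/acceptor trinucleotide conservation scores and
    (when a genome is given) splice dinucleotides.

    Donor trinucleotide: last exonic base + first two intronic bases.
    Acceptor trinucleotide: last two intronic bases + first exonic base.
    Positions are strand-aware; scores come back in transcript-sense
    order with missing positions as None.
    """
    donor_scores: list[tuple] = []
    acceptor_scores: list[tuple] = []
    donor_dinucs: list[str] = []
    acceptor_dinucs: list[str] = []
    introns = iso.introns()
    order = introns if iso.strand == "+" else introns[::-1]
    for s, e in order:
        if iso.strand == "+":
            donor_pos = (s - 1, s, s + 1)
            acceptor_pos = (e - 2, e - 1, e)
        else:
            donor_pos = (e, e - 1, e - 2)
            acceptor_pos = (s + 1, s, s - 1)
        donor_scores.append(tuple(track.get(iso.contig, p) for p in donor_pos))
        acceptor_scores.append(tuple(track.get(iso.contig, p) for p in acceptor_pos))
        if genome is not None:
            left = genome.fetch(iso.contig, s, s + 2)
            right = genome.fetch(iso.contig, e - 2, e)
            if iso.strand == "+":
                donor_dinucs.append(left)
                acceptor_dinucs.append(right)
            else:
                donor_dinucs.append(reverse_complement(right))
                acceptor_dinucs.append(reverse_complement(left))
    return donor_scores, acceptor_scores, donor_dinucs, acceptor_dinucs


JunctionKey = tuple[str, int, int, str]  # (contig, start, end, strand)


def validate_novel_isoforms(
    records: Sequence[ClassificationRecord],
    isoforms: Mapping[str, AlignedIsoform],
    junction_counts: Mapping[JunctionKey, int],
    min_support: int = 3,
) -> tuple[list[ClassificationRecord], list[ClassificationRecord]]:
    """Flag each isoform validated iff every novel junction it carries has
    short-read support >= min_support (junctions absent from the table
    count 0). Returns (all records with flags set, the filtered list that
    drops unvalidated novel isoforms)."""
    validated_flags: dict[str, bool] = {}
    for rec in records:
        iso = isoforms[rec.isoform_id]
        ok = True
        for s, e in rec.novel_junctions:
            count = junction_counts.get((iso.contig, s, e, iso.strand), 0)
            if count < min_support:
                ok = False
                break
        validated_flags[rec.isoform_id] = ok
    filtered = [
        rec
        for rec in records
        if validated_flags[rec.isoform_id] or not rec.is_novel
    ]
    return list(records), filtered


def annotate_features(
    records: Sequence[ClassificationRecord],
    isoforms: Mapping[str, AlignedIsoform],
    peaks: Optional[CagePeaks] = None,
    genome: Optional[GenomeRef] = None,
    track=None,
    junction_counts: Optional[Mapping[JunctionKey, int]] = None,
    min_junction_support: int = 3,
) -> list[FeatureRecord]:
    """Full feature annotation of classified isoforms; any input left None
    simply leaves the corresponding fields at their defaults."""
    validated: dict[str, bool] = {rec.isoform_id: True for rec in records}
    if junction_counts is not None:
        _, _filtered = validate_novel_isoforms(
            records, isoforms, junction_counts, min_junction_support
        )
        kept = {r.isoform_id for r in _filtered}
        for rec in records:
            validated[rec.isoform_id] = rec.isoform_id in kept or not rec.is_novel
    out = []
    for rec in records:
        iso = isoforms[rec.isoform_id]
        fr = FeatureRecord(isoform_id=rec.isoform_id, validated=validated[rec.isoform_id])
        if peaks is not None:
            fr.cage_distance, fr.within_cage = cage_annotate(iso, peaks)
        if genome is not None:
            found, motif, offset = polya_motif_scan(iso, genome)
            fr.polya_motif_found = found
            fr.polya_motif = motif
            fr.polya_motif_offset = offset
            fr.polya_motif_offset_start = None if offset is None else offset + 5
        if track is not None:
            ds, as_, dd, ad = junction_conservation(iso, track, genome)
            fr.donor_scores, fr.acceptor_scores = ds, as_
            fr.donor_dinucs, fr.acceptor_dinucs = dd, ad
        out.append(fr)
    return out


def feature_table(features: Sequence[FeatureRecord]) -> pd.DataFrame:
    rows = []
    for fr in features:
        rows.append({
            "isoform_id": fr.isoform_id,
            "cage_distance": "." if fr.cage_distance is None else fr.cage_distance,
            "within_cage": int(fr.within_cage),
            "polya_motif_found": int(fr.polya_motif_found),
            "polya_motif": fr.polya_motif or ".",
            "polya_motif_offset": "." if fr.polya_motif_offset is None else fr.polya_motif_offset,
            "validated": int(fr.validated),
        })
    return pd.DataFrame(rows)
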