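"""Full-length read classification, demultiplexing, and PCR-chimera calls.

A read is full-length (FL) when it carries the 5' primer, the 3' primer,
and a polyA tail preceding the 3' primer. Chimeras formed by stitch-like
PCR of partial fragments are detected through a dual inner-barcode
scheme: a molecule synthesized with a matched 5'/3' barcode pair stays
concordant through amplification, while a hybrid molecule shows a
swapped (discordant) pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .synthetic_data import LongReadRecord

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNRESOLVED = "unresolved"


def classify_full_length(read: LongReadRecord) -> bool:
    """FL iff 5' primer AND 3' primer AND polyA are all present."""
    return read.has_5p_primer and read.has_3p_primer and read.has_polyA


def demultiplex(
    reads: Iterable[LongReadRecord],
    sample_barcodes: Sequence[str],
) -> dict[str, list[LongReadRecord]]:
    """Partition FL reads by sample barcode; unknown barcodes go to
    'unassigned'. Non-FL reads are excluded entirely."""
    if len(set(sample_barcodes)) != len(sample_barcodes):
        raise ValueError("sample barcodes must be unique")
    bins: dict[str, list[LongReadRecord]] = {bc: [] for bc in sample_barcodes}
    bins["unassigned"] = []
    known = set(sample_barcodes)
    for r in reads:
        if not classify_full_length(r):
            continue
        if r.sample_barcode in known:
            bins[r.sample_barcode].append(r)
        else:
            bins["unassigned"].append(r)
    return bins


def dual_barcode_concordance(
    read: LongReadRecord,
    pairs: Iterable[tuple[str, str]],
) -> str:
    """Concordant iff the inner 5'/3' barcodes form a known matched pair;
    discordant iff both are present but mismatched; unresolved if either
    is absent."""
    if read.inner_5p_barcode is None or read.inner_3p_barcode is None:
        return UNRESOLVED
    if (read.inner_5p_barcode, read.inner_3p_barcode) in set(pairs):
        return CONCORDANT
    return DISCORDANT


def estimate_chimera_rate(labels: Iterable[str]) -> float:
    """Read-level discordance fraction among resolved reads."""
    n_c = n_d = 0
    for lab in labels:
        if lab == CONCORDANT:
            n_c += 1
        elif lab == DISCORDANT:
            n_d += 1
    if n_c + n_d == 0:
        raise ValueError("no resolved reads")
    return n_d / (n_c + n_d)


@dataclass
class ChimeraReport:
    n_reads: int
    n_concordant: int
    n_discordant: int
    per_isoform: dict[str, tuple[int, int, str]]  # id -> (conc, disc, call)
    nonchimeric_rate_all: float
    nonchimeric_rate_novel: Optional[float] = None
    n_isoforms_unresolved: int = 0
    read_level_chimera_rate: Optional[float] = None


def call_isoform_chimeras(
    isoform_members: Mapping[str, Sequence[str]],
    read_labels: Mapping[str, str],
    novel_isoforms: Optional[set[str]] = None,
) -> ChimeraReport:
    """Majority vote per isoform over its member reads' concordance labels.

    An isoform is non-chimeric iff strictly more than half of its resolved
    member reads are concordant; ties call chimeric ("a majority" read
    strictly — conservative for novel-isoform claims). Unresolved reads
    are excluded from the vote denominator; isoforms with zero resolved
    reads receive no call and are counted separately.
    """
    per_isoform: dict[str, tuple[int, int, str]] = {}
    total = n_conc = n_disc = 0
    n_unres_iso = 0
    for iso_id in sorted(isoform_members):
        members = isoform_members[iso_id]
        c = d = 0
        for rid in members:
            total += 1
            lab = read_labels.get(rid, UNRESOLVED)
            if lab == CONCORDANT:
                c += 1
            elif lab == DISCORDANT:
                d += 1
        n_conc += c
        n_disc += d
        if c + d == 0:
            n_unres_iso += 1
            continue
        call = "non-chimeric" if c > (c + d) / 2 else "chimeric"
        per_isoform[iso_id] = (c, d, call)
    called = list(per_isoform.values())
    rate_all = (
        sum(1 for _, _, call in called if call == "non-chimeric") / len(called)
        if called
        else float("nan")
    )
    rate_novel = None
    if novel_isoforms is not None:
        novel_called = [
            v for iso_id, v in per_isoform.items() if iso_id in novel_isoforms
        ]
        if novel_called:
            rate_novel = sum(
                1 for _, _, call in novel_called if call == "non-chimeric"
            ) / len(novel_called)
    read_rate = n_disc / (n_conc + n_disc) if (n_conc + n_disc) else None
    return ChimeraReport(
        n_reads=total,
        n_concordant=n_conc,
        n_discordant=n_disc,
        per_isoform=per_isoform,
        nonchimeric_rate_all=rate_all,
        nonchimeric_rate_novel=rate_novel,
        n_isoforms_unresolved=n_unres_iso,
        read_level_chimera_rate=read_rate,
    )
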