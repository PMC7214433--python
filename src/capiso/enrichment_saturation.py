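"""Enrichment statistics and saturation-discovery curves.

On-target rate is the fraction of total transcriptional abundance (TPM
mode) or of full-length reads (FL mode) attributable to the targeted
genes; fold enrichment divides the capturant's on-target rate by the
unenriched input's. Saturation-discovery curves subsample the finite
pool of full-length reads without replacement and average the number of
unique genes/isoforms over iterations; the hypergeometric closed form
E[unique] = sum_i (1 - C(N-n_i, d)/C(N, d)) serves as the analytic
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .capture_coverage import exonic_overlap
from .genomic_model import AnnotationSet
from .synthetic_data import CaptureDesign, ExpressionProfile


@dataclass
class EnrichmentReport:
    on_target_input: float
    on_target_capturant: float
    fold_enrichment: Optional[float]
    per_gene_fraction_input: dict[str, float]
    per_gene_fraction_capturant: dict[str, float]
    per_isoform_efficiency: Optional[dict[str, float]] = None


@dataclass
class SaturationCurve:
    depths: list[int]
    mean_unique_genes: list[float]
    mean_unique_isoforms: list[float]
    sd_unique_genes: list[float]
    sd_unique_isoforms: list[float]
    n_iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths,
            "mean_unique_genes": self.mean_unique_genes,
            "mean_unique_isoforms": self.mean_unique_isoforms,
            "sd_unique_genes": self.sd_unique_genes,
            "sd_unique_isoforms": self.sd_unique_isoforms,
        })


def gene_abundance_fractions(
    source: ExpressionProfile | Mapping[str, float],
    annotation: AnnotationSet,
) -> dict[str, float]:
    """Per-gene fraction of total abundance (or FL-read count): member
    transcripts summed, normalized by the grand total."""
    abundance = source.abundance if isinstance(source, ExpressionProfile) else source
    per_gene: dict[str, float] = {}
    total = 0.0
    for tid, value in abundance.items():
        t = annotation.transcripts.get(tid)
        if t is None:
            raise ValueError(f"transcript {tid!r} not in annotation")
        per_gene[t.gene_id] = per_gene.get(t.gene_id, 0.0) + value
        total += value
    if total <= 0:
        raise ValueError("total abundance is zero")
    return {g: v / total for g, v in per_gene.items()}


def on_target_rate(
    fractions: Mapping[str, float], targets: Iterable[str]
) -> float:
    """Sum of per-gene fractions over the targeted genes."""
    targets = set(targets)
    return sum(v for g, v in fractions.items() if g in targets)


def fold_enrichment(input_rate: float, capturant_rate: float) -> Optional[float]:
    """capturant_rate / input_rate; None (undefined) when input is zero."""
    if input_rate == 0:
        return None
    return capturant_rate / input_rate


def capture_efficiency(
    input_depth: Mapping[str, float],
    capturant_depth: Mapping[str, float],
) -> dict[str, Optional[float]]:
    """Per-isoform capturant/input depth ratios; None where input is 0."""
    out: dict[str, Optional[float]] = {}
    for iso in sorted(set(input_depth) | set(capturant_depth)):
        inp = input_depth.get(iso, 0.0)
        cap = capturant_depth.get(iso, 0.0)
        out[iso] = cap / inp if inp > 0 else None
    return out


def efficiency_by_overlap(
    efficiencies: Mapping[str, Optional[float]],
    design: CaptureDesign,
    annotation: AnnotationSet,
) -> pd.DataFrame:
    """Tabulate per-isoform efficiency against nt of overlap with the
    gene's probe template (the spike-in style analysis shape)."""
    rows = []
    for tid in sorted(efficiencies):
        if tid not in annotation.transcripts:
            continue
        t = annotation.transcripts[tid]
        targeted = t.gene_id in design.targets
        overlap = 0
        if targeted:
            template = annotation.transcripts[design.template[t.gene_id]]
            overlap = exonic_overlap(template, t)
        rows.append({
            "isoform_id": tid,
            "gene_id": t.gene_id,
            "targeted": targeted,
            "overlap_nt": overlap,
            "efficiency": efficiencies[tid],
        })
    return pd.DataFrame(rows)


def enrichment_report(
    input_profile: ExpressionProfile | Mapping[str, float],
    capturant_profile: ExpressionProfile | Mapping[str, float],
    annotation: AnnotationSet,
    targets: Iterable[str],
) -> EnrichmentReport:
    targets = set(targets)
    unknown = targets - set(annotation.genes)
    if unknown:
        import warnings

        warnings.warn(f"targets not in annotation: {sorted(unknown)}")
    f_in = gene_abundance_fractions(input_profile, annotation)
    f_cap = gene_abundance_fractions(capturant_profile, annotation)
    r_in = on_target_rate(f_in, targets)
    r_cap = on_target_rate(f_cap, targets)
    return EnrichmentReport(
        on_target_input=r_in,
        on_target_capturant=r_cap,
        fold_enrichment=fold_enrichment(r_in, r_cap),
        per_gene_fraction_input=f_in,
        per_gene_fraction_capturant=f_cap,
    )


# ---------------------------------------------------------------------------
# Saturation-discovery


def expected_unique_hypergeometric(
    category_counts: Sequence[int], depth: int
) -> float:
    """Closed-form E[number of distinct categories] when drawing ``depth``
    reads without replacement from a pool with the given per-category
    counts: sum_i (1 - C(N-n_i, d)/C(N, d))."""
    counts = np.asarray(category_counts, dtype=np.int64)
    n_total = int(counts.sum())
    if depth > n_total:
        raise ValueError("depth exceeds pool size")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_denom = log_comb(n_total, depth)
    p_absent = np.where(
        n_total - counts >= depth,
        np.exp(log_comb(n_total - counts, depth) - log_denom),
        0.0,
    )
    return float(np.sum(1.0 - p_absent))


def discovery_curve(
    read_assignments: Sequence[tuple[str, str, Optional[str]]],
    depths: Sequence[int],
    n_iterations: int = 100,
    seed: int = 0,
    isoform_filter: Optional[set[str]] = None,
) -> SaturationCurve:
    """Mean unique genes / isoforms over random subsamples of the read pool.

    ``read_assignments`` rows are (read_id, gene_id, isoform_id); sampling
    is without replacement, ``n_iterations`` per depth, arithmetic means.
    ``isoform_filter`` optionally restricts the isoform count to ids in
    the set (e.g. reference-matching isoforms only); gene counts are
    unaffected by the filter.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_total = len(read_assignments)
    for d in depths:
        if d > n_total:
            raise ValueError(f"depth {d} exceeds pool size {n_total}")
        if d < 1:
            raise ValueError("depths must be >= 1")
    genes = np.array([g for _, g, _ in read_assignments])
    isos = np.array([
        i if (i is not None and (isoform_filter is None or i in isoform_filter))
        else ""
        for _, _, i in read_assignments
    ])
    rng = np.random.default_rng(seed)
    mean_g, mean_i, sd_g, sd_i = [], [], [], []
    for d in depths:
        ug = np.empty(n_iterations)
        ui = np.empty(n_iterations)
        for it in range(n_iterations):
            idx = rng.choice(n_total, size=d, replace=False)
            ug[it] = len(np.unique(genes[idx]))
            sampled_iso = isos[idx]
            ui[it] = len(np.unique(sampled_iso[sampled_iso != ""]))
        mean_g.append(float(ug.mean()))
        mean_i.append(float(ui.mean()))
        sd_g.append(float(ug.std(ddof=1)) if n_iterations > 1 else 0.0)
        sd_i.append(float(ui.std(ddof=1)) if n_iterations > 1 else 0.0)
    return SaturationCurve(
        depths=list(depths),
        mean_unique_genes=mean_g,
        mean_unique_isoforms=mean_i,
        sd_unique_genes=sd_g,
        sd_unique_isoforms=sd_i,
        n_iterations=n_iterations,
        seed=seed,
    )


def rank_abundance_table(
    fractions: Mapping[str, float],
    targets: Iterable[str],
    top_n: int = 50,
) -> pd.DataFrame:
    """Genes by descending abundance fraction (ties lexicographic), each
    flagged targeted or not; at most ``top_n`` rows."""
    targets = set(targets)
    ordered = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(
        [
            {"rank": r + 1, "gene_id": g, "fraction": f, "targeted": g in targets}
            for r, (g, f) in enumerate(ordered)
        ]
    )
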