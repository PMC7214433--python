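"""End-to-end synthetic capture experiment: simulate -> process reads ->
classify -> annotate -> validate -> report.

A single global seed expands into independent per-stage substreams, so a
stage rerun in isolation reproduces its in-pipeline output. Two runs
with the same config produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .capture_coverage import (
    coverage_estimate,
    filter_coding_basic,
    select_representative,
)
from .enrichment_saturation import (
    discovery_curve,
    enrichment_report,
    gene_abundance_fractions,
    rank_abundance_table,
)
from .feature_annotation import (
    CagePeaks,
    annotate_features,
    feature_table,
    validate_novel_isoforms,
)
from .genomic_model import ScoreTrack, write_bed12, write_fasta, write_gtf, write_track
from .isoform_classification import (
    ReferenceIndex,
    classification_table,
    classify_isoform,
    collapse_reads,
    filter_alignments,
)
from .longread_processing import (
    call_isoform_chimeras,
    classify_full_length,
    demultiplex,
    dual_barcode_concordance,
)
from . import synthetic_data as sd

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All knobs of the synthetic experiment plus analysis thresholds."""

    seed: int = 0
    outdir: str = "capiso_run"
    # simulation
    n_genes: int = 50
    isoforms_per_gene_range: tuple[int, int] = (1, 8)
    exons_per_transcript_range: tuple[int, int] = (3, 12)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (60, 500)
    log10_expression_range: float = 6.0
    n_targets: int = 15
    p_on: float = 0.5
    p_bg: float = 0.005
    overlap_full: int = 45
    overlap_floor: int = 35
    n_reads: int = 30000
    fl_rate: float = 0.9
    chimera_rate: float = 0.02
    sample_barcodes: tuple[str, ...] = tuple(f"sample{i:02d}" for i in range(7))
    n_dual_pairs: int = 96
    mean_junction_depth: float = 50.0
    heldout_isoform_fraction: float = 0.25
    # analysis thresholds
    min_overlap: int = 50
    min_coverage: float = 0.99
    min_identity: float = 0.95
    min_junction_support: int = 3
    polya_window: tuple[int, int] = (5, 25)
    saturation_iterations: int = 100
    saturation_depth_fractions: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 0.75, 1.0)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()
        }
        data["schema_version"] = CONFIG_SCHEMA_VERSION
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data.pop("schema_version", None)
        for f in dataclasses.fields(cls):
            if f.name in data and isinstance(data[f.name], list):
                data[f.name] = tuple(data[f.name])
        return cls(**data)


def _stage_seeds(seed: int, n: int = 9) -> list[int]:
    """Independent per-stage integer seeds (< 2^31) from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: RunConfig, outdir: Optional[str] = None) -> dict:
    """Run the full synthetic experiment; write all artifacts under
    ``outdir`` and return the in-memory bundle."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    bundle: dict = {"config": config, "outdir": out}

    # --- simulate
    genome, annotation = sd.simulate_annotation(
        n_genes=config.n_genes,
        isoforms_per_gene_range=config.isoforms_per_gene_range,
        exons_per_transcript_range=config.exons_per_transcript_range,
        exon_len_range=config.exon_len_range,
        intron_len_range=config.intron_len_range,
        seed=seeds[0],
    )
    write_fasta(genome, out / "genome.fa")
    write_gtf(annotation, out / "annotation.gtf")
    profile = sd.simulate_expression(
        annotation, log10_range=config.log10_expression_range, seed=seeds[1]
    )
    sd.write_expression_tsv(profile, out / "expression_input.tsv")
    design = sd.design_capture(annotation, n_targets=config.n_targets, seed=seeds[2])
    model = sd.CaptureModel(
        p_on=config.p_on,
        p_bg=config.p_bg,
        overlap_full=config.overlap_full,
        overlap_floor=config.overlap_floor,
    )
    capturant = sd.simulate_capture(profile, design, model, annotation, seed=seeds[3])
    sd.write_expression_tsv(capturant, out / "expression_capturant.tsv")
    with open(out / "targets.txt", "w") as fh:
        for g in sorted(design.targets):
            fh.write(g + "\n")
    reference, heldout = sd.holdout_novel_isoforms(
        annotation,
        fraction=config.heldout_isoform_fraction,
        seed=seeds[8],
        protect=set(design.template.values()),
    )
    write_gtf(reference, out / "reference.gtf")
    pairs = sd.default_dual_barcode_pairs(config.n_dual_pairs)
    reads = sd.simulate_long_reads(
        capturant,
        annotation,
        n_reads=config.n_reads,
        fl_rate=config.fl_rate,
        chimera_rate=config.chimera_rate,
        sample_barcodes=config.sample_barcodes,
        dual_barcode_pairs=pairs,
        seed=seeds[4],
    )
    sd.write_reads_tsv(reads, out / "reads.tsv")
    junction_counts_df = sd.simulate_short_read_junction_counts(
        capturant, annotation, mean_depth=config.mean_junction_depth, seed=seeds[5]
    )
    sd.write_junction_counts_tsv(junction_counts_df, out / "junction_counts.tsv")
    bundle.update(
        genome=genome, annotation=annotation, reference=reference,
        heldout=heldout, profile=profile, design=design,
        capture_model=model, capturant=capturant, reads=reads,
    )

    # --- process reads
    fl_reads = [r for r in reads if classify_full_length(r)]
    bins = demultiplex(reads, config.sample_barcodes)
    labels = {r.read_id: dual_barcode_concordance(r, pairs) for r in fl_reads}
    with open(out / "read_labels.tsv", "w") as fh:
        fh.write("read_id\tfull_length\tsample_barcode\tconcordance\n")
        for r in reads:
            fl = classify_full_length(r)
            fh.write(
                f"{r.read_id}\t{int(fl)}\t{r.sample_barcode}\t"
                f"{labels.get(r.read_id, '.')}\n"
            )
    bundle.update(fl_reads=fl_reads, demux=bins, concordance_labels=labels)

    # --- classify
    isoforms = collapse_reads(fl_reads)
    isoforms = filter_alignments(
        isoforms, min_coverage=config.min_coverage, min_identity=config.min_identity
    )
    iso_by_id = {iso.isoform_id: iso for iso in isoforms}
    index = ReferenceIndex(reference)
    records = [
        classify_isoform(iso, reference, index=index, genome=genome)
        for iso in isoforms
    ]
    write_bed12(isoforms, out / "isoforms.bed12")
    cls_df = classification_table(records, iso_by_id)
    cls_df.to_csv(out / "classification.tsv", sep="\t", index=False)
    bundle.update(isoforms=isoforms, iso_by_id=iso_by_id, records=records)

    # --- chimera calls
    members = {iso.isoform_id: iso.member_reads for iso in isoforms}
    novel_ids = {rec.isoform_id for rec in records if rec.is_novel}
    chimera_report = call_isoform_chimeras(members, labels, novel_isoforms=novel_ids)
    with open(out / "chimera_report.json", "w") as fh:
        json.dump(
            {
                "n_reads": chimera_report.n_reads,
                "n_concordant": chimera_report.n_concordant,
                "n_discordant": chimera_report.n_discordant,
                "nonchimeric_rate_all": chimera_report.nonchimeric_rate_all,
                "nonchimeric_rate_novel": chimera_report.nonchimeric_rate_novel,
                "read_level_chimera_rate": chimera_report.read_level_chimera_rate,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    bundle["chimera_report"] = chimera_report

    # --- annotate + validate
    peaks = CagePeaks(sd.simulate_cage_peaks(annotation))
    track_ivs = sd.simulate_conservation_track(annotation)
    write_track(track_ivs, out / "conservation.bedgraph")
    track = ScoreTrack(track_ivs)
    junction_counts = {
        (r.contig, int(r.start), int(r.end), r.strand): int(r.count)
        for r in junction_counts_df.itertuples(index=False)
    }
    features = annotate_features(
        records,
        iso_by_id,
        peaks=peaks,
        genome=genome,
        track=track,
        junction_counts=junction_counts,
        min_junction_support=config.min_junction_support,
    )
    feature_table(features).to_csv(out / "features.tsv", sep="\t", index=False)
    _, validated_records = validate_novel_isoforms(
        records, iso_by_id, junction_counts, config.min_junction_support
    )
    bundle.update(features=features, validated_records=validated_records)

    from .isoform_classification import recovery_statistics

    recovery = recovery_statistics(
        records,
        iso_by_id,
        reference,
        probe_tpm=design.probe_tpm,
        expression=profile,
    )
    recovery.to_csv(out / "recovery.tsv", sep="\t", index=False)
    bundle["recovery"] = recovery

    # --- enrichment + saturation + coverage
    enr = enrichment_report(profile, capturant, annotation, design.targets)
    bundle["enrichment"] = enr
    fl_fracs = gene_abundance_fractions(
        _fl_counts_per_transcript(fl_reads), annotation
    )
    bundle["rank_abundance"] = rank_abundance_table(fl_fracs, design.targets)
    bundle["rank_abundance"].to_csv(out / "rank_abundance.tsv", sep="\t", index=False)

    read_to_iso = {
        rid: iso.isoform_id for iso in isoforms for rid in iso.member_reads
    }
    assignments = [
        (
            r.read_id,
            annotation.transcripts[r.truth_transcript_id].gene_id,
            read_to_iso.get(r.read_id),
        )
        for r in fl_reads
    ]
    depths = sorted(
        {max(1, int(round(f * len(assignments))))
         for f in config.saturation_depth_fractions}
    )
    curve = discovery_curve(
        assignments,
        depths,
        n_iterations=config.saturation_iterations,
        seed=seeds[6],
    )
    curve.to_frame().to_csv(out / "saturation_curve.tsv", sep="\t", index=False)
    bundle["saturation"] = curve

    basic = filter_coding_basic(annotation)
    reps = select_representative(basic, mode="appris")
    coverage = coverage_estimate(
        basic, reps, min_overlap=config.min_overlap, mode="appris"
    )
    bundle["coverage"] = coverage

    config.to_yaml(out / "run_config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "capiso_version": __version__,
                "seed": config.seed,
                "stage_seeds": seeds,
                "n_reads": len(reads),
                "n_full_length": len(fl_reads),
                "n_isoforms": len(isoforms),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    make_report(bundle, out / "summary.txt")
    return bundle


def _fl_counts_per_transcript(fl_reads) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in fl_reads:
        counts[r.truth_transcript_id] = counts.get(r.truth_transcript_id, 0) + 1
    return counts


def make_report(bundle: dict, path=None) -> str:
    """Human-readable run summary; sections for missing stages are marked
    absent rather than failing."""
    lines = ["# capiso run summary", ""]
    enr = bundle.get("enrichment")
    if enr is not None:
        fold = "undefined" if enr.fold_enrichment is None else f"{enr.fold_enrichment:.2f}"
        lines += [
            "[enrichment]",
            f"on_target_input      {enr.on_target_input:.4f}",
            f"on_target_capturant  {enr.on_target_capturant:.4f}",
            f"fold_enrichment      {fold}",
            "",
        ]
    else:
        lines += ["[enrichment] absent", ""]
    ch = bundle.get("chimera_report")
    if ch is not None:
        novel = "." if ch.nonchimeric_rate_novel is None else f"{ch.nonchimeric_rate_novel:.4f}"
        lines += [
            "[chimeras]",
            f"read_level_chimera_rate  {ch.read_level_chimera_rate:.4f}",
            f"nonchimeric_rate_all     {ch.nonchimeric_rate_all:.4f}",
            f"nonchimeric_rate_novel   {novel}",
            "",
        ]
    else:
        lines += ["[chimeras] absent", ""]
    records = bundle.get("records")
    if records is not None:
        from .isoform_classification import novelty_summary

        summ = novelty_summary(
            records,
            bundle.get("iso_by_id"),
            bundle.get("reference", bundle.get("annotation")),
        )
        lines += ["[classification]", f"n_isoforms  {summ['n_isoforms']}"]
        for cat in sorted(summ["category_counts"]):
            lines.append(f"  {cat:<18} {summ['category_counts'][cat]}")
        lines += [
            f"novel_isoform_fraction      {summ['novel_isoform_fraction']:.4f}",
            f"novel_junction_fraction     {summ.get('novel_junction_fraction', float('nan')):.4f}",
            f"novel_splice_site_fraction  {summ.get('novel_splice_site_fraction', float('nan')):.4f}",
            f"intron_retention_fraction   {summ['intron_retention_fraction']:.4f}",
            "",
        ]
    else:
        lines += ["[classification] absent", ""]
    cov = bundle.get("coverage")
    if cov is not None:
        lines += [
            "[probe coverage]",
            f"mode {cov.mode}  min_overlap {cov.min_overlap}",
            f"genes {cov.n_genes}  isoforms {cov.n_isoforms}  "
            f"covered {cov.n_covered}  fraction {cov.fraction_covered:.4f}",
            "",
        ]
    else:
        lines += ["[probe coverage] absent", ""]
    sat = bundle.get("saturation")
    if sat is not None:
        lines += ["[saturation]", "depth\tmean_genes\tmean_isoforms"]
        for d, g, i in zip(sat.depths, sat.mean_unique_genes, sat.mean_unique_isoforms):
            lines.append(f"{d}\t{g:.2f}\t{i:.2f}")
        lines.append("")
    else:
        lines += ["[saturation] absent", ""]
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
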