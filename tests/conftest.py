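import numpy as np
import pytest

from capiso import genomic_model as gm
from capiso import synthetic_data as sd
from capiso.pipeline import RunConfig, run_pipeline


def make_tx(tid, exons, gene="G1", contig="chr1", strand="+", **kw):
    return gm.TranscriptModel(
        transcript_id=tid, gene_id=gene, contig=contig, strand=strand,
        exons=tuple(exons), **kw,
    )


@pytest.fixture(scope="session")
def sim20():
    """Synthetic genome + annotation: 20 genes, up to 8 isoforms each."""
    return sd.simulate_annotation(
        n_genes=20, isoforms_per_gene_range=(1, 8), seed=7
    )


@pytest.fixture(scope="session")
def sim20_expression(sim20):
    _, ann = sim20
    return sd.simulate_expression(ann, seed=11)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One mid-size end-to-end pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = RunConfig(seed=5, n_genes=30, n_targets=10, n_reads=12000,
                    outdir=str(out))
    return run_pipeline(cfg)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept independent of the implementation paths)


def overlap_per_base(a, b):
    """Per-base set-intersection exonic overlap."""
    if a.contig != b.contig or a.strand != b.strand:
        return 0
    abases = set()
    for s, e in a.exons:
        abases.update(range(s, e))
    bbases = set()
    for s, e in b.exons:
        bbases.update(range(s, e))
    return len(abases & bbases)


def classify_brute_force(iso, annotation):
    """Exhaustive reference classifier: enumerates every contiguous
    sub-chain of every reference transcript and rebuilds the junction /
    splice-site sets from scratch."""
    chain = iso.introns()
    refs = [
        t for t in annotation.transcripts.values()
        if t.contig == iso.contig and t.strand == iso.strand
    ]
    if len(iso.exons) == 1:
        s, e = iso.exons[0]
        for t in sorted(refs, key=lambda t: t.transcript_id):
            if any(es <= s and e <= ee for es, ee in t.exons):
                return "mono-exon-known"
        for t in annotation.transcripts.values():
            if t.contig == iso.contig and max(s, t.start) < min(e, t.end):
                return "mono-exon-novel"
        return "intergenic"
    for t in refs:
        if t.introns() == chain:
            return "FSM"
    for t in refs:
        ref_chain = t.introns()
        n = len(chain)
        for i in range(len(ref_chain) - n + 1):
            if ref_chain[i:i + n] == chain and len(ref_chain) > n:
                return "ISM"
    junctions = set()
    sites = set()
    for t in refs:
        for s, e in t.introns():
            junctions.add((s, e))
            d, a = gm.splice_sites_of_intron(t.contig, t.strand, (s, e))
            sites.add(d)
            sites.add(a)
    if all(j in junctions for j in chain):
        return "NIC"
    all_sites_known = True
    for j in chain:
        d, a = gm.splice_sites_of_intron(iso.contig, iso.strand, j)
        if d not in sites or a not in sites:
            all_sites_known = False
    return "NIC" if all_sites_known else "NNC"
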