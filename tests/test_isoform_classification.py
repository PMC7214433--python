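"""Structural classification: collapse, category assignment, intron
retention, recovery and novelty summaries."""

import numpy as np
import pytest

from capiso import genomic_model as gm
from capiso import synthetic_data as sd
from capiso.isoform_classification import (
    AlignedIsoform,
    ReferenceIndex,
    classify_isoform,
    collapse_reads,
    detect_intron_retention,
    filter_alignments,
    novelty_summary,
    recovery_statistics,
)
from conftest import classify_brute_force, make_tx


@pytest.fixture(scope="module")
def reference():
    r1 = make_tx("R1", [(100, 200), (300, 400), (500, 600), (700, 800)], gene="GR")
    r2 = make_tx("R2", [(100, 200), (500, 600), (700, 800)], gene="GR")
    other = make_tx("O1", [(2000, 2100), (2300, 2400)], gene="GO", strand="-")
    return gm.AnnotationSet.build([r1, r2, other])


def iso(exons, strand="+", contig="chr1", iid="q"):
    return AlignedIsoform(isoform_id=iid, contig=contig, strand=strand,
                          exons=tuple(exons))


class TestClassifyExamples:
    def test_fsm_exact_chain(self, reference):
        rec = classify_isoform(
            iso([(90, 200), (300, 400), (500, 600), (700, 820)]), reference
        )
        assert rec.category == "FSM"
        assert rec.matched_transcript_id == "R1"
        assert rec.novel_junctions == [] and rec.novel_splice_sites == []

    def test_ism_consecutive_subchain(self, reference):
        # R1 chain minus its first intron
        rec = classify_isoform(iso([(320, 400), (500, 600), (700, 800)]), reference)
        assert rec.category == "ISM"
        assert rec.matched_transcript_id == "R1"

    def test_nic_known_junction_recombination(self, reference):
        rec = classify_isoform(iso([(100, 200), (300, 600), (700, 800)]), reference)
        # junction (200,300) known from R1; (600,700) known; middle exon
        # spans (400,500)? construct: exons (100,200),(300,600),(700,800)
        # -> introns (200,300),(600,700): both annotated, chain novel
        assert rec.category == "NIC"
        assert rec.subcategory == "combination_of_known_junctions"

    def test_nic_novel_junction_from_known_sites(self, reference):
        # junction (400,700): donor 400 and acceptor 700 both annotated,
        # but the junction itself is not
        rec = classify_isoform(iso([(100, 200), (300, 400), (700, 800)]), reference)
        assert rec.category == "NIC"
        assert rec.subcategory == "novel_junction_from_known_sites"
        assert rec.novel_junctions == [(400, 700)]
        assert rec.novel_splice_sites == []

    def test_nnc_shifted_donor(self, reference):
        rec = classify_isoform(
            iso([(100, 200), (300, 408), (500, 600), (700, 800)]), reference
        )
        assert rec.category == "NNC"
        assert (408, "donor") in rec.novel_splice_sites

    def test_donor_position_annotated_only_as_acceptor_is_novel(self, reference):
        # 500 is an annotated acceptor on '+'; using it as a donor is novel
        rec = classify_isoform(iso([(400, 500), (700, 800)]), reference)
        assert (500, "donor") in rec.novel_splice_sites

    def test_mono_exon_known(self, reference):
        rec = classify_isoform(iso([(120, 180)]), reference)
        assert rec.category == "mono-exon-known"
        assert rec.matched_gene_id == "GR"

    def test_mono_exon_novel_in_intron(self, reference):
        rec = classify_isoform(iso([(230, 280)]), reference)
        assert rec.category == "mono-exon-novel"

    def test_intergenic(self, reference):
        rec = classify_isoform(iso([(5000, 5100)]), reference)
        assert rec.category == "intergenic"

    def test_strand_mismatch_not_fsm(self, reference):
        rec = classify_isoform(
            iso([(100, 200), (300, 400), (500, 600), (700, 800)], strand="-"),
            reference,
        )
        assert rec.category != "FSM"


class TestOracleEquivalence:
    def test_agrees_with_brute_force_on_random_fixtures(self, sim20):
        """Random perturbations of annotated transcripts classified
        identically by the fast path and the exhaustive enumerator."""
        _, ann = sim20
        index = ReferenceIndex(ann)
        rng = np.random.default_rng(99)
        tids = sorted(ann.transcripts)
        n_checked = 0
        for k in range(1200):
            t = ann.transcripts[tids[int(rng.integers(len(tids)))]]
            exons = [list(e) for e in t.exons]
            op = int(rng.integers(5))
            if op == 1 and len(exons) >= 3:
                del exons[1 + int(rng.integers(len(exons) - 2))]
            elif op == 2 and len(exons) >= 2:
                i = int(rng.integers(len(exons) - 1))
                exons[i][1] += int(rng.integers(1, 20))
                if exons[i][1] >= exons[i + 1][0]:
                    continue
            elif op == 3 and len(exons) >= 3:
                exons = exons[1:] if rng.random() < 0.5 else exons[:-1]
            elif op == 4:
                s, e = exons[int(rng.integers(len(exons)))]
                exons = [[s, e]]
            q = iso([tuple(e) for e in exons], strand=t.strand, contig=t.contig,
                    iid=f"q{k}")
            got = classify_isoform(q, ann, index=index)
            assert got.category == classify_brute_force(q, ann), (
                q.exons, t.transcript_id
            )
            n_checked += 1
        assert n_checked >= 1000


class TestFilterAlignments:
    def test_inclusive_thresholds(self):
        keep = filter_alignments([
            AlignedIsoform("a", "c1", "+", ((0, 10),), coverage=0.99, identity=0.95),
            AlignedIsoform("b", "c1", "+", ((0, 10),), coverage=0.989, identity=0.99),
            AlignedIsoform("c", "c1", "+", ((0, 10),), coverage=1.0, identity=0.949),
        ])
        assert [i.isoform_id for i in keep] == ["a"]

    def test_counts_on_mixed_fixture(self):
        rng = np.random.default_rng(1)
        isos = []
        for i in range(7):
            isos.append(AlignedIsoform(f"ok{i}", "c1", "+", ((0, 10),)))
        for i, (cov, ident) in enumerate([(0.9, 1.0), (1.0, 0.9), (0.5, 0.5)]):
            isos.append(AlignedIsoform(f"bad{i}", "c1", "+", ((0, 10),),
                                       coverage=cov, identity=ident))
        assert len(filter_alignments(isos)) == 7

    def test_target_region_restriction(self):
        isos = [
            AlignedIsoform("in", "c1", "+", ((100, 200),)),
            AlignedIsoform("out", "c1", "+", ((500, 600),)),
            AlignedIsoform("other", "c2", "+", ((100, 200),)),
        ]
        keep = filter_alignments(isos, target_regions={"c1": [(150, 160)]})
        assert [i.isoform_id for i in keep] == ["in"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            filter_alignments([], min_coverage=1.2)


def fl_read(rid, blocks, sample="s1", contig="c1", strand="+"):
    return sd.LongReadRecord(
        read_id=rid, sample_barcode=sample, has_5p_primer=True,
        has_3p_primer=True, has_polyA=True, inner_5p_barcode=None,
        inner_3p_barcode=None, contig=contig, strand=strand,
        blocks=tuple(blocks), truth_transcript_id="T", truth_chimera=False,
    )


class TestCollapse:
    def test_same_chain_different_ends_collapse(self):
        r1 = fl_read("r1", [(100, 200), (300, 400)])
        r2 = fl_read("r2", [(150, 200), (300, 450)], sample="s2")
        (only,) = collapse_reads([r1, r2])
        assert only.exons == ((100, 200), (300, 450))
        assert only.fl_counts == {"s1": 1, "s2": 1}
        assert only.total_fl_count == 2

    def test_different_chains_stay_separate(self):
        r1 = fl_read("r1", [(100, 200), (300, 400)])
        r2 = fl_read("r2", [(100, 200), (350, 400)])
        assert len(collapse_reads([r1, r2])) == 2

    def test_mono_exon_single_linkage(self):
        r1 = fl_read("r1", [(100, 200)])
        r2 = fl_read("r2", [(150, 250)])
        r3 = fl_read("r3", [(400, 500)])
        isos = collapse_reads([r1, r2, r3])
        assert sorted(i.exons for i in isos) == [((100, 250),), ((400, 500),)]

    def test_collapse_recovers_expressed_chains(self, sim20, sim20_expression):
        """Without chimeras or truncation, distinct isoforms equal the
        distinct expressed junction chains."""
        _, ann = sim20
        reads = sd.simulate_long_reads(
            sim20_expression, ann, n_reads=8000, fl_rate=1.0,
            chimera_rate=0.0, seed=21,
        )
        isos = collapse_reads(reads)
        observed = {(i.contig, i.strand, i.introns()) for i in isos}
        expressed_tids = {r.truth_transcript_id for r in reads}
        expected = {
            (t.contig, t.strand, t.introns())
            for tid in expressed_tids
            for t in [ann.transcripts[tid]]
        }
        assert observed == expected


class TestIntronRetention:
    def test_exon_spanning_annotated_intron(self, reference):
        q = iso([(100, 600), (700, 800)])
        assert detect_intron_retention(q, reference, "GR") is True

    def test_fsm_is_never_retained(self, reference):
        q = iso([(100, 200), (300, 400), (500, 600), (700, 800)])
        rec = classify_isoform(q, reference)
        assert rec.category == "FSM" and rec.intron_retention is False

    def test_against_per_base_oracle(self, sim20):
        """Set-based oracle: an isoform retains an intron iff its exonic
        bases cover all of some annotated intron plus at least one base of
        each flanking exon."""
        _, ann = sim20
        rng = np.random.default_rng(7)
        checked = 0
        for tid in sorted(ann.transcripts):
            t = ann.transcripts[tid]
            q = iso(t.exons, strand=t.strand, contig=t.contig, iid=tid)
            got = detect_intron_retention(q, ann, t.gene_id)
            bases = set()
            for s, e in t.exons:
                bases.update(range(s, e))
            want = False
            for other_id in ann.genes[t.gene_id]:
                o = ann.transcripts[other_id]
                for i in range(len(o.exons) - 1):
                    intron = set(range(o.exons[i][1], o.exons[i + 1][0]))
                    left = set(range(*o.exons[i]))
                    right = set(range(*o.exons[i + 1]))
                    if intron <= bases and (left & bases) and (right & bases):
                        want = True
            assert got == want, tid
            checked += 1
        assert checked > 50


class TestReports:
    def test_all_fsm_recovery_one(self, reference):
        isos = {
            "q1": iso([(100, 200), (300, 400), (500, 600), (700, 800)], iid="q1"),
            "q2": iso([(100, 200), (500, 600), (700, 800)], iid="q2"),
            "q3": iso([(2000, 2100), (2300, 2400)], strand="-", iid="q3"),
        }
        records = [classify_isoform(i, reference) for i in isos.values()]
        table = recovery_statistics(records, isos, reference)
        row = table[table.stratum == "all"].iloc[0]
        assert row.gene_recovery == 1.0 and row.isoform_recovery == 1.0

    def test_nnc_only_gene_detected_but_not_isoform(self, reference):
        q = iso([(100, 200), (300, 408), (500, 600), (700, 800)], iid="q1")
        records = [classify_isoform(q, reference)]
        table = recovery_statistics(records, {"q1": q}, reference)
        row = table[table.stratum == "all"].iloc[0]
        assert row.n_genes_detected == 1
        assert row.n_isoforms_detected == 0

    def test_novelty_all_fsm_is_zero(self, reference):
        isos = {"q1": iso([(100, 200), (300, 400), (500, 600), (700, 800)], iid="q1")}
        records = [classify_isoform(isos["q1"], reference)]
        summ = novelty_summary(records, isos, reference)
        assert summ["novel_isoform_fraction"] == 0.0
        assert summ["novel_junction_fraction"] == 0.0
        assert summ["novel_splice_site_fraction"] == 0.0

    def test_novelty_counts_distinct_elements_once(self, reference):
        # one NNC isoform contributing 1 novel donor; shared sites and
        # junctions between the two isoforms are counted once
        q1 = iso([(100, 200), (300, 408), (500, 600), (700, 800)], iid="q1")
        q2 = iso([(100, 200), (300, 400), (500, 600), (700, 800)], iid="q2")
        isos = {"q1": q1, "q2": q2}
        records = [classify_isoform(q, reference) for q in isos.values()]
        summ = novelty_summary(records, isos, reference)
        # donors {200,400,408,600}, acceptors {300,500,700} -> 7 distinct
        assert summ["n_distinct_splice_sites"] == 7
        assert summ["novel_splice_site_fraction"] == pytest.approx(1 / 7)
        assert summ["novel_junction_fraction"] == pytest.approx(1 / 4)
        assert summ["novel_isoform_fraction"] == 0.5


class TestPipelineInvariants:
    def test_category_partition_and_fsm_purity(self, bundle):
        cats = {"FSM", "ISM", "NIC", "NNC", "mono-exon-known",
                "mono-exon-novel", "intergenic"}
        for rec in bundle["records"]:
            assert rec.category in cats
            if rec.category == "FSM":
                assert rec.novel_junctions == []
                assert rec.novel_splice_sites == []

    def test_novelty_amplification_ordering(self, bundle):
        """Site-level novelty amplifies through junctions to isoforms:
        isoform fraction >= junction fraction >= splice-site fraction."""
        summ = novelty_summary(
            bundle["records"], bundle["iso_by_id"], bundle["reference"]
        )
        assert (
            summ["novel_isoform_fraction"]
            >= summ["novel_junction_fraction"]
            >= summ["novel_splice_site_fraction"]
        )

    def test_tsl_confirmations_counted(self, bundle):
        summ = novelty_summary(
            bundle["records"], bundle["iso_by_id"], bundle["reference"]
        )
        assert summ["tsl_2_to_5_confirmed"] == sum(
            v for k, v in summ["tsl_confirmations"].items() if k >= 2
        )
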