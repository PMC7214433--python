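"""CAGE support, polyA motif scanning, splice-site conservation, and the
short-read novel-junction validation filter."""

import numpy as np
import pytest

from capiso import feature_annotation as fa
from capiso import genomic_model as gm
from capiso.isoform_classification import AlignedIsoform, classify_isoform
from conftest import make_tx


def iso(exons, strand="+", contig="chr1", iid="q"):
    return AlignedIsoform(isoform_id=iid, contig=contig, strand=strand,
                          exons=tuple(exons))


class TestCage:
    def test_five_prime_at_center(self):
        peaks = fa.CagePeaks({"chr1": [(990, 1010)]})  # center 1000
        d, within = fa.cage_annotate(iso([(1000, 1200)]), peaks)
        assert d == 0 and within

    def test_half_open_peak_boundary(self):
        peaks = fa.CagePeaks({"chr1": [(1000, 1100)]})
        _, within_inside = fa.cage_annotate(iso([(1099, 1300)]), peaks)
        _, within_outside = fa.cage_annotate(iso([(1100, 1300)]), peaks)
        assert within_inside is True
        assert within_outside is False

    def test_no_peaks_on_contig(self):
        peaks = fa.CagePeaks({"chr2": [(0, 10)]})
        d, within = fa.cage_annotate(iso([(100, 200)]), peaks)
        assert d is None and within is False

    def test_sign_convention_upstream_negative(self):
        peaks = fa.CagePeaks({"chr1": [(990, 1010)]})  # center 1000
        d_plus, _ = fa.cage_annotate(iso([(980, 1200)]), peaks)
        assert d_plus == -20  # 5' end upstream of center on '+'
        d_minus, _ = fa.cage_annotate(iso([(800, 1021)], strand="-"), peaks)
        assert d_minus == -20  # 5' end at 1020, upstream of center on '-'

    def test_nearest_center_matches_linear_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            centers_ivs = []
            for _ in range(int(rng.integers(1, 20))):
                s = int(rng.integers(0, 10000))
                w = int(rng.integers(1, 60))
                centers_ivs.append((s, s + w))
            peaks = fa.CagePeaks({"c": centers_ivs})
            pos = int(rng.integers(0, 10000))
            got = peaks.nearest_center("c", pos)
            oracle = min(((s + e) // 2 for s, e in centers_ivs),
                         key=lambda c: abs(c - pos))
            assert abs(got - pos) == abs(oracle - pos)


def genome_with(seq, name="chr1"):
    return gm.GenomeRef({name: seq})


class TestPolyaScan:
    def test_motif_last_base_five_upstream(self):
        # 3' end at position 100; motif occupying offsets 10..5 upstream
        seq = ["C"] * 200
        seq[90:96] = list("AATAAA")  # last base at 95 = 5 upstream of 100
        g = genome_with("".join(seq))
        found, motif, offset = fa.polya_motif_scan(iso([(0, 101)]), g)
        assert found and motif == "AATAAA" and offset == 5

    def test_motif_outside_window_not_found(self):
        seq = ["C"] * 200
        seq[65:71] = list("AATAAA")  # last base at 70 = 30 upstream of 100
        g = genome_with("".join(seq))
        found, _, _ = fa.polya_motif_scan(iso([(0, 101)]), g)
        assert not found

    def test_minus_strand_reverse_complement(self):
        # sense AATAAA on '-' = genomic TTTATT downstream of the 3' end
        seq = ["C"] * 200
        seq[105:111] = list("TTTATT")  # sense last base offset 5 from 3' end 100
        g = genome_with("".join(seq))
        found, motif, offset = fa.polya_motif_scan(iso([(100, 180)], strand="-"), g)
        assert found and motif == "AATAAA" and offset == 5

    def test_window_truncated_at_contig_start(self):
        # 3' end at 11: window truncates to [0, 7) and still finds the
        # motif at offset 6; a 3' end at 8 leaves a 4-base window, too
        # short for any hexamer
        g = genome_with("AATAAA" + "C" * 10)
        found, _, offset = fa.polya_motif_scan(iso([(0, 12)]), g)
        assert found and offset == 6
        found_short, _, _ = fa.polya_motif_scan(iso([(0, 9)]), g)
        assert not found_short

    def test_agrees_with_brute_force_window_search(self):
        """Random sequences: scan result equals explicit substring search
        over the sense window [5, 25] nt upstream of the 3' end."""
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        for k in range(1000):
            seq = "".join(rng.choice(bases, size=120))
            strand = "+" if k % 2 == 0 else "-"
            q = iso([(10, 110)], strand=strand)
            g = genome_with(seq)
            found, motif, offset = fa.polya_motif_scan(q, g)
            # oracle: build the sense window explicitly
            if strand == "+":
                window = seq[109 - 25: 109 - 4]
            else:
                window = gm.reverse_complement(seq[10 + 5: 10 + 26])
            best = None
            for m in fa.POLYA_MOTIFS:
                for i in range(len(window) - 5):
                    if window[i:i + 6] == m:
                        off = 5 + (len(window) - (i + 6))
                        if best is None or off < best[0]:
                            best = (off, m)
            if best is None:
                assert not found
            else:
                assert (found, motif, offset) == (True, best[1], best[0])


class TestJunctionConservation:
    def test_plus_strand_positions(self):
        # intron (200, 300): donor {199,200,201}, acceptor {298,299,300}
        track = gm.ScoreTrack({"chr1": [(p, p + 1, float(p)) for p in
                                        (199, 200, 201, 298, 299, 300)]})
        q = iso([(100, 200), (300, 400)])
        donors, acceptors, _, _ = fa.junction_conservation(q, track)
        assert donors == [(199.0, 200.0, 201.0)]
        assert acceptors == [(298.0, 299.0, 300.0)]

    def test_constant_track_all_ones(self):
        track = gm.ScoreTrack({"chr1": [(0, 1000, 1.0)]})
        q = iso([(100, 200), (300, 400), (500, 600)])
        donors, acceptors, _, _ = fa.junction_conservation(q, track)
        for tri in donors + acceptors:
            assert tri == (1.0, 1.0, 1.0)

    def test_minus_strand_matches_enumeration(self):
        track = gm.ScoreTrack({"chr1": [(p, p + 1, float(p)) for p in range(600)]})
        q = iso([(100, 200), (300, 400)], strand="-")
        donors, acceptors, _, _ = fa.junction_conservation(q, track)
        # '-' donor at the right intron boundary, sense order e, e-1, e-2
        assert donors == [(300.0, 299.0, 298.0)]
        assert acceptors == [(201.0, 200.0, 199.0)]

    def test_missing_positions_stay_missing(self):
        track = gm.ScoreTrack({"chr1": [(199, 202, 2.0)]})
        q = iso([(100, 200), (300, 400)])
        donors, acceptors, _, _ = fa.junction_conservation(q, track)
        assert donors == [(2.0, 2.0, 2.0)]
        assert acceptors == [(None, None, None)]

    def test_dinucleotides_with_genome(self, sim20):
        genome, ann = sim20
        tid = sorted(ann.transcripts)[0]
        t = ann.transcripts[tid]
        q = iso(t.exons, strand=t.strand, contig=t.contig)
        track = gm.ScoreTrack({})
        _, _, dd, ad = fa.junction_conservation(q, track, genome)
        assert set(dd) == {"GT"} and set(ad) == {"AG"}


@pytest.fixture()
def validation_setup():
    ref = gm.AnnotationSet.build([
        make_tx("R1", [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]),
    ])
    # four query isoforms, each introducing one novel junction with
    # different short-read support
    supports = {0: 0, 1: 2, 2: 3, 3: 10}
    isos = {}
    records = []
    counts = {}
    for k, support in supports.items():
        shift = 3 + k  # novel donor shift
        exons = [(0, 100 + shift), (200, 300), (400, 500), (600, 700), (800, 900)]
        q = iso(exons, iid=f"q{k}")
        isos[q.isoform_id] = q
        rec = classify_isoform(q, ref)
        assert rec.novel_junctions == [(100 + shift, 200)]
        records.append(rec)
        counts[("chr1", 100 + shift, 200, "+")] = support
    fsm = iso([(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)], iid="fsm")
    isos["fsm"] = fsm
    records.append(classify_isoform(fsm, ref))
    return ref, isos, records, counts


class TestValidation:
    def test_exact_support_threshold(self, validation_setup):
        _, isos, records, counts = validation_setup
        _, filtered = fa.validate_novel_isoforms(records, isos, counts, min_support=3)
        kept = {r.isoform_id for r in filtered}
        # support 3 (inclusive) and 10 survive; 0 and 2 do not; FSM vacuous
        assert kept == {"q2", "q3", "fsm"}

    def test_missing_junction_counts_zero(self, validation_setup):
        _, isos, records, _ = validation_setup
        _, filtered = fa.validate_novel_isoforms(records, isos, {}, min_support=3)
        assert {r.isoform_id for r in filtered} == {"fsm"}

    def test_monotone_in_min_support(self, validation_setup):
        _, isos, records, counts = validation_setup
        kept_sizes = []
        for ms in (0, 1, 3, 5, 11):
            _, filtered = fa.validate_novel_isoforms(records, isos, counts, ms)
            kept_sizes.append(len(filtered))
        assert kept_sizes == sorted(kept_sizes, reverse=True)

    def test_conjunction_over_novel_junctions(self):
        ref = gm.AnnotationSet.build([
            make_tx("R1", [(0, 100), (200, 300), (400, 500), (600, 700)]),
        ])
        # two novel junctions: one supported, one not
        q = iso([(0, 105), (200, 310), (400, 500), (600, 700)], iid="q")
        rec = classify_isoform(q, ref)
        assert len(rec.novel_junctions) == 2
        counts = {("chr1", 105, 200, "+"): 10, ("chr1", 310, 400, "+"): 2}
        _, filtered = fa.validate_novel_isoforms([rec], {"q": q}, counts, 3)
        assert filtered == []


class TestAnnotateFeatures:
    def test_fields_absent_without_inputs(self, validation_setup):
        _, isos, records, _ = validation_setup
        feats = fa.annotate_features(records, isos)
        for fr in feats:
            assert fr.cage_distance is None
            assert fr.polya_motif_found is False
            assert fr.validated is True

    def test_pipeline_features_cover_all_isoforms(self, bundle):
        assert {f.isoform_id for f in bundle["features"]} == set(bundle["iso_by_id"])
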