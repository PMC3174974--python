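import pytest

from cisd import classify, motif
from cisd.classify import ArchitectureAnnotation, Segment
from cisd.io import SequenceRecord
from cisd.motif import MotifHit


def hit(start, status="strict"):
    return MotifHit(record_id="r", start=start, window="X" * 17, status=status,
                    ligand_positions=(start + 1, start + 3, start + 12, start + 16))


class TestAssignType:
    def test_tandem_motifs_are_type6(self):
        # motifs end at start+16; gap of 20 residues between them
        call = classify.assign_type([hit(10), hit(47)], taxon="bacteria")
        assert call.cisd_type == "6"
        assert any(e.startswith("tandem_spacing") for e in call.evidence)

    def test_tandem_plus_cterminal_fmn_is_type5(self):
        arch = ArchitectureAnnotation([Segment("FMN_binding", 120, 280)])
        call = classify.assign_type([hit(10), hit(47)], arch, taxon="bacteria")
        assert call.cisd_type == "5"
        assert "fmn_fusion" in call.evidence

    def test_duf1271_fusion_is_type7(self):
        arch = ArchitectureAnnotation([Segment("DUF1271", 1, 70)])
        call = classify.assign_type([hit(90)], arch, taxon="bacteria")
        assert call.cisd_type == "7" and call.subtype7 == "DC"

    @pytest.mark.parametrize("taxon,expected", [
        ("eukaryote", "1"), ("apicomplexa", "2"), ("archaea", "3"), ("bacteria", "4"),
    ])
    def test_single_motif_taxon_defaults(self, taxon, expected):
        call = classify.assign_type([hit(30)], taxon=taxon)
        assert call.cisd_type == expected and call.confidence == "taxonomic"

    def test_no_motif_is_orphan_with_evidence(self):
        call = classify.assign_type([], taxon="bacteria")
        assert call.cisd_type == "orphan" and "no_motif" in call.evidence

    def test_disrupted_hits_do_not_define_architecture(self):
        call = classify.assign_type([hit(30), hit(67, "disrupted")], taxon="bacteria")
        assert call.cisd_type == "4"

    def test_his_to_cys_counts_as_motif_bearing(self):
        call = classify.assign_type([hit(10), hit(47, "his_to_cys")], taxon="bacteria")
        assert call.cisd_type == "6"

    def test_annotated_motif_segment_rescues_disrupted_tandem(self):
        """A fully disrupted second motif with an exact annotation still
        gives the tandem architecture."""
        arch = ArchitectureAnnotation([Segment("CISD_motif", 10, 26),
                                       Segment("CISD_motif", 47, 63)])
        call = classify.assign_type([hit(10), hit(47, "disrupted")], arch,
                                    taxon="bacteria")
        assert call.cisd_type == "6"

    def test_architecture_beats_taxonomy(self):
        # a tandem-motif archaeal sequence is type 6, not 3
        call = classify.assign_type([hit(10), hit(47)], taxon="archaea")
        assert call.cisd_type == "6"

    def test_spacing_outside_range_not_tandem(self):
        call = classify.assign_type([hit(10), hit(110)], taxon="bacteria",
                                    spacing_range=(5, 40))
        assert call.cisd_type == "4"

    def test_homology_override(self):
        # a bacterial single-motif sequence closest to the archaeal-style
        # seeds is reassigned by homology
        seeds = {
            "3": [SequenceRecord("s3", "MKVACDCAATAAAPACDGSHKLMNPQ")],
            "4": [SequenceRecord("s4", "WWWWYYYYHHHHKKKKRRRRDDDDEE")],
        }
        seq = SequenceRecord("q", "MKVACDCAATAAAPACDGSHKLMNPR")
        call = classify.assign_type([hit(4)], taxon="bacteria", seeds=seeds,
                                    sequence=seq)
        assert call.cisd_type == "3" and call.confidence == "homology"

    def test_unknown_taxon_rejected(self):
        with pytest.raises(classify.ClassificationError):
            classify.assign_type([hit(1)], taxon="martian")

    def test_every_call_has_evidence(self):
        for motifs, taxon in ([[], "unknown"], [[hit(5)], "eukaryote"],
                              [[hit(5), hit(42)], "bacteria"]):
            assert classify.assign_type(motifs, taxon=taxon).evidence


class TestSubtype7:
    @pytest.mark.parametrize("kinds,expected", [
        (["DUF1271", "CISD_motif"], "DC"),
        (["DUF1271", "CISD_motif", "CISD_motif"], "DCC"),
        (["CISD_motif", "DUF1271", "CISD_motif"], "CDC"),
    ])
    def test_linear_orders(self, kinds, expected):
        segs = [Segment(k, 100 * i + 1, 100 * i + 50) for i, k in enumerate(kinds)]
        assert classify.assign_subtype7(ArchitectureAnnotation(segs)) == expected

    def test_bad_arrangement_reports_order(self):
        segs = [Segment("CISD_motif", 1, 17), Segment("CISD_motif", 50, 66),
                Segment("DUF1271", 100, 160)]
        with pytest.raises(classify.ClassificationError, match="CCD"):
            classify.assign_subtype7(ArchitectureAnnotation(segs))


class TestColumnConservation:
    def test_identical_rows(self):
        aln = [SequenceRecord(f"r{i}", "MKV") for i in range(5)]
        assert classify.column_conservation(aln, 2, {"K"}) == 1.0

    def test_counted_by_hand(self):
        rows = ["MKV", "MKV", "MKV", "MRV", "MRV"]
        aln = [SequenceRecord(f"r{i}", s) for i, s in enumerate(rows)]
        assert classify.column_conservation(aln, 2, {"K"}) == pytest.approx(0.6)

    def test_gap_rows_excluded_from_denominator(self):
        rows = ["MKV", "M-V", "MKV", "M-V"]
        aln = [SequenceRecord(f"r{i}", s) for i, s in enumerate(rows)]
        assert classify.column_conservation(aln, 2, {"K"}) == 1.0

    def test_ragged_alignment_raises(self):
        aln = [SequenceRecord("a", "MKV"), SequenceRecord("b", "MK")]
        with pytest.raises(classify.ClassificationError):
            classify.column_conservation(aln, 1, {"M"})


class TestDeterminism:
    def test_order_independent(self, sequences_500):
        """Classification of a record does not depend on the surrounding
        record order (pure function of its own inputs)."""
        data = sequences_500
        calls = {}
        for rec, truth in zip(data.records, data.truth):
            hits = motif.scan_cdgsh(rec, max_mismatch=2)
            calls[rec.id] = classify.assign_type(hits, truth.architecture, truth.taxon)
        for rec, truth in reversed(list(zip(data.records, data.truth))):
            hits = motif.scan_cdgsh(rec, max_mismatch=2)
            assert classify.assign_type(hits, truth.architecture, truth.taxon) == calls[rec.id]
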