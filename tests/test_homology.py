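"""Orthology evidence, structure-aware alignment and exon-homology rules."""

import pytest

from crossplice.homology import (
    AlignScoring,
    OrthologyEvidence,
    align_with_structure,
    assess_exon_homology,
    blast_reciprocal_rule,
    build_exon_clusters,
    build_gene_clusters,
    exon_residue_spans,
)
from crossplice.model import ProteinIsoform


class TestBlastReciprocal:
    def test_reciprocal_within_top3(self):
        hits = {"a": [("x", 9.0), ("b", 8.0)], "b": [("y", 9.0), ("z", 8.0), ("a", 7.0)]}
        ev = blast_reciprocal_rule(hits)
        assert OrthologyEvidence("a", "b", "blastp") in ev

    def test_rank_four_excluded(self):
        hits = {
            "a": [("w", 9.0), ("x", 8.0), ("y", 7.0), ("b", 6.0)],
            "b": [("a", 9.0)],
        }
        assert blast_reciprocal_rule(hits) == set()

    def test_ties_at_rank_three_count(self):
        hits = {
            "a": [("x", 9.0), ("y", 8.0), ("z", 7.0), ("b", 7.0)],  # b ties 3rd
            "b": [("a", 9.0)],
        }
        ev = blast_reciprocal_rule(hits)
        assert OrthologyEvidence("a", "b", "blastp") in ev


class TestGeneClusters:
    def test_two_of_three_rule(self):
        ev = {
            OrthologyEvidence("A", "B", "oma"),
            OrthologyEvidence("A", "B", "blastp"),
            OrthologyEvidence("B", "C", "multiparanoid"),
        }
        clusters = build_gene_clusters(ev)
        assert {"A", "B"} in clusters and {"C"} in clusters

    def test_guilt_by_association(self):
        ev = set()
        for pair in (("A", "B"), ("B", "C")):
            ev.add(OrthologyEvidence(*pair, "oma"))
            ev.add(OrthologyEvidence(*pair, "blastp"))
        assert {"A", "B", "C"} in build_gene_clusters(ev)

    def test_edge_order_invariance(self):
        ev = [
            OrthologyEvidence("A", "B", "oma"),
            OrthologyEvidence("A", "B", "blastp"),
            OrthologyEvidence("C", "B", "oma"),
            OrthologyEvidence("C", "B", "multiparanoid"),
        ]
        fwd = build_gene_clusters(ev)
        rev = build_gene_clusters(ev[::-1])
        assert sorted(map(sorted, fwd)) == sorted(map(sorted, rev))


def iso(seq: str, junctions, gene="g", iso_id="t") -> ProteinIsoform:
    return ProteinIsoform(gene_id=gene, isoform_id=iso_id, sequence=seq, junction_map=junctions)


class TestAlignment:
    def test_identical_sequences_identity_alignment(self):
        a = iso("MKLVAAAQRS", [(3, 1)])
        st = align_with_structure(a, iso("MKLVAAAQRS", [(3, 1)], gene="h"))
        assert st.gapped_a == st.gapped_b == "MKLVAAAQRS"
        assert st.markers_a == st.markers_b == [(3, 1)]

    def test_insertion_projects_markers_to_same_column(self):
        # an insertion before the junction becomes a gap in the other
        # species, so conserved intron positions still share one column
        a = iso("MKLVAQRS", [(5, 0)])
        b = iso("MKLWVAQRS", [(6, 0)])
        st = align_with_structure(a, b)
        assert st.markers_b[0][0] == st.markers_a[0][0]

    def test_intron_sliding_shifts_marker_column(self):
        a = iso("MKLVAQRS", [(5, 0)])
        b = iso("MKLVAQRS", [(6, 0)], gene="h")  # junction slid by one residue
        st = align_with_structure(a, b)
        assert st.markers_b[0][0] == st.markers_a[0][0] + 1

    def test_exon_spans_from_junction_map(self):
        spans = exon_residue_spans(iso("A" * 12, [(4, 0), (8, 2)]))
        assert spans == [(0, 4), (4, 8), (8, 12)]


def _three_exon_iso(up, alt, down, gene="g"):
    seq = up + alt + down
    junctions = [(len(up), 0), (len(up) + len(alt), 0)]
    return iso(seq, junctions, gene=gene)


UP = "MKWLERNYCHD"
ALT = "FPQITVGASMK"
DOWN = "WYEHRLNDCQS"


class TestExonHomology:
    def test_identical_isoforms_automatic_full_similarity(self):
        a = _three_exon_iso(UP, ALT, DOWN)
        b = _three_exon_iso(UP, ALT, DOWN, gene="h")
        v = assess_exon_homology(align_with_structure(a, b), 1)[1]
        assert v.status == "automatic" and v.similarity == pytest.approx(100.0)

    def test_phase_mismatch_flags_for_review(self):
        a = _three_exon_iso(UP, ALT, DOWN)
        b = iso(UP + ALT + DOWN, [(len(UP), 1), (len(UP) + len(ALT), 1)], gene="h")
        v = assess_exon_homology(align_with_structure(a, b), 1)[1]
        assert v.status == "manual_flag" and v.introns_conserved == (False, False)

    @pytest.mark.parametrize("offset,expected", [(3, "automatic"), (4, "manual_flag")])
    def test_marker_offset_tolerance(self, offset, expected):
        # intron sliding: b's upstream junction sits `offset` residues
        # downstream of a's on an otherwise identical protein
        a = _three_exon_iso(UP, ALT, DOWN)
        b = iso(
            UP + ALT + DOWN,
            [(len(UP) + offset, 0), (len(UP) + len(ALT), 0)],
            gene="h",
        )
        v = assess_exon_homology(align_with_structure(a, b), 1)[1]
        assert v.status == expected

    def test_similarity_boundary_at_twenty_percent(self):
        # identity mode: 2/10 identical = 20% (not > 20) fails; 3/10 passes
        scoring = AlignScoring(similarity_mode="identity")
        alt_a = "FPQITVGASM"
        alt_20 = "FPWWWWWWWW"  # 2 of 10 identical
        alt_30 = "FPQWWWWWWW"  # 3 of 10
        a = _three_exon_iso(UP, alt_a, DOWN)
        low = assess_exon_homology(
            align_with_structure(a, _three_exon_iso(UP, alt_20, DOWN, gene="h"), scoring), 1
        )[1]
        high = assess_exon_homology(
            align_with_structure(a, _three_exon_iso(UP, alt_30, DOWN, gene="h"), scoring), 1
        )[1]
        assert low.status == "manual_flag"  # structure holds, similarity fails
        assert high.status == "automatic"

    def test_multi_candidate_realignment_keeps_best(self):
        # a's long alt exon straddles two exons of b, so both b candidates
        # exceed the similarity cutoff; local realignment must keep only the
        # higher-similarity candidate
        half1, half2 = "FPQITVGASMK", "RDENWCHYLTV"
        half2_div = "RDENAAAYLTV"  # diverged copy of the second half
        a = _three_exon_iso(UP, half1 + half2, DOWN)
        b = iso(
            UP + half1 + half2_div + DOWN,
            [
                (len(UP), 0),
                (len(UP) + len(half1), 0),
                (len(UP) + len(half1) + len(half2_div), 0),
            ],
            gene="h",
        )
        verdicts = assess_exon_homology(align_with_structure(a, b), 1, candidate_indices_b=[1, 2])
        assert verdicts[1].similarity > 20.0 and verdicts[2].similarity > 20.0
        assert verdicts[1].status != "none" and verdicts[2].status == "none"

    def test_structure_clause_symmetric_in_species_order(self):
        a = _three_exon_iso(UP, ALT, DOWN)
        b_up = UP[:5] + "GG" + UP[5:]
        b = iso(b_up + ALT + DOWN, [(len(b_up), 0), (len(b_up) + len(ALT), 0)], gene="h")
        v_ab = assess_exon_homology(align_with_structure(a, b), 1)[1]
        v_ba = assess_exon_homology(align_with_structure(b, a), 1)[1]
        assert v_ab.introns_conserved == v_ba.introns_conserved
        assert v_ab.status == v_ba.status


class TestExonClusters:
    def test_transitive_assembly(self):
        pairs = [
            (("h", "g1", "e1"), ("m", "g2", "e2")),
            (("m", "g2", "e2"), ("z", "g3", "e3")),
        ]
        clusters = build_exon_clusters(pairs)
        assert any(len(c.members) == 3 for c in clusters)

    def test_singleton_reported_for_unpaired_exon(self):
        clusters = build_exon_clusters([], all_exons=[("h", "g1", "e1")])
        assert len(clusters) == 1 and clusters[0].members == {("h", "g1", "e1")}

    def test_conflicting_same_gene_exons_flagged_not_merged_away(self):
        pairs = [
            (("h", "g1", "e1"), ("m", "g2", "e2")),
            (("h", "g1", "e9"), ("m", "g2", "e2")),  # second exon of the same gene
        ]
        clusters = build_exon_clusters(pairs)
        cl = next(c for c in clusters if len(c.members) == 3)
        assert cl.conflicts  # flagged, component kept

    def test_idempotent_and_order_independent(self):
        pairs = [
            (("h", "g1", "e1"), ("m", "g2", "e2")),
            (("m", "g2", "e2"), ("z", "g3", "e3")),
        ]
        a = build_exon_clusters(pairs)
        b = build_exon_clusters(pairs[::-1])
        assert [sorted(c.members) for c in a] == [sorted(c.members) for c in b]
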