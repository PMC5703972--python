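"""Motif scanning, region schema, coverage/conservation profiles, and
direct/indirect classification."""

import numpy as np
import pytest

import oracles
from crossplice.model import AsEvent, GeneModel, MotifSet, ScoreTrack, Transcript
from crossplice.motifs import (
    EventHits,
    classify_direct_indirect,
    conservation_profile,
    coverage_profile,
    covered_positions,
    extract_regions,
    region_schema_segments,
    scan_motifs,
    shared_regulation_enrichment,
    smooth_trailing,
    windowed_fraction,
)

GU = MotifSet(["GTGTGT"])


class TestScan:
    def test_overlapping_occurrences(self):
        assert scan_motifs("GTGTGTGT", GU) == [0, 2]

    def test_no_hits(self):
        assert scan_motifs("AAAAAAAA", GU) == []

    def test_u_alphabet_equivalent(self):
        assert scan_motifs("GUGUGUGU", GU) == scan_motifs("GTGTGTGT", GU)

    def test_short_sequence_empty(self):
        assert scan_motifs("GTG", GU) == []

    def test_duplicate_motifs_do_not_change_hits(self):
        dup = MotifSet(["GTGTGT", "GUGUGU"])
        assert scan_motifs("GTGTGTGT", dup) == scan_motifs("GTGTGTGT", GU)


def _event_setup(up_len=100, alt_len=90, dn_len=100, i1=400, i2=400, strand="+"):
    lengths = [up_len, i1, alt_len, i2, dn_len]
    pos, ivs = 50, []
    for ln in lengths:
        ivs.append((pos, pos + ln))
        pos += ln
    total = pos + 50
    seq = "A" * total
    if strand == "+":
        exons = [ivs[0], ivs[2], ivs[4]]
    else:
        seq = seq  # coordinates mirror below
        exons = [(total - ivs[0][1], total - ivs[0][0]),
                 (total - ivs[2][1], total - ivs[2][0]),
                 (total - ivs[4][1], total - ivs[4][0])]
    model = GeneModel("g", "sp", "c", strand, {"t": Transcript("t", exons)})
    event = AsEvent("ev", "g", "AltEx", exons[1], exons[0], exons[2])
    return model, event, seq


class TestRegions:
    def test_short_intron_segments_overlap(self):
        model, event, seq = _event_setup(i2=400)
        regions = extract_regions(event, model, {"c": seq})
        segs = region_schema_segments(regions)
        assert len(segs["dn_intron_5p"]) == 250 and len(segs["dn_intron_3p"]) == 250
        assert len(regions.dn_intron) == 400  # segments [0,250) and [150,400) overlap

    def test_short_alt_exon_neglected(self):
        model, event, seq = _event_setup(alt_len=60)
        segs = region_schema_segments(extract_regions(event, model, {"c": seq}))
        assert "alt_exon_5p" not in segs and "alt_exon_3p" not in segs

    def test_minus_strand_reverse_complemented(self):
        model, event, seq = _event_setup(strand="-")
        # put a motif at the transcript-oriented start of the alt exon
        alt = event.alt_interval
        s = list(seq)
        # transcript 5' end of the exon is the genomic *end* on '-'
        s[alt[1] - 6 : alt[1]] = list("ACACAC")  # revcomp('ACACAC')='GTGTGT'
        regions = extract_regions(event, model, {"c": "".join(s)})
        assert regions.alt_exon.startswith("GTGTGT")


class TestCoverage:
    def test_zero_hits_zero_profile(self):
        prof = windowed_fraction(covered_positions(120, [], 6))
        assert np.all(prof == 0)

    def test_single_mid_segment_hit_value(self):
        # one hexamer centred in a long segment: 6 covered positions in a
        # full 51-nt window -> 6/51 at the hit's centre
        cov = covered_positions(200, [97], 6)
        prof = windowed_fraction(cov, 51)
        assert prof[100] == pytest.approx(6 / 51)

    def test_saturated_segment_interior_one(self):
        cov = covered_positions(100, list(range(0, 95)), 6)
        prof = windowed_fraction(cov, 51)
        assert np.all(prof == 1.0)

    def test_profile_matches_bruteforce_on_random_sequences(self, rng):
        motifs = MotifSet(["GTGTGT", "TGGTGG"])
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 300))))
            hits = scan_motifs(seq, motifs)
            got = windowed_fraction(covered_positions(len(seq), hits, 6), 51)
            want = oracles.oracle_window_profile(seq, motifs.as_set(), 6, 51)
            assert np.allclose(got, want)

    def test_mean_across_events_and_counts(self):
        segs1 = {"alt_exon_5p": "GTGTGTA" + "A" * 68}
        segs2 = {"alt_exon_5p": "A" * 75}
        prof = coverage_profile([segs1, segs2], GU)
        assert prof.n_events["alt_exon_5p"] == 2
        single = coverage_profile([segs1], GU)
        assert np.allclose(prof.segments["alt_exon_5p"], single.segments["alt_exon_5p"] / 2)


def hits(alt=(), up=(), dn=(), L_up=400, L_dn=400, n_upx=0, n_dnx=0):
    return EventHits(
        alt_exon=set(alt),
        up_intron=set(up),
        dn_intron=set(dn),
        up_intron_len=L_up,
        dn_intron_len=L_dn,
        n_up_exon_junction=n_upx,
        n_dn_exon_junction=n_dnx,
    )


class TestClassifier:
    def test_silenced_motif_in_alt_exon_is_direct(self):
        assert classify_direct_indirect("silenced", hits(alt=[10])) == "direct"

    def test_enhanced_splice_site_span_excluded(self):
        # motifs only within the first 6 nt of the downstream intron: not
        # direct (5'ss excluded) and not indirect (downstream intron occupied)
        assert classify_direct_indirect("enhanced", hits(dn=[2])) == "discarded"

    def test_silenced_no_motifs_anywhere_is_indirect(self):
        assert classify_direct_indirect("silenced", hits()) == "indirect"

    def test_silenced_5prime_splice_site_span_allowed(self):
        assert classify_direct_indirect("silenced", hits(dn=[2])) == "direct"

    def test_enhanced_downstream_intron_direct(self):
        assert classify_direct_indirect("enhanced", hits(dn=[100])) == "direct"

    def test_enhanced_upstream_3ss_motif_blocks_indirect(self):
        # motif in the last 250 nt of the upstream intron: not allowed in the
        # restricted scenario, and it vetoes the indirect label
        assert classify_direct_indirect("enhanced", hits(up=[300])) == "discarded"

    def test_expanded_upstream_first250_allows_silenced(self):
        h = hits(up=[100])
        assert classify_direct_indirect("silenced", h, "restricted") == "discarded"
        assert classify_direct_indirect("silenced", h, "expanded") == "direct"

    def test_expanded_enhanced_acceptor_exclusion(self):
        # upstream-intron motif within 50 nt of the 3' splice site stays
        # disallowed even in the expanded scenario
        h_near = hits(up=[380])  # L_up=400 -> within the last 50
        h_far = hits(up=[100])
        assert classify_direct_indirect("enhanced", h_near, "expanded") == "discarded"
        assert classify_direct_indirect("enhanced", h_far, "expanded") == "direct"

    def test_min_motifs_monotone(self):
        h = hits(alt=[10, 40])
        labels = [classify_direct_indirect("silenced", h, min_motifs=m) for m in (1, 2, 3, 4)]
        assert labels == ["direct", "direct", "discarded", "discarded"]

    def test_restricted_direct_implies_expanded_direct(self, rng):
        for _ in range(200):
            h = hits(
                alt=rng.integers(0, 80, size=rng.integers(0, 3)).tolist(),
                up=rng.integers(0, 400, size=rng.integers(0, 3)).tolist(),
                dn=rng.integers(0, 400, size=rng.integers(0, 3)).tolist(),
                n_upx=int(rng.integers(0, 2)),
            )
            for direction in ("enhanced", "silenced"):
                if classify_direct_indirect(direction, h, "restricted") == "direct":
                    assert classify_direct_indirect(direction, h, "expanded") == "direct"


class TestFisher:
    def test_fully_separated_table(self):
        from math import comb

        p = shared_regulation_enrichment(10, 0, 0, 10)
        assert p == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_balanced_table_not_significant(self):
        assert shared_regulation_enrichment(5, 5, 5, 5) > 0.5

    def test_all_zero_table(self):
        assert shared_regulation_enrichment(0, 0, 0, 0) == 1.0


class TestConservation:
    def test_constant_track_constant_profile(self):
        track = ScoreTrack({"c": np.full(1000, 0.7)})
        mean, n = conservation_profile([("c", 400, 500)], track)
        assert len(mean) == 100 + 300 and np.allclose(mean, 0.7)

    def test_step_track_matches_bruteforce_smoothing(self):
        vals = np.concatenate([np.zeros(200), np.ones(200)])
        track = ScoreTrack({"c": vals})
        mean, _ = conservation_profile([("c", 150, 250)], track)
        want = oracles.oracle_smooth(list(vals[0:400]), 10)
        assert np.allclose(mean, want)

    def test_out_of_bounds_exon_skipped(self):
        track = ScoreTrack({"c": np.ones(300)})
        mean, n = conservation_profile([("c", 10, 50)], track)  # flank exceeds bounds
        assert len(mean) == 0

    def test_smoothing_window_anchoring(self):
        vals = np.arange(20, dtype=float)
        got = smooth_trailing(vals, 10)
        assert got[0] == pytest.approx(np.mean(vals[0:10]))
        assert got[15] == pytest.approx(np.mean(vals[15:20]))
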