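"""Synthetic-data generator: determinism, evolutionary limits, PSI noise
model, motif planting, and referential closure of the ground truth."""

import numpy as np
import pytest

from crossplice.model import SampleDesign, SampleInfo
from crossplice.motifs import extract_regions, scan_event, scan_motifs
from crossplice.simulate import (
    DEFAULT_MOTIFS,
    SimParams,
    default_design,
    plant_motifs,
    simulate_expression_counts,
    simulate_gene_families,
    simulate_psi_tables,
    simulate_score_track,
)

TREE = "((a:1,b:1):1,c:2);"


def small_sim(seed=11, **kw):
    params = SimParams(n_families=8, **kw)
    return simulate_gene_families(TREE, params, seed=seed)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        s1, s2 = small_sim(seed=5), small_sim(seed=5)
        for sp in s1.species:
            assert s1.species[sp].genome == s2.species[sp].genome
        p1 = simulate_psi_tables(s1, default_design(), seed=9)
        p2 = simulate_psi_tables(s2, default_design(), seed=9)
        for sp in p1:
            assert p1[sp].data.equals(p2[sp].data)

    def test_single_leaf_tree_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_families("(only:1);", SimParams(n_families=1), seed=0)


class TestEvolutionLimits:
    def test_zero_divergence_identical_proteins(self):
        sim = small_sim(p_sub=0.0)
        for gt in sim.truth.genes:
            seqs = {
                sim.species[sp].isoforms[g][0].sequence for sp, g in gt.gene_ids.items()
            }
            assert len(seqs) == 1

    def test_no_gain_loss_identical_exon_counts(self):
        sim = small_sim(p_gain=0.0, p_loss=0.0)
        for gt in sim.truth.genes:
            counts = {
                len(next(iter(sim.species[sp].models[g].transcripts.values())).exons)
                for sp, g in gt.gene_ids.items()
            }
            assert len(counts) == 1

    def test_junction_phases_conserved_without_divergence(self):
        sim = small_sim(p_sub=0.0)
        for gt in sim.truth.genes:
            maps = {
                tuple(sim.species[sp].isoforms[g][0].junction_map)
                for sp, g in gt.gene_ids.items()
            }
            assert len(maps) == 1


class TestPsiSampling:
    def test_loss_and_gain_shift_signs(self):
        sim = small_sim(frac_dependent=1.0, p_constitutive=0.0, depth=4000)
        design = SampleDesign(
            {
                "c1": SampleInfo("control", "loss", "1"),
                "l1": SampleInfo("perturbed", "loss", "1"),
            }
        )
        gain = SampleDesign(
            {
                "c1": SampleInfo("control", "gain", "1"),
                "g1": SampleInfo("perturbed", "gain", "1"),
            }
        )
        psi_loss = simulate_psi_tables(sim, design, seed=3)["a"]
        psi_gain = simulate_psi_tables(sim, gain, seed=3)["a"]
        for et in sim.truth.exons:
            ev = et.event_ids.get("a")
            if ev is None or not et.esrp_dependent:
                continue
            d_loss = psi_loss.record(ev, "c1")["psi"] - psi_loss.record(ev, "l1")["psi"]
            d_gain = psi_gain.record(ev, "c1")["psi"] - psi_gain.record(ev, "g1")["psi"]
            expect = et.effective_dpsi["a"]
            assert d_loss == pytest.approx(expect, abs=6.0)
            # gain-of-function reverses the shift (possibly clamped)
            if et.direction == "enhanced":
                assert d_gain <= 1.0
            else:
                assert d_gain >= -1.0

    def test_null_dpsi_shrinks_with_depth(self):
        """Standard error of observed dPSI scales ~ depth^-1/2."""
        spreads = {}
        for depth in (50, 200):
            sim = simulate_gene_families(
                "(a:1,b:1);",
                SimParams(n_families=600, frac_dependent=0.0, depth=depth, p_constitutive=0.0),
                seed=21,
            )
            psi = simulate_psi_tables(sim, default_design(1), seed=22)["a"]
            mat = psi.psi_matrix()
            dpsi = (mat["ctrl_1"] - mat["pert_1"]).to_numpy()
            spreads[depth] = np.nanstd(dpsi)
        ratio = spreads[50] / spreads[200]
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestMotifPlanting:
    def test_direct_enhanced_hits_in_downstream_intron(self):
        sim = small_sim(frac_dependent=1.0, frac_direct=1.0, frac_enhanced=1.0)
        plant_motifs(sim, DEFAULT_MOTIFS, "restricted", n_plant=2, seed=7)
        for et in sim.truth.exons:
            for sp_name, ev_id in et.event_ids.items():
                sp = sim.species[sp_name]
                ev = sp.events[ev_id]
                regions = extract_regions(ev, sp.models[ev.gene_id], sp.genome)
                n = len(scan_motifs(regions.dn_intron[:250], DEFAULT_MOTIFS))
                assert n >= 2

    def test_indirect_targets_scrubbed_clean(self):
        sim = small_sim(frac_dependent=1.0, frac_direct=0.0)
        plant_motifs(sim, DEFAULT_MOTIFS, "restricted", seed=7)
        for et in sim.truth.exons:
            for sp_name, ev_id in et.event_ids.items():
                sp = sim.species[sp_name]
                ev = sp.events[ev_id]
                regions = extract_regions(ev, sp.models[ev.gene_id], sp.genome)
                h = scan_event(regions, DEFAULT_MOTIFS)
                assert not h.alt_exon and not h.up_intron and not h.dn_intron


class TestClosure:
    def test_truth_entities_resolve_to_generated_objects(self):
        sim = small_sim()
        psi = simulate_psi_tables(sim, default_design(), seed=2)
        counts = simulate_expression_counts(sim, default_design(), seed=3)
        for et in sim.truth.exons:
            assert sorted(et.event_ids) == et.species_present
            for sp, ev in et.event_ids.items():
                assert ev in sim.species[sp].events
                assert psi[sp].has_event(ev)
        for gt in sim.truth.genes:
            for sp, g in gt.gene_ids.items():
                assert g in sim.species[sp].models
                assert g in set(counts[sp]["gene_id"])

    def test_score_track_matches_genome_geometry(self):
        sim = small_sim()
        track = simulate_score_track(sim.species["a"], seed=4)
        for chrom, seq in sim.species["a"].genome.items():
            arr = track.arrays[chrom]
            assert len(arr) == len(seq)
            assert np.all((arr >= 0) & (arr <= 1))
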