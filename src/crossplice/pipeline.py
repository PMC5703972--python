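"""End-to-end orchestration: simulate -> diffsplice/diffexpr -> exon
homology -> regulatory maps/scenarios -> cross-species comparison.

Every stage reads its inputs from and writes its outputs to the run
directory, so stages can also be invoked individually on an existing
run.  A JSON manifest records the effective configuration, the seed and
a SHA-256 checksum of every output file; re-running with the same
configuration and seed reproduces the checksums exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compare as xsp
from . import diffexpr as dex
from . import diffsplice as dsp
from . import io as cio
from . import motifs as mot
from . import simulate as sim_mod
from .homology import (
    AlignScoring,
    ExonKey,
    align_with_structure,
    assess_exon_homology,
    build_exon_clusters,
    build_gene_clusters,
)
from .model import SampleDesign, derive_protein_junction_map

DEFAULT_TREE = "((human:1,mouse:1):1,zebrafish:2);"


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "run"
    species_tree: str = DEFAULT_TREE
    replicates: int = 2
    scenario: str = "restricted"
    min_motifs: int = 1
    window: int = 51
    sim: sim_mod.SimParams = field(default_factory=sim_mod.SimParams)
    # per-species calling thresholds; every leaf of the tree needs an entry
    species_params: dict = field(default_factory=dict)
    expr_params: dict = field(
        default_factory=lambda: {
            "min_crpkm": 2.0,
            "min_reads": 50,
            "min_avg_fold": 2.0,
            "min_pairwise_fold": 1.5,
        }
    )

    def leaves(self) -> list[str]:
        _, leaves = sim_mod._parse_tree(self.species_tree)
        return leaves

    def validate(self) -> None:
        required = ("min_dpsi", "min_pairwise")
        for sp in self.leaves():
            if sp not in self.species_params:
                raise ValueError(f"config missing species_params.{sp}")
            for key in required:
                if key not in self.species_params[sp]:
                    raise ValueError(f"config missing species_params.{sp}.{key}")

    def splice_params(self, species: str) -> dsp.SpeciesParams:
        d = dict(self.species_params[species])
        return dsp.SpeciesParams(species=species, **d)

    def diffexpr_params(self, species: str) -> dex.ExprParams:
        return dex.ExprParams(species=species, **self.expr_params)


def default_config(outdir: str = "run", seed: int = 1, **overrides) -> RunConfig:
    cfg = RunConfig(outdir=outdir, seed=seed, **overrides)
    for sp in cfg.leaves():
        cfg.species_params.setdefault(sp, {"min_dpsi": 15.0, "min_pairwise": 5.0})
    return cfg


def _p(cfg: RunConfig, *parts: str) -> str:
    return os.path.join(cfg.outdir, *parts)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> sim_mod.Simulation:
    os.makedirs(_p(cfg, "inputs"), exist_ok=True)
    sim = sim_mod.simulate_gene_families(cfg.species_tree, cfg.sim, seed=cfg.seed)
    sim_mod.plant_motifs(sim, sim_mod.DEFAULT_MOTIFS, cfg.scenario, n_plant=2, seed=cfg.seed + 1)
    design = sim_mod.default_design(cfg.replicates)
    psi = sim_mod.simulate_psi_tables(sim, design, seed=cfg.seed + 2)
    counts = sim_mod.simulate_expression_counts(sim, design, seed=cfg.seed + 3)
    evidence = sim_mod.simulate_orthology_evidence(sim, seed=cfg.seed + 4)
    design.to_frame().to_csv(_p(cfg, "inputs", "design.tsv"), sep="\t", index=False)
    cio.write_motif_list(sim_mod.DEFAULT_MOTIFS, _p(cfg, "inputs", "motifs.txt"))
    cio.write_evidence_table(evidence, _p(cfg, "inputs", "evidence.tsv"))
    for i, (sp_name, sp) in enumerate(sorted(sim.species.items())):
        cio.write_fasta(sp.genome, _p(cfg, "inputs", f"{sp_name}.genome.fa"))
        cio.write_gene_models(sp.models, _p(cfg, "inputs", f"{sp_name}.models.gtf"))
        cio.write_fasta(
            {iso.isoform_id: iso.sequence for isos in sp.isoforms.values() for iso in isos},
            _p(cfg, "inputs", f"{sp_name}.proteins.fa"),
        )
        cio.write_psi_table(psi[sp_name], _p(cfg, "inputs", f"{sp_name}.psi.tsv"))
        cio.write_counts_table(counts[sp_name], _p(cfg, "inputs", f"{sp_name}.counts.tsv"))
        cio.write_events_table(sp.events, _p(cfg, "inputs", f"{sp_name}.events.tsv"))
        track = sim_mod.simulate_score_track(sp, seed=cfg.seed + 5 + i)
        cio.write_bedgraph(track, _p(cfg, "inputs", f"{sp_name}.track.bedgraph"))
    sim.truth.to_json(_p(cfg, "inputs", "truth.json"))
    return sim


def _load_design(cfg: RunConfig) -> SampleDesign:
    return SampleDesign.from_frame(pd.read_csv(_p(cfg, "inputs", "design.tsv"), sep="\t"))


def stage_diffsplice(cfg: RunConfig, rescue: dict[str, set] | None = None) -> dict:
    os.makedirs(_p(cfg, "results"), exist_ok=True)
    design = _load_design(cfg)
    calls = {}
    for sp in cfg.leaves():
        table = cio.read_psi_table(_p(cfg, "inputs", f"{sp}.psi.tsv"))
        params = cfg.splice_params(sp)
        calls[sp] = dsp.call_species_events(
            table, design, params, rescue_candidates=(rescue or {}).get(sp, ())
        )
        dsp.calls_to_frame(calls[sp]).to_csv(
            _p(cfg, "results", f"{sp}.diffsplice.tsv"), sep="\t", index=False
        )
    return calls


def stage_diffexpr(cfg: RunConfig) -> dict:
    os.makedirs(_p(cfg, "results"), exist_ok=True)
    design = _load_design(cfg)
    calls = {}
    totals = {s: cfg.sim.library_size for s in design.sample_ids()}
    for sp in cfg.leaves():
        counts = cio.read_counts_table(_p(cfg, "inputs", f"{sp}.counts.tsv"))
        expr = dex.crpkm_table(counts, totals=totals)
        calls[sp] = dex.call_diff_genes(expr, design, cfg.diffexpr_params(sp))
        dex.calls_to_frame(calls[sp]).to_csv(
            _p(cfg, "results", f"{sp}.diffexpr.tsv"), sep="\t", index=False
        )
    return calls


def _load_species_data(cfg: RunConfig, sp: str):
    genome = cio.read_fasta(_p(cfg, "inputs", f"{sp}.genome.fa"))
    models = cio.read_gene_models(_p(cfg, "inputs", f"{sp}.models.gtf"), species=sp)
    events = cio.read_events_table(_p(cfg, "inputs", f"{sp}.events.tsv"))
    return genome, models, events


def _alt_exon_index(model, event) -> int:
    tx = next(iter(model.transcripts.values()))
    for i, iv in enumerate(tx.exons):
        if tuple(iv) == tuple(event.alt_interval):
            return i
    raise ValueError(f"event {event.event_id}: alt exon not found in transcript")


def stage_exonhom(cfg: RunConfig, scoring: AlignScoring | None = None) -> list:
    """Gene clusters from evidence, then structure-aware exon pairing."""
    os.makedirs(_p(cfg, "results"), exist_ok=True)
    scoring = scoring or AlignScoring()
    evidence = cio.read_evidence_table(_p(cfg, "inputs", "evidence.tsv"))
    data = {sp: _load_species_data(cfg, sp) for sp in cfg.leaves()}
    all_genes = [g for sp in cfg.leaves() for g in data[sp][1]]
    gene_clusters = build_gene_clusters(evidence, genes=all_genes)
    cio.write_gene_clusters(gene_clusters, _p(cfg, "results", "gene_clusters.tsv"))

    gene_species = {g: sp for sp in cfg.leaves() for g in data[sp][1]}
    gene_event = {}
    for sp in cfg.leaves():
        for ev in data[sp][2].values():
            gene_event[ev.gene_id] = ev

    # approvals of manually flagged pairs, if the operator provided any
    approvals: set[tuple[str, str]] = set()
    approvals_path = _p(cfg, "inputs", "approvals.tsv")
    if os.path.exists(approvals_path):
        df = pd.read_csv(approvals_path, sep="\t")
        approvals = {tuple(sorted((r["event_a"], r["event_b"]))) for _, r in df.iterrows()}

    accepted: list[tuple[ExonKey, ExonKey]] = []
    review_rows = []
    all_keys: list[ExonKey] = []
    for sp in cfg.leaves():
        for ev in data[sp][2].values():
            all_keys.append((sp, ev.gene_id, ev.event_id))
    iso_cache: dict[str, object] = {}

    def isoform(sp: str, gene_id: str):
        if gene_id not in iso_cache:
            genome, models, _ = data[sp]
            model = models[gene_id]
            tx_id = next(iter(model.transcripts))
            iso_cache[gene_id] = derive_protein_junction_map(model, tx_id, genome=genome)
        return iso_cache[gene_id]

    for cluster in gene_clusters:
        genes = sorted(g for g in cluster if g in gene_event)
        for i, ga in enumerate(genes):
            for gb in genes[i + 1 :]:
                sa, sb = gene_species[ga], gene_species[gb]
                if sa == sb:
                    continue
                ev_a, ev_b = gene_event[ga], gene_event[gb]
                model_a, model_b = data[sa][1][ga], data[sb][1][gb]
                idx_a = _alt_exon_index(model_a, ev_a)
                idx_b = _alt_exon_index(model_b, ev_b)
                structure = align_with_structure(isoform(sa, ga), isoform(sb, gb), scoring)
                verdicts = assess_exon_homology(structure, idx_a)
                v = verdicts.get(idx_b)
                if v is None:
                    continue
                key_a: ExonKey = (sa, ga, ev_a.event_id)
                key_b: ExonKey = (sb, gb, ev_b.event_id)
                pair_id = tuple(sorted((ev_a.event_id, ev_b.event_id)))
                if v.status == "automatic" or (v.status == "manual_flag" and pair_id in approvals):
                    accepted.append((key_a, key_b))
                elif v.status == "manual_flag":
                    review_rows.append(
                        {
                            "event_a": ev_a.event_id,
                            "event_b": ev_b.event_id,
                            "similarity": round(v.similarity, 2),
                            "introns_conserved": f"{v.introns_conserved[0]},{v.introns_conserved[1]}",
                        }
                    )
    exon_clusters = build_exon_clusters(accepted, all_keys)
    cio.write_exon_clusters(exon_clusters, _p(cfg, "results", "exon_clusters.tsv"))
    pd.DataFrame(
        review_rows, columns=["event_a", "event_b", "similarity", "introns_conserved"]
    ).to_csv(_p(cfg, "results", "manual_review.tsv"), sep="\t", index=False)
    return exon_clusters


def stage_maps(cfg: RunConfig, calls: dict) -> None:
    """Regulatory-map coverage profiles plus conservation profiles."""
    motifs = cio.read_motif_list(_p(cfg, "inputs", "motifs.txt"))
    rows = []
    for sp in cfg.leaves():
        genome, models, events = _load_species_data(cfg, sp)
        classes: dict[str, list] = {"enhanced": [], "silenced": [], "background": []}
        coords: list[tuple[str, int, int]] = []
        for ev in events.values():
            call = calls[sp].get(ev.event_id)
            regions = mot.extract_regions(ev, models[ev.gene_id], genome)
            segs = mot.region_schema_segments(regions)
            if call is not None and call.called:
                classes[call.direction].append(segs)
                coords.append((models[ev.gene_id].chrom, *ev.alt_interval))
            else:
                classes["background"].append(segs)
        for cls, seg_sets in classes.items():
            if not seg_sets:
                continue
            profile = mot.coverage_profile(seg_sets, motifs, window=cfg.window)
            for seg in mot.SCHEMA_SEGMENTS:
                if seg not in profile.segments:
                    continue
                for pos, val in enumerate(profile.segments[seg]):
                    rows.append(
                        {
                            "species": sp,
                            "class": cls,
                            "segment": seg,
                            "position": pos,
                            "value": round(float(val), 6),
                            "n_events": profile.n_events[seg],
                        }
                    )
        # conservation over called exons
        lengths = {c: len(s) for c, s in genome.items()}
        track = cio.read_bedgraph(_p(cfg, "inputs", f"{sp}.track.bedgraph"), lengths)
        mean, n = mot.conservation_profile(coords, track)
        cons = pd.DataFrame(
            {
                "position": np.arange(len(mean)),
                "value": np.round(mean, 6),
                "n_exons": n,
            }
        )
        cons.to_csv(_p(cfg, "results", f"{sp}.conservation.tsv"), sep="\t", index=False)
    pd.DataFrame(rows).to_csv(_p(cfg, "results", "regulatory_maps.tsv"), sep="\t", index=False)


def stage_scenarios(cfg: RunConfig, calls: dict) -> dict:
    motifs = cio.read_motif_list(_p(cfg, "inputs", "motifs.txt"))
    labels: dict[str, dict[str, str]] = {}
    for sp in cfg.leaves():
        genome, models, events = _load_species_data(cfg, sp)
        rows = []
        labels[sp] = {}
        for ev in events.values():
            call = calls[sp].get(ev.event_id)
            if call is None or not call.called:
                continue
            regions = mot.extract_regions(ev, models[ev.gene_id], genome)
            hits = mot.scan_event(regions, motifs)
            label = mot.classify_direct_indirect(
                call.direction, hits, cfg.scenario, cfg.min_motifs
            )
            labels[sp][ev.event_id] = label
            rows.append({"event_id": ev.event_id, "direction": call.direction, "target_class": label})
        pd.DataFrame(rows, columns=["event_id", "direction", "target_class"]).to_csv(
            _p(cfg, "results", f"{sp}.targets.tsv"), sep="\t", index=False
        )
    return labels


def stage_compare(cfg: RunConfig, calls: dict, clusters, labels: dict) -> pd.DataFrame:
    psi = {sp: cio.read_psi_table(_p(cfg, "inputs", f"{sp}.psi.tsv")) for sp in cfg.leaves()}
    summary = xsp.overlap_summary(calls, clusters, psi)
    summary.to_csv(_p(cfg, "results", "overlap_summary.tsv"), sep="\t", index=False)
    xsp.summarize_overlap_counts(summary).to_csv(
        _p(cfg, "results", "overlap_counts.tsv"), sep="\t", index=False
    )
    status_rows = []
    for cluster in clusters:
        for sp in cfg.leaves():
            st = xsp.classify_homolog_status(cluster, sp, psi.get(sp))
            status_rows.append(
                {
                    "cluster_id": st.cluster_id,
                    "species": st.species,
                    "status": st.status,
                    "coverage_ok": st.coverage_ok,
                }
            )
    pd.DataFrame(status_rows).to_csv(_p(cfg, "results", "homolog_status.tsv"), sep="\t", index=False)

    # direct vs indirect shared-regulation enrichment per species
    enr_rows = []
    shared_events = {
        (r["species"], r["event_id"]): len(r["shared_with"].split(",")) > 1
        for _, r in summary.iterrows()
        if r["category"] == "shared"
    }
    for sp in cfg.leaves():
        table = {"direct": [0, 0], "indirect": [0, 0]}
        for event_id, label in labels.get(sp, {}).items():
            if label not in table or (sp, event_id) not in shared_events:
                continue
            table[label][0 if shared_events[(sp, event_id)] else 1] += 1
        p = mot.shared_regulation_enrichment(
            table["direct"][0], table["direct"][1], table["indirect"][0], table["indirect"][1]
        )
        enr_rows.append(
            {
                "species": sp,
                "direct_shared": table["direct"][0],
                "direct_not": table["direct"][1],
                "indirect_shared": table["indirect"][0],
                "indirect_not": table["indirect"][1],
                "p_one_sided": p,
            }
        )
    pd.DataFrame(enr_rows).to_csv(_p(cfg, "results", "shared_enrichment.tsv"), sep="\t", index=False)
    return summary


def stage_recovery(cfg: RunConfig, calls: dict, expr_calls: dict, clusters, labels: dict) -> dict:
    """Score pipeline outputs against the simulation's ground truth."""
    truth = sim_mod.SimTruth.from_json(_p(cfg, "inputs", "truth.json"))
    metrics: dict = {}
    # differential splicing
    tp = fp = fn = tn = 0
    for et in truth.exons:
        for sp, event_id in et.event_ids.items():
            if sp not in calls:
                continue
            call = calls[sp].get(event_id)
            called = bool(call and call.called)
            positive = et.esrp_dependent and et.alternative.get(sp, False)
            tp += called and positive
            fp += called and not positive
            fn += positive and not called
            tn += not positive and not called
    metrics["diffsplice"] = {
        "sensitivity": tp / max(tp + fn, 1),
        "false_call_rate": fp / max(fp + tn, 1),
        "n_positive": tp + fn,
        "n_negative": fp + tn,
    }
    # differential expression
    tp = fp = fn = tn = 0
    for gt in truth.genes:
        for sp, gene_id in gt.gene_ids.items():
            if sp not in expr_calls:
                continue
            called = gene_id in expr_calls[sp]
            tp += called and gt.de
            fp += called and not gt.de
            fn += gt.de and not called
            tn += not gt.de and not called
    metrics["diffexpr"] = {
        "sensitivity": tp / max(tp + fn, 1),
        "false_call_rate": fp / max(fp + tn, 1),
    }
    # exon-cluster recovery (pairs of focal events across species)
    scores = exon_cluster_pair_scores(truth, clusters)
    metrics["exon_clusters"] = {k: scores[k] for k in ("precision", "recall", "f1")}
    # direct/indirect classification of called, truly dependent exons
    n_ok = n_tot = 0
    for et in truth.exons:
        if not et.esrp_dependent:
            continue
        want = "direct" if et.direct else "indirect"
        for sp, event_id in et.event_ids.items():
            got = labels.get(sp, {}).get(event_id)
            if got is None:
                continue
            n_tot += 1
            n_ok += got == want
    metrics["target_classes"] = {
        "accuracy": n_ok / max(n_tot, 1),
        "n": n_tot,
    }
    with open(_p(cfg, "results", "recovery_metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return metrics


# ---------------------------------------------------------------------------
# In-memory homology pass (no file round-trip); used by recovery studies
# ---------------------------------------------------------------------------


def exon_clusters_from_simulation(sim, evidence, scoring: AlignScoring | None = None):
    """Run the gene-clustering + exon-homology path directly on a
    :class:`~crossplice.simulate.Simulation`; returns (exon_clusters,
    gene_clusters)."""
    scoring = scoring or AlignScoring()
    all_genes = [g for sp in sim.species.values() for g in sp.models]
    gene_clusters = build_gene_clusters(evidence, genes=all_genes)
    gene_species = {g: sp_name for sp_name, sp in sim.species.items() for g in sp.models}
    gene_event = {
        ev.gene_id: ev for sp in sim.species.values() for ev in sp.events.values()
    }
    accepted: list[tuple[ExonKey, ExonKey]] = []
    all_keys: list[ExonKey] = [
        (sp_name, ev.gene_id, ev.event_id)
        for sp_name, sp in sorted(sim.species.items())
        for ev in sp.events.values()
    ]
    for cluster in gene_clusters:
        genes = sorted(g for g in cluster if g in gene_event)
        for i, ga in enumerate(genes):
            for gb in genes[i + 1 :]:
                sa, sb = gene_species[ga], gene_species[gb]
                if sa == sb:
                    continue
                ev_a, ev_b = gene_event[ga], gene_event[gb]
                model_a = sim.species[sa].models[ga]
                model_b = sim.species[sb].models[gb]
                iso_a = sim.species[sa].isoforms[ga][0]
                iso_b = sim.species[sb].isoforms[gb][0]
                idx_a = _alt_exon_index(model_a, ev_a)
                idx_b = _alt_exon_index(model_b, ev_b)
                structure = align_with_structure(iso_a, iso_b, scoring)
                v = assess_exon_homology(structure, idx_a).get(idx_b)
                if v is not None and v.status == "automatic":
                    accepted.append(((sa, ga, ev_a.event_id), (sb, gb, ev_b.event_id)))
    return build_exon_clusters(accepted, all_keys), gene_clusters


def exon_cluster_pair_scores(truth, clusters) -> dict:
    """Precision/recall/F1 of cross-species exon pairing versus truth."""
    true_pairs = set()
    for et in truth.exons:
        evs = sorted(et.event_ids.values())
        for i, a in enumerate(evs):
            for b in evs[i + 1 :]:
                true_pairs.add((a, b))
    pred_pairs = set()
    for cl in clusters:
        mem = sorted(m[2] for m in cl.members)
        for i, a in enumerate(mem):
            for b in mem[i + 1 :]:
                pred_pairs.add((a, b))
    inter = len(true_pairs & pred_pairs)
    prec = inter / max(len(pred_pairs), 1)
    rec = inter / max(len(true_pairs), 1)
    return {
        "precision": prec,
        "recall": rec,
        "f1": 2 * prec * rec / max(prec + rec, 1e-12),
        "n_true_pairs": len(true_pairs),
        "n_pred_pairs": len(pred_pairs),
    }


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in dependency order and write the run manifest."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    stage_simulate(cfg)
    calls = stage_diffsplice(cfg)
    expr_calls = stage_diffexpr(cfg)
    clusters = stage_exonhom(cfg)
    # low-coverage rescue: events whose homologous exon is called elsewhere
    rescue: dict[str, set] = {sp: set() for sp in cfg.leaves()}
    by_event = {m[2]: cl for cl in clusters for m in cl.members}
    for sp, sp_calls in calls.items():
        for event_id, call in sp_calls.items():
            if not call.called or event_id not in by_event:
                continue
            for other_sp, _, other_event in by_event[event_id].members:
                if other_sp != sp:
                    rescue[other_sp].add(other_event)
    if any(rescue.values()):
        calls = stage_diffsplice(cfg, rescue=rescue)
    labels = stage_scenarios(cfg, calls)
    stage_maps(cfg, calls)
    stage_compare(cfg, calls, clusters, labels)
    metrics = stage_recovery(cfg, calls, expr_calls, clusters, labels)

    files = {}
    for sub in ("inputs", "results"):
        d = _p(cfg, sub)
        for name in sorted(os.listdir(d)):
            files[f"{sub}/{name}"] = cio.sha256_file(os.path.join(d, name))
    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "files": files,
    }
    cio.write_manifest(manifest, _p(cfg, "manifest.json"))
    return metrics


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("outdir", None)  # path-independent manifests
    return d
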