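"""Cross-species regulatory-conservation bookkeeping.

Assigns every called exon to exactly one of: NH (no homologous
counterpart in any other species), NC (homologs exist but at least one
homolog-bearing species lacks sufficient read coverage), or a shared-set
membership recording the species in which the exon is regulated in the
same (loss-of-function-oriented) direction.  Also classifies each
homolog per species as absent-from-genome / constitutive / alternative,
and implements the cross-species GO category-selection rule on
precomputed enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffsplice import DiffSpliceCall
from .homology import ExonCluster, ExonKey
from .model import PsiTable, tier_at_least


@dataclass
class HomologParams:
    alt_lo: float = 10.0   # PSI bounds defining "alternatively spliced"
    alt_hi: float = 90.0
    alt_tier: str = "OK"   # tier floor for the alternative call
    coverage_tier: str = "VLOW"  # tier floor for "sufficient read coverage"


@dataclass
class HomologStatus:
    cluster_id: str
    species: str
    status: str  # not_in_genome | constitutive | alternative
    coverage_ok: bool
    regulated_same_direction: bool = False


def _event_coverage_ok(psi: PsiTable, event_id: str, tier_floor: str) -> bool:
    recs = psi.event_records(event_id)
    return all(
        not np.isnan(r["psi"]) and tier_at_least(r["tier"], tier_floor)
        for _, r in recs.iterrows()
    )


def classify_homolog_status(
    cluster: ExonCluster,
    species: str,
    psi: PsiTable | None,
    params: HomologParams | None = None,
    species_universe: Sequence[str] | None = None,
) -> HomologStatus:
    """Genome-presence / constitutive / alternative status of a cluster's
    exon in one species.

    "Alternative" means PSI within [alt_lo, alt_hi] in at least one
    sample at tier >= alt_tier; present exons failing that are
    constitutive.  ``psi`` may be None only when the species has no
    member in the cluster.
    """
    params = params or HomologParams()
    if species_universe is not None and species not in species_universe:
        raise ValueError(f"species {species!r} not in the analysis universe")
    members = [m for m in cluster.members if m[0] == species]
    if not members:
        return HomologStatus(cluster.cluster_id, species, "not_in_genome", False)
    if psi is None:
        raise ValueError(f"PSI table required for species {species!r}")
    event_id = members[0][2]
    if not psi.has_event(event_id):
        return HomologStatus(cluster.cluster_id, species, "not_in_genome", False)
    recs = psi.event_records(event_id)
    alternative = any(
        (not np.isnan(r["psi"]))
        and params.alt_lo <= r["psi"] <= params.alt_hi
        and tier_at_least(r["tier"], params.alt_tier)
        for _, r in recs.iterrows()
    )
    coverage = _event_coverage_ok(psi, event_id, params.coverage_tier)
    return HomologStatus(
        cluster.cluster_id,
        species,
        "alternative" if alternative else "constitutive",
        coverage,
    )


def overlap_summary(
    calls_by_species: Mapping[str, Mapping[str, DiffSpliceCall]],
    clusters: Sequence[ExonCluster],
    psi_by_species: Mapping[str, PsiTable],
    params: HomologParams | None = None,
) -> pd.DataFrame:
    """Assign every called exon to NH / NC / a shared regulation set.

    Returns one row per called exon with its category and, for shared
    exons, the sorted set of species sharing same-direction regulation.
    The exon identifier inside clusters is the species' event id.
    """
    params = params or HomologParams()
    by_key: dict[ExonKey, ExonCluster] = {}
    for cl in clusters:
        for m in cl.members:
            by_key[m] = cl
    rows = []
    for species, calls in calls_by_species.items():
        psi = psi_by_species[species]
        for event_id, call in calls.items():
            if not call.called:
                continue
            gene_id = psi.events.loc[event_id, "gene_id"] if psi.has_event(event_id) else ""
            key: ExonKey = (species, gene_id, event_id)
            cluster = by_key.get(key)
            others = (
                sorted({m[0] for m in cluster.members} - {species}) if cluster is not None else []
            )
            if not others:
                category, shared = "NH", ()
            else:
                lacking = [
                    sp
                    for sp in others
                    if not _homolog_covered(cluster, sp, psi_by_species.get(sp), params)
                ]
                if lacking:
                    category, shared = "NC", ()
                else:
                    same = {species}
                    for sp in others:
                        h_event = next(m[2] for m in cluster.members if m[0] == sp)
                        h_call = calls_by_species.get(sp, {}).get(h_event)
                        if h_call is not None and h_call.called and h_call.direction == call.direction:
                            same.add(sp)
                    category, shared = "shared", tuple(sorted(same))
            rows.append(
                {
                    "species": species,
                    "event_id": event_id,
                    "cluster_id": cluster.cluster_id if cluster is not None else "",
                    "category": category,
                    "shared_with": ",".join(shared),
                }
            )
    return pd.DataFrame(rows, columns=["species", "event_id", "cluster_id", "category", "shared_with"])


def _homolog_covered(
    cluster: ExonCluster, species: str, psi: PsiTable | None, params: HomologParams
) -> bool:
    if psi is None:
        return False
    members = [m for m in cluster.members if m[0] == species]
    if not members:
        return False
    event_id = members[0][2]
    if not psi.has_event(event_id):
        return False
    return _event_coverage_ok(psi, event_id, params.coverage_tier)


def summarize_overlap_counts(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-species NH / NC / shared-set counts from an overlap summary."""
    rows = []
    for species, sub in summary.groupby("species"):
        counts = sub["category"].value_counts().to_dict()
        shared_sets = sub.loc[sub["category"] == "shared", "shared_with"].value_counts().to_dict()
        rows.append(
            {
                "species": species,
                "NH": counts.get("NH", 0),
                "NC": counts.get("NC", 0),
                "shared": counts.get("shared", 0),
                "shared_sets": ";".join(f"{k}:{v}" for k, v in sorted(shared_sets.items())),
            }
        )
    return pd.DataFrame(rows)


def select_go_categories(
    tables: Mapping[str, pd.DataFrame],
    p_threshold: float = 0.05,
    ratio_threshold: float = 1.3,
    strict: bool = True,
) -> list[str]:
    """Cross-species GO category selection on precomputed enrichment tables.

    A category is selected iff its p-value is below ``p_threshold`` in at
    least one species and its observed/expected ratio exceeds
    ``ratio_threshold`` in every species.  In strict mode (default) a
    category untested in any species is excluded; otherwise the ratio
    clause applies only to the species where it was tested.
    """
    per_species = {
        sp: df.set_index("category")[["p", "ratio"]] for sp, df in tables.items()
    }
    all_categories = sorted(set().union(*(set(d.index) for d in per_species.values())))
    selected = []
    for cat in all_categories:
        tested = [sp for sp, d in per_species.items() if cat in d.index]
        if strict and len(tested) < len(per_species):
            continue
        if not any(per_species[sp].loc[cat, "p"] < p_threshold for sp in tested):
            continue
        if all(per_species[sp].loc[cat, "ratio"] > ratio_threshold for sp in tested):
            selected.append(cat)
    return selected
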