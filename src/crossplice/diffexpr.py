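"""cRPKM expression quantification and differential-expression filters.

cRPKM corrects RPKM for multi-mapping by dividing by the number of
uniquely mappable positions of the reference transcript rather than its
full length:

    cRPKM = reads / (mappable_length/1e3) / (total_mapped_reads/1e6)

A gene is called differentially expressed iff it passes, in order:
(i) cRPKM > 2 in both replicates of at least one condition;
(ii) at least 50 raw reads in at least one sample;
(iii) a minimum fold difference between the condition averages
(2 for zebrafish, 1.5 for sea urchin by default); and
(iv) a minimum fold difference between all cross-condition pairwise
replicate comparisons in a consistent direction (1.5 / 1.2).
Fold differences are symmetric (max/min) with direction tracked
separately; zero expression is floored at a pseudo-cRPKM before ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SampleDesign


@dataclass
class ExprParams:
    species: str = "generic"
    min_crpkm: float = 2.0
    min_reads: int = 50
    min_avg_fold: float = 2.0
    min_pairwise_fold: float = 1.5
    pseudo_crpkm: float = 0.01  # floor applied before any ratio


@dataclass
class DiffExprCall:
    gene_id: str
    direction: str  # up | down (in the perturbed condition)
    avg_fold: float
    min_pairwise_fold: float


def compute_crpkm(raw_reads: float, mappable_length_nt: float, total_mapped_reads: float) -> float:
    if mappable_length_nt <= 0:
        raise ValueError("mappable length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return raw_reads / (mappable_length_nt / 1e3) / (total_mapped_reads / 1e6)


def crpkm_table(counts: pd.DataFrame, totals: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Add a ``crpkm`` column to a counts table.

    ``totals`` maps sample -> total mapped reads; by default the
    per-sample sum of the table's reads is used as the library size.
    """
    if totals is None:
        totals = counts.groupby("sample")["reads"].sum().to_dict()
    out = counts.copy()
    out["crpkm"] = [
        compute_crpkm(r["reads"], r["mappable_length"], totals[r["sample"]])
        for _, r in counts.iterrows()
    ]
    return out


def _fold(a: float, b: float, floor: float) -> float:
    a, b = max(a, floor), max(b, floor)
    return max(a, b) / min(a, b)


def call_diff_genes(
    expr: pd.DataFrame,
    design: SampleDesign,
    params: ExprParams,
) -> dict[str, DiffExprCall]:
    """Apply the expression and fold-change filters gene by gene.

    ``expr`` is a long table with columns gene_id, sample, reads, crpkm.
    Direction is "up"/"down" in the perturbed condition.
    """
    controls = design.controls()
    perturbed = design.perturbed()
    calls: dict[str, DiffExprCall] = {}
    for gene_id, sub in expr.groupby("gene_id"):
        sub = sub.set_index("sample")
        if any(s not in sub.index for s in controls + perturbed):
            continue
        c = sub.loc[controls, "crpkm"].to_numpy(dtype=float)
        p = sub.loc[perturbed, "crpkm"].to_numpy(dtype=float)
        reads = sub.loc[controls + perturbed, "reads"].to_numpy(dtype=float)
        if not ((c > params.min_crpkm).all() or (p > params.min_crpkm).all()):
            continue
        if reads.max() < params.min_reads:
            continue
        floor = params.pseudo_crpkm
        avg_c, avg_p = max(c.mean(), floor), max(p.mean(), floor)
        avg_fold = _fold(avg_c, avg_p, floor)
        if avg_fold < params.min_avg_fold:
            continue
        # all cross-condition pairwise folds, consistent direction
        signs = set()
        ok = True
        for cv in c:
            for pv in p:
                f = _fold(cv, pv, floor)
                if f < params.min_pairwise_fold:
                    ok = False
                    break
                signs.add(max(pv, floor) >= max(cv, floor))
            if not ok:
                break
        if not ok or len(signs) > 1:
            continue
        direction = "up" if avg_p > avg_c else "down"
        if (avg_p >= avg_c) != signs.pop():
            continue  # average and pairwise directions disagree
        min_pf = min(
            _fold(cv, pv, floor) for cv in c for pv in p
        )
        calls[gene_id] = DiffExprCall(
            gene_id=gene_id,
            direction=direction,
            avg_fold=avg_fold,
            min_pairwise_fold=min_pf,
        )
    return calls


def calls_to_frame(calls: Mapping[str, DiffExprCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "direction": c.direction,
                "avg_fold": c.avg_fold,
                "min_pairwise_fold": c.min_pairwise_fold,
            }
            for c in calls.values()
        ]
    )
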