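"""Identification of splicing-factor-dependent AS events from PSI tables.

The calling scheme gates each event on read coverage (tier VLOW or
higher in all compared samples), then requires a minimum absolute
change between condition averages (|dPSI| of 15 for zebrafish/mouse or
10 for sea urchin by default) and a minimum dPSI of 5 between *all*
control x perturbed pairwise comparisons in one consistent direction.
Intron-retention events additionally require a non-significant binomial
read-imbalance test in every sample.  A multi-grouping combination mode
(for the human multi-source design, including pooled-read merged
samples and opposite-direction loss/gain pairing) and a low-coverage
rescue rule for events with homologs called in another species are
provided on top.

Direction convention: ``dpsi_avg = mean(control) - mean(perturbed)`` in
loss-of-function orientation, so positive values mean inclusion is
higher with the functional factor ("enhanced").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DEFAULT_TIER_BOUNDS,
    PsiTable,
    SampleDesign,
    tier_at_least,
    tier_from_reads,
)


@dataclass
class SpeciesParams:
    """Per-species calling thresholds.

    ``dpsi_inclusive`` controls the boundary convention: True means the
    average-dPSI cutoff is met at equality ("a minimum dPSI of 15"),
    False means a strict inequality ("|dPSI| > 15", the multi-source
    human phrasing).  The pairwise cutoff follows the same switch.
    """

    species: str = "generic"
    min_dpsi: float = 15.0
    min_pairwise: float = 5.0
    ir_alpha: float = 0.05
    min_tier: str = "VLOW"
    dpsi_inclusive: bool = True
    ir_two_sided: bool = True
    tier_bounds: tuple = DEFAULT_TIER_BOUNDS

    def __post_init__(self) -> None:
        if self.min_dpsi < self.min_pairwise:
            raise ValueError(
                f"min_dpsi ({self.min_dpsi}) must be >= min_pairwise ({self.min_pairwise})"
            )

    def _avg_ok(self, dpsi: float) -> bool:
        return abs(dpsi) >= self.min_dpsi if self.dpsi_inclusive else abs(dpsi) > self.min_dpsi

    def _pair_ok(self, values: Sequence[float], direction: int) -> bool:
        if self.dpsi_inclusive:
            return all(direction * v >= self.min_pairwise for v in values)
        return all(direction * v > self.min_pairwise for v in values)


@dataclass
class EventStats:
    dpsi_avg: float
    pairwise: list[float]
    coverage_ok: bool
    low_coverage_samples: list[str] = field(default_factory=list)


@dataclass
class DiffSpliceCall:
    event_id: str
    species: str
    direction: str | None  # enhanced | silenced | None
    dpsi_avg: float
    dpsi_pairwise_min: float
    coverage_ok: bool
    ir_balance_ok: bool | None  # None = not applicable / no evidence
    called: bool
    rescued: bool = False
    provenance: list[str] = field(default_factory=list)


def compute_event_stats(
    psi: PsiTable,
    design: SampleDesign,
    event_id: str,
    min_tier: str = "VLOW",
) -> EventStats:
    """Average and all-pairwise dPSI (control - perturbed) plus coverage gate."""
    recs = psi.event_records(event_id)
    controls = [s for s in design.controls() if s in recs.index]
    perturbed = [s for s in design.perturbed() if s in recs.index]
    if not controls or not perturbed:
        raise ValueError(f"event {event_id}: need >=1 control and >=1 perturbed sample")
    low = []
    for s in controls + perturbed:
        r = recs.loc[s]
        if np.isnan(r["psi"]) or not tier_at_least(r["tier"], min_tier):
            low.append(s)
    c_vals = [recs.loc[s, "psi"] for s in controls]
    p_vals = [recs.loc[s, "psi"] for s in perturbed]

    def _mean(vals):
        finite = [v for v in vals if not np.isnan(v)]
        return float(np.mean(finite)) if finite else float("nan")

    dpsi_avg = _mean(c_vals) - _mean(p_vals)
    pairwise = [float(c - p) for c in c_vals for p in p_vals]
    return EventStats(
        dpsi_avg=dpsi_avg,
        pairwise=pairwise,
        coverage_ok=not low,
        low_coverage_samples=low,
    )


def ir_balance_test(b5: int, b3: int, two_sided: bool = True) -> float | None:
    """Exact binomial p-value for imbalance between intron-boundary reads.

    Tests the observed (b5, b3) split against Binomial(b5+b3, 0.5).
    Returns None when both counts are zero (no evidence of balance; the
    event then fails IR gating).
    """
    if b5 < 0 or b3 < 0:
        raise ValueError("boundary read counts must be non-negative")
    n = b5 + b3
    if n == 0:
        return None
    if two_sided:
        return float(stats.binomtest(b5, n, 0.5, alternative="two-sided").pvalue)
    k = max(b5, b3)
    return float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)


def _ir_gate(recs: pd.DataFrame, samples: Iterable[str], params: SpeciesParams) -> bool | None:
    """True iff imbalance is non-significant in every sample; None if any
    sample lacks boundary-read evidence."""
    ok = True
    for s in samples:
        r = recs.loc[s]
        b5, b3 = r["b5"], r["b3"]
        if np.isnan(b5) or np.isnan(b3):
            return None
        p = ir_balance_test(int(b5), int(b3), two_sided=params.ir_two_sided)
        if p is None:
            return None
        if p < params.ir_alpha:
            ok = False
    return ok


def _evaluate(
    stats_: EventStats,
    is_ir: bool,
    ir_ok: bool | None,
    params: SpeciesParams,
    coverage_override: bool = False,
) -> tuple[bool, str | None, float]:
    """Apply thresholds; returns (called, direction, worst pairwise value)."""
    direction = 1 if stats_.dpsi_avg >= 0 else -1
    worst = min(stats_.pairwise) if direction > 0 else max(stats_.pairwise)
    passed = (
        (stats_.coverage_ok or coverage_override)
        and params._avg_ok(stats_.dpsi_avg)
        and params._pair_ok(stats_.pairwise, direction)
    )
    if is_ir:
        passed = passed and ir_ok is True
    label = None
    if passed:
        label = "enhanced" if direction > 0 else "silenced"
    return passed, label, float(worst)


def call_species_events(
    psi: PsiTable,
    design: SampleDesign,
    params: SpeciesParams,
    rescue_candidates: Iterable[str] = (),
) -> dict[str, DiffSpliceCall]:
    """Call factor-dependent events for one species.

    ``rescue_candidates`` lists event ids whose homologous exon was
    called in another species; those failing the coverage gate are
    re-admitted under the low-coverage rescue rule (exactly one sample
    below the tier floor with at least two supporting reads) and then
    re-evaluated against the same dPSI cutoffs.
    """
    rescue_candidates = set(rescue_candidates)
    calls: dict[str, DiffSpliceCall] = {}
    for event_id in psi.event_ids:
        ev_type = psi.events.loc[event_id, "type"]
        recs = psi.event_records(event_id)
        st = compute_event_stats(psi, design, event_id, min_tier=params.min_tier)
        is_ir = ev_type == "IR"
        compared = [s for s in design.sample_ids() if s in recs.index]
        ir_ok = _ir_gate(recs, compared, params) if is_ir else None
        rescued = False
        if not st.coverage_ok and event_id in rescue_candidates:
            rescued = rescue_low_coverage(psi, design, event_id, True, params)
        called, direction, worst = _evaluate(
            st, is_ir, ir_ok, params, coverage_override=rescued
        )
        calls[event_id] = DiffSpliceCall(
            event_id=event_id,
            species=params.species,
            direction=direction,
            dpsi_avg=st.dpsi_avg,
            dpsi_pairwise_min=worst,
            coverage_ok=st.coverage_ok,
            ir_balance_ok=ir_ok,
            called=called,
            rescued=rescued and called,
        )
    return calls


def rescue_low_coverage(
    psi: PsiTable,
    design: SampleDesign,
    event_id: str,
    homolog_called_elsewhere: bool,
    params: SpeciesParams,
) -> bool:
    """Low-coverage rescue eligibility for a homolog-supported event.

    True iff exactly one compared sample falls below the tier floor and
    that sample still has at least two supporting reads.
    """
    if not homolog_called_elsewhere:
        return False
    st = compute_event_stats(psi, design, event_id, min_tier=params.min_tier)
    if st.coverage_ok or len(st.low_coverage_samples) != 1:
        return False
    recs = psi.event_records(event_id)
    r = recs.loc[st.low_coverage_samples[0]]
    return bool(r["inc"] + r["exc"] >= 2)


# ---------------------------------------------------------------------------
# Multi-source (human-style) grouping combination
# ---------------------------------------------------------------------------


@dataclass
class Comparison:
    """One control-vs-perturbed contrast inside a grouping.

    ``merge_reads`` pools the listed samples per side into a single
    pseudo-sample by summing inclusion/exclusion reads and recomputing
    PSI and tier from the pooled totals.
    """

    name: str
    controls: list[str]
    perturbed: list[str]
    sign: str = "loss"  # loss | gain
    merge_reads: bool = False


@dataclass
class Grouping:
    """A set of comparisons that must all pass for the grouping to call.

    When the grouping pairs loss- with gain-of-function comparisons the
    raw dPSI values must point in opposite directions (equivalently: the
    same direction after orienting every comparison to loss-of-function).
    """

    name: str
    comparisons: list[Comparison]


def _merged_record(recs: pd.DataFrame, samples: Sequence[str], params: SpeciesParams) -> pd.Series:
    inc = int(recs.loc[list(samples), "inc"].sum())
    exc = int(recs.loc[list(samples), "exc"].sum())
    total = inc + exc
    psi = 100.0 * inc / total if total > 0 else np.nan
    return pd.Series(
        {
            "psi": psi,
            "tier": tier_from_reads(total, params.tier_bounds),
            "inc": inc,
            "exc": exc,
            "b5": np.nan,
            "b3": np.nan,
        }
    )


def _comparison_stats(
    recs: pd.DataFrame, comp: Comparison, params: SpeciesParams
) -> EventStats:
    if comp.merge_reads:
        rows = {
            "ctrl": _merged_record(recs, comp.controls, params),
            "pert": _merged_record(recs, comp.perturbed, params),
        }
        controls, perturbed = ["ctrl"], ["pert"]
        recs = pd.DataFrame(rows).T
    else:
        controls, perturbed = comp.controls, comp.perturbed
    low = []
    for s in controls + perturbed:
        r = recs.loc[s]
        if np.isnan(r["psi"]) or not tier_at_least(r["tier"], params.min_tier):
            low.append(s)
    c_vals = [recs.loc[s, "psi"] for s in controls]
    p_vals = [recs.loc[s, "psi"] for s in perturbed]

    def _mean(vals):
        finite = [v for v in vals if not np.isnan(v)]
        return float(np.mean(finite)) if finite else float("nan")

    return EventStats(
        dpsi_avg=_mean(c_vals) - _mean(p_vals),
        pairwise=[float(c - p) for c in c_vals for p in p_vals],
        coverage_ok=not low,
        low_coverage_samples=low,
    )


def combine_groupings(
    psi: PsiTable,
    groupings: Sequence[Grouping],
    params: SpeciesParams,
) -> dict[str, DiffSpliceCall]:
    """Union-of-groupings calling for a multi-source design.

    An event is in the combined set iff it passes in at least one
    grouping; the final direction is reported in loss-of-function
    orientation, provenance records the passing groupings.
    """
    for g in groupings:
        for comp in g.comparisons:
            signs = {comp.sign}
            if signs - {"loss", "gain"}:
                raise ValueError(f"comparison {comp.name}: unknown sign {comp.sign!r}")
    calls: dict[str, DiffSpliceCall] = {}
    for event_id in psi.event_ids:
        recs = psi.event_records(event_id)
        passing: list[str] = []
        best: tuple[float, float] | None = None  # (oriented dpsi_avg, worst pairwise)
        for g in groupings:
            oriented: list[float] = []
            all_pass = True
            g_best: tuple[float, float] | None = None
            for comp in g.comparisons:
                if any(s not in recs.index for s in comp.controls + comp.perturbed):
                    all_pass = False
                    break
                st = _comparison_stats(recs, comp, params)
                orient = 1.0 if comp.sign == "loss" else -1.0
                called, _, worst = _evaluate(st, False, None, params)
                if not called:
                    all_pass = False
                    break
                oriented.append(orient * st.dpsi_avg)
                if g_best is None or abs(orient * st.dpsi_avg) > abs(g_best[0]):
                    g_best = (orient * st.dpsi_avg, orient * worst)
            if not all_pass or not oriented:
                continue
            # loss/gain pairing: oriented values must agree in sign
            # (raw values in "opposite direction")
            if len({v >= 0 for v in oriented}) > 1:
                continue
            passing.append(g.name)
            if best is None or abs(g_best[0]) > abs(best[0]):
                best = g_best
        if passing and best is not None:
            calls[event_id] = DiffSpliceCall(
                event_id=event_id,
                species=params.species,
                direction="enhanced" if best[0] >= 0 else "silenced",
                dpsi_avg=best[0],
                dpsi_pairwise_min=best[1],
                coverage_ok=True,
                ir_balance_ok=None,
                called=True,
                provenance=sorted(passing),
            )
    return calls


def calls_to_frame(calls: Mapping[str, DiffSpliceCall]) -> pd.DataFrame:
    rows = []
    for c in calls.values():
        rows.append(
            {
                "event_id": c.event_id,
                "species": c.species,
                "called": c.called,
                "direction": c.direction if c.called else "",
                "dpsi_avg": c.dpsi_avg,
                "dpsi_pairwise_min": c.dpsi_pairwise_min,
                "coverage_ok": c.coverage_ok,
                "ir_balance_ok": "" if c.ir_balance_ok is None else c.ir_balance_ok,
                "rescued": c.rescued,
                "provenance": ",".join(c.provenance),
            }
        )
    return pd.DataFrame(rows)
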