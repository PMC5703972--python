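"""Motif scanning, RNA regulatory maps, direct/indirect target
classification and conservation profiles.

The regulatory map uses a standardized exon-centric region schema: 75 nt
from both ends of the alternative exon, 250 nt from the 5' and 3' ends of
both flanking introns, 75 nt from the 5' end of the upstream exon and
75 nt from the 3' end of the downstream exon; features shorter than the
requested span are neglected (dropped, never padded).  A 51-nt window is
slid along each segment and the fraction of window positions covered by
any motif of the set is averaged across events per position.

Direct/indirect classification follows a positional code with two
scenarios.  "Restricted": silenced exons may carry motifs in the
alternative exon, the first 6 nt of the downstream intron (the 5' splice
site span) and/or the last 250 nt of the upstream intron; enhanced exons
in the first 250 nt of the downstream intron excluding that same 6-nt 5'
splice-site span.  "Expanded" additionally allows, for silenced exons,
the first 250 nt of the upstream intron, and for enhanced exons the last
25 nt of the upstream exon together with the upstream intron (excluding
the 50 nt next to the 3' splice site) or the last 250 nt of the
downstream intron.  An exon is "direct" when the motif count summed over
the allowed regions reaches the threshold, "indirect" when it is not
direct and has no motifs at all in the direction's giveaway regions, and
"discarded" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .model import AsEvent, GeneModel, MotifSet, ScoreTrack

SPLICE_SITE_5P_NT = 6  # downstream-intron span overlapping the 5' splice site
INTRON_FLANK_NT = 250
EXON_END_NT = 75
EXON_JUNCTION_NT = 25
ACCEPTOR_EXCLUSION_NT = 50  # 3' splice-site exclusion in the expanded scenario


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_motifs(seq: str, motifs: MotifSet) -> list[int]:
    """All (overlapping) start positions of any motif in the sequence."""
    s = _norm(seq)
    k = motifs.k
    mset = motifs.as_set()
    return [i for i in range(len(s) - k + 1) if s[i : i + k] in mset]


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass
class EventRegions:
    """Sequences around one event, all in transcript orientation."""

    event_id: str
    direction: str | None  # enhanced | silenced | None (background)
    up_exon: str
    up_intron: str
    alt_exon: str
    dn_intron: str
    dn_exon: str


def extract_regions(event: AsEvent, model: GeneModel, genome: Mapping[str, str]) -> EventRegions:
    """Pull the upstream-exon / intron / alt-exon / intron / downstream-exon
    sequences for an event, reverse-complemented into transcript
    orientation for minus-strand genes."""
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom} not in genome")
    chrom_seq = genome[model.chrom]
    if event.upstream_exon is None or event.downstream_exon is None:
        raise ValueError(f"event {event.event_id}: flanking exons required")

    def fetch(iv: tuple[int, int]) -> str:
        s = chrom_seq[iv[0] : iv[1]]
        return _revcomp(s) if model.strand == "-" else s.upper()

    alt = event.alt_interval
    up, dn = event.upstream_exon, event.downstream_exon
    if model.strand == "+":
        up_intron_iv = (up[1], alt[0])
        dn_intron_iv = (alt[1], dn[0])
    else:
        up_intron_iv = (alt[1], up[0])
        dn_intron_iv = (dn[1], alt[0])
    if up_intron_iv[0] > up_intron_iv[1] or dn_intron_iv[0] > dn_intron_iv[1]:
        raise ValueError(f"event {event.event_id}: flanking exons not consistent with strand")
    return EventRegions(
        event_id=event.event_id,
        direction=None,
        up_exon=fetch(up),
        up_intron=fetch(up_intron_iv),
        alt_exon=fetch(alt),
        dn_intron=fetch(dn_intron_iv),
        dn_exon=fetch(dn),
    )


#: Schema segment order for regulatory maps.
SCHEMA_SEGMENTS = (
    "up_exon",
    "up_intron_5p",
    "up_intron_3p",
    "alt_exon_5p",
    "alt_exon_3p",
    "dn_intron_5p",
    "dn_intron_3p",
    "dn_exon",
)


def region_schema_segments(
    regions: EventRegions,
    junction_proximal_flanks: bool = False,
) -> dict[str, str]:
    """Slice an event's sequences into the fixed-length schema segments.

    Features shorter than the requested span are neglected.  By default
    the flanking-exon segments are the 5' end of the upstream exon and
    the 3' end of the downstream exon (the verbatim schema);
    ``junction_proximal_flanks`` switches them to the junction-proximal
    ends instead.
    """
    out: dict[str, str] = {}
    if len(regions.up_exon) >= EXON_END_NT:
        out["up_exon"] = (
            regions.up_exon[-EXON_END_NT:] if junction_proximal_flanks else regions.up_exon[:EXON_END_NT]
        )
    if len(regions.up_intron) >= INTRON_FLANK_NT:
        out["up_intron_5p"] = regions.up_intron[:INTRON_FLANK_NT]
        out["up_intron_3p"] = regions.up_intron[-INTRON_FLANK_NT:]
    if len(regions.alt_exon) >= EXON_END_NT:
        out["alt_exon_5p"] = regions.alt_exon[:EXON_END_NT]
        out["alt_exon_3p"] = regions.alt_exon[-EXON_END_NT:]
    if len(regions.dn_intron) >= INTRON_FLANK_NT:
        out["dn_intron_5p"] = regions.dn_intron[:INTRON_FLANK_NT]
        out["dn_intron_3p"] = regions.dn_intron[-INTRON_FLANK_NT:]
    if len(regions.dn_exon) >= EXON_END_NT:
        out["dn_exon"] = (
            regions.dn_exon[:EXON_END_NT] if junction_proximal_flanks else regions.dn_exon[-EXON_END_NT:]
        )
    return out


# ---------------------------------------------------------------------------
# Coverage profiles (regulatory maps)
# ---------------------------------------------------------------------------


@dataclass
class RegionProfile:
    """Per-position values over schema segments plus contributor counts."""

    segments: dict[str, np.ndarray] = field(default_factory=dict)
    n_events: dict[str, int] = field(default_factory=dict)


def covered_positions(length: int, hit_starts: Iterable[int], k: int) -> np.ndarray:
    cov = np.zeros(length, dtype=bool)
    for h in hit_starts:
        cov[h : h + k] = True
    return cov


def windowed_fraction(cov: np.ndarray, window: int = 51) -> np.ndarray:
    """Fraction of covered positions in a window centred at each position,
    truncated at the segment ends (the actual span is the denominator)."""
    n = len(cov)
    half = window // 2
    csum = np.concatenate([[0], np.cumsum(cov.astype(int))])
    out = np.empty(n)
    for p in range(n):
        lo, hi = max(0, p - half), min(n, p + half + 1)
        out[p] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def coverage_profile(
    segment_sets: Sequence[Mapping[str, str]],
    motifs: MotifSet,
    window: int = 51,
) -> RegionProfile:
    """Mean motif-coverage profile across events for one event class.

    ``segment_sets`` holds, per event, the schema segments returned by
    :func:`region_schema_segments`.  Profiles are averaged per segment
    over the events in which the segment exists.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for segs in segment_sets:
        for name, seq in segs.items():
            hits = scan_motifs(seq, motifs)
            frac = windowed_fraction(covered_positions(len(seq), hits, motifs.k), window)
            if name not in sums:
                sums[name] = np.zeros(len(seq))
                counts[name] = 0
            sums[name] += frac
            counts[name] += 1
    return RegionProfile(
        segments={n: sums[n] / counts[n] for n in sums},
        n_events=dict(counts),
    )


# ---------------------------------------------------------------------------
# Direct / indirect classification
# ---------------------------------------------------------------------------


@dataclass
class EventHits:
    """Motif hit start positions in the scan universe of one event.

    Intron hits are intron-relative (0 = first intronic base after the
    donor for the respective intron, transcript orientation); exon-end
    hits are counted only.  The scan universe is the alternative exon,
    the first and last 250 nt of both introns, the last 25 nt of the
    upstream exon and the first 25 nt of the downstream exon.
    """

    alt_exon: set[int]
    up_intron: set[int]
    dn_intron: set[int]
    up_intron_len: int
    dn_intron_len: int
    n_up_exon_junction: int
    n_dn_exon_junction: int


def scan_event(regions: EventRegions, motifs: MotifSet) -> EventHits:
    k = motifs.k

    def intron_hits(seq: str) -> set[int]:
        L = len(seq)
        if L <= 2 * INTRON_FLANK_NT:
            return set(scan_motifs(seq, motifs))
        first = set(scan_motifs(seq[:INTRON_FLANK_NT], motifs))
        last = {L - INTRON_FLANK_NT + h for h in scan_motifs(seq[-INTRON_FLANK_NT:], motifs)}
        return first | last

    return EventHits(
        alt_exon=set(scan_motifs(regions.alt_exon, motifs)),
        up_intron=intron_hits(regions.up_intron),
        dn_intron=intron_hits(regions.dn_intron),
        up_intron_len=len(regions.up_intron),
        dn_intron_len=len(regions.dn_intron),
        n_up_exon_junction=len(scan_motifs(regions.up_exon[-EXON_JUNCTION_NT:], motifs)),
        n_dn_exon_junction=len(scan_motifs(regions.dn_exon[:EXON_JUNCTION_NT], motifs)),
    )


SCENARIOS = ("restricted", "expanded")


def classify_direct_indirect(
    direction: str,
    hits: EventHits,
    scenario: str = "restricted",
    min_motifs: int = 1,
) -> str:
    """Classify a regulated exon as direct / indirect / discarded."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if direction not in ("enhanced", "silenced"):
        raise ValueError(f"direction must be enhanced/silenced, got {direction!r}")
    L_up, L_dn = hits.up_intron_len, hits.dn_intron_len

    if direction == "silenced":
        allowed = len(hits.alt_exon)
        allowed += sum(1 for h in hits.dn_intron if h < SPLICE_SITE_5P_NT)
        if scenario == "restricted":
            allowed += sum(1 for h in hits.up_intron if h >= L_up - INTRON_FLANK_NT)
        else:  # expanded: first 250 as well -> whole scanned upstream intron
            allowed += len(hits.up_intron)
        if allowed >= min_motifs:
            return "direct"
        if not hits.up_intron and not hits.alt_exon:
            return "indirect"
        return "discarded"

    # enhanced
    allowed = sum(1 for h in hits.dn_intron if SPLICE_SITE_5P_NT <= h < INTRON_FLANK_NT)
    if scenario == "expanded":
        allowed += hits.n_up_exon_junction
        allowed += sum(1 for h in hits.up_intron if h < L_up - ACCEPTOR_EXCLUSION_NT)
        allowed += sum(1 for h in hits.dn_intron if h >= max(L_dn - INTRON_FLANK_NT, INTRON_FLANK_NT))
    if allowed >= min_motifs:
        return "direct"
    giveaway_up = any(h >= L_up - INTRON_FLANK_NT for h in hits.up_intron)
    if not hits.dn_intron and not giveaway_up:
        return "indirect"
    return "discarded"


def shared_regulation_enrichment(
    direct_shared: int,
    direct_not: int,
    indirect_shared: int,
    indirect_not: int,
) -> float:
    """One-sided Fisher exact test that direct targets are enriched for
    shared regulation relative to indirect targets."""
    table = [[direct_shared, direct_not], [indirect_shared, indirect_not]]
    if sum(sum(r) for r in table) == 0:
        return 1.0
    return float(_stats.fisher_exact(table, alternative="greater")[1])


# ---------------------------------------------------------------------------
# Conservation profiles
# ---------------------------------------------------------------------------


def smooth_trailing(values: np.ndarray, window: int = 10, centered: bool = False) -> np.ndarray:
    """Mean over ``window`` consecutive positions starting at each position
    (trailing convention; truncated at the array end).  ``centered``
    switches to a centred window."""
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        if centered:
            lo, hi = max(0, i - window // 2), min(n, i + (window + 1) // 2)
        else:
            lo, hi = i, min(n, i + window)
        out[i] = np.nanmean(values[lo:hi])
    return out


def conservation_profile(
    exons: Sequence[tuple[str, int, int]],
    track: ScoreTrack,
    flank: int = 150,
    smooth: int = 10,
    centered: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Average smoothed score profile over exons with flanking regions.

    Each exon contributes a profile of length ``len(exon) + 2*flank``
    anchored at the start of the upstream flank; exons extending beyond
    the track are skipped.  Returns ``(mean_profile, n_contributors)``;
    positions with no contributors are trimmed from the end.
    """
    profiles = []
    for chrom, start, end in exons:
        if chrom not in track:
            continue
        try:
            vals = track.get(chrom, start - flank, end + flank)
        except IndexError:
            continue
        profiles.append(smooth_trailing(np.asarray(vals, dtype=float), smooth, centered))
    if not profiles:
        return np.array([]), np.array([], dtype=int)
    max_len = max(len(p) for p in profiles)
    acc = np.zeros(max_len)
    n = np.zeros(max_len, dtype=int)
    for p in profiles:
        mask = ~np.isnan(p)
        acc[: len(p)][mask] += p[mask]
        n[: len(p)][mask] += 1
    mean = np.full(max_len, np.nan)
    nz = n > 0
    mean[nz] = acc[nz] / n[nz]
    return mean, n
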