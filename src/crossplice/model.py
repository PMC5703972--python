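"""Core domain types for the comparative splicing pipeline.

Conventions used throughout the package:

* All genomic intervals are 0-based half-open ``(start, end)`` tuples.
* Strand handling happens at parse time: exon lists are stored in
  transcript orientation (5'->3'), so downstream modules reason in
  "upstream/downstream" terms without per-module strand branching.
* PSI values are percentages in ``[0, 100]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Read-coverage tiers
# ---------------------------------------------------------------------------

#: Ordinal read-support labels, worst to best.
TIER_ORDER: tuple[str, ...] = ("N", "VLOW", "LOW", "OK", "SOK")

_TIER_RANK = {t: i for i, t in enumerate(TIER_ORDER)}

#: Default read-count boundaries for tier assignment when (re)computing
#: tiers from supporting reads.  The upstream quantifier does not publish
#: its boundaries, so this explicit mapping keeps behaviour reproducible;
#: it is configurable wherever tiers are assigned.
DEFAULT_TIER_BOUNDS: tuple[tuple[int, str], ...] = (
    (5, "N"),      # total < 5
    (15, "VLOW"),  # 5 <= total < 15
    (25, "LOW"),   # 15 <= total < 25
    (100, "OK"),   # 25 <= total < 100
)


def tier_rank(tier: str) -> int:
    """Ordinal rank of a coverage tier (N=0 < VLOW < LOW < OK < SOK=4)."""
    try:
        return _TIER_RANK[tier]
    except KeyError:
        raise ValueError(f"unknown coverage tier {tier!r}") from None


def tier_at_least(tier: str, floor: str) -> bool:
    return tier_rank(tier) >= tier_rank(floor)


def tier_from_reads(total: int, bounds: Sequence[tuple[int, str]] = DEFAULT_TIER_BOUNDS) -> str:
    """Assign a coverage tier from the total number of supporting reads."""
    if total < 0:
        raise ValueError("read count must be non-negative")
    for cutoff, tier in bounds:
        if total < cutoff:
            return tier
    return TIER_ORDER[-1]


# ---------------------------------------------------------------------------
# Gene models and protein isoforms
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One transcript: exons in transcript orientation plus an optional CDS.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation (descending genomic coordinate on '-' strand).
    ``cds_start``/``cds_end`` are genomic bounds of the coding region.
    """

    transcript_id: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Coding portion of each exon, transcript order, empty if no CDS."""
        if self.cds_start is None or self.cds_end is None:
            return []
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out

    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals())


@dataclass
class GeneModel:
    gene_id: str
    species: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    mappable_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def validate(self) -> None:
        """Check exon ordering/overlap and CDS containment invariants."""
        for tx in self.transcripts.values():
            if not tx.exons:
                raise ValueError(f"transcript {tx.transcript_id} has zero exons")
            ordered = tx.exons if self.strand == "+" else tx.exons[::-1]
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if not (s1 < e1 <= s2 < e2):
                    raise ValueError(
                        f"transcript {tx.transcript_id}: exons overlap or are unordered"
                    )
            if tx.cds_start is not None:
                covered = sum(
                    max(0, min(e, tx.cds_end) - max(s, tx.cds_start)) for s, e in tx.exons
                )
                in_exon_start = any(s <= tx.cds_start < e for s, e in tx.exons)
                in_exon_end = any(s < tx.cds_end <= e for s, e in tx.exons)
                if not (in_exon_start and in_exon_end) or covered == 0:
                    raise ValueError(
                        f"transcript {tx.transcript_id}: CDS not contained in exons"
                    )
        total_exonic = max((t.exonic_length for t in self.transcripts.values()), default=0)
        if self.mappable_length and self.mappable_length > sum(
            t.exonic_length for t in self.transcripts.values()
        ):
            # mappable length can never exceed the union of exonic sequence;
            # the per-transcript sum is a cheap upper bound on the union
            if self.mappable_length > total_exonic and len(self.transcripts) == 1:
                raise ValueError(
                    f"gene {self.gene_id}: mappable_length exceeds exonic length"
                )


@dataclass
class ProteinIsoform:
    """A protein with intron positions projected onto residue coordinates.

    ``junction_map`` holds one ``(residue_index, phase)`` per intron of the
    coding region: ``residue_index = floor(coding_nt_5prime / 3)`` (0-based)
    and ``phase = coding_nt_5prime mod 3``.
    """

    gene_id: str
    isoform_id: str
    sequence: str
    junction_map: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev = -1
        for idx, phase in self.junction_map:
            if idx <= prev:
                raise ValueError("junction residue indices must be strictly increasing")
            if phase not in (0, 1, 2):
                raise ValueError(f"invalid intron phase {phase}")
            prev = idx


@dataclass
class AsEvent:
    """An alternative-splicing event anchored on a gene model.

    Intervals are genomic 0-based half-open; ``upstream``/``downstream``
    refer to transcript orientation.
    """

    event_id: str
    gene_id: str
    type: str  # AltEx | IR | Alt5 | Alt3
    alt_interval: tuple[int, int]
    upstream_exon: tuple[int, int] | None = None
    downstream_exon: tuple[int, int] | None = None

    TYPES = ("AltEx", "IR", "Alt5", "Alt3")

    def __post_init__(self) -> None:
        if self.type not in self.TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


# ---------------------------------------------------------------------------
# PSI tables
# ---------------------------------------------------------------------------

PSI_CONSISTENCY_TOL = 0.05  # PSI units; absorbs printed rounding


class PsiTable:
    """Events x samples table of PSI values with tiers and read support.

    Internally a long-format :class:`pandas.DataFrame` with one row per
    ``(event_id, sample_id)`` and columns ``psi``, ``tier``, ``inc``,
    ``exc`` plus ``b5``/``b3`` boundary reads for intron-retention events
    (NaN elsewhere).  ``events`` carries per-event metadata (gene, type,
    coordinate string).
    """

    DATA_COLUMNS = ["event_id", "sample_id", "psi", "tier", "inc", "exc", "b5", "b3"]

    def __init__(self, events: pd.DataFrame, data: pd.DataFrame, samples: Sequence[str]):
        self.events = events
        self.data = data
        self.samples = list(samples)
        self._idx = data.set_index(["event_id", "sample_id"])

    @classmethod
    def from_records(cls, events: pd.DataFrame, records: Iterable[dict]) -> "PsiTable":
        data = pd.DataFrame(list(records), columns=cls.DATA_COLUMNS)
        samples = list(dict.fromkeys(data["sample_id"]))
        return cls(events, data, samples)

    @property
    def event_ids(self) -> list[str]:
        return list(self.events.index)

    def has_event(self, event_id: str) -> bool:
        return event_id in self.events.index

    def record(self, event_id: str, sample_id: str) -> pd.Series:
        try:
            return self._idx.loc[(event_id, sample_id)]
        except KeyError:
            raise KeyError(f"no PSI record for event {event_id!r}, sample {sample_id!r}")

    def event_records(self, event_id: str) -> pd.DataFrame:
        if not self.has_event(event_id):
            raise KeyError(f"event {event_id!r} absent from PSI table")
        return self.data[self.data["event_id"] == event_id].set_index("sample_id")

    def psi_matrix(self) -> pd.DataFrame:
        return self.data.pivot(index="event_id", columns="sample_id", values="psi")

    def validate_row(self, psi: float, inc: int, exc: int) -> bool:
        """PSI/read-count consistency: psi == 100*inc/(inc+exc) within tolerance."""
        total = inc + exc
        if total <= 0:
            return True
        return abs(psi - 100.0 * inc / total) <= PSI_CONSISTENCY_TOL

    def check_consistency(self) -> pd.DataFrame:
        """Return the rows violating the PSI/read-count invariant."""
        bad = [
            i
            for i, r in self.data.iterrows()
            if not self.validate_row(r["psi"], int(r["inc"]), int(r["exc"]))
        ]
        return self.data.loc[bad]


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------


@dataclass
class SampleInfo:
    condition: str  # control | perturbed
    perturbation_sign: str = "loss"  # loss | gain
    replicate_id: str = "1"
    grouping_id: str = "main"

    def __post_init__(self) -> None:
        if self.condition not in ("control", "perturbed"):
            raise ValueError(f"condition must be control/perturbed, got {self.condition!r}")
        if self.perturbation_sign not in ("loss", "gain"):
            raise ValueError(f"perturbation_sign must be loss/gain, got {self.perturbation_sign!r}")


class SampleDesign:
    """Maps sample ids to condition / perturbation sign / replicate / grouping.

    A *grouping* is a label for one comparison set (used by the
    multi-source combination logic); each grouping must contain at least
    one control and one perturbed sample.
    """

    def __init__(self, samples: Mapping[str, SampleInfo]):
        self.samples = dict(samples)
        for gid in self.grouping_ids():
            if not self.controls(gid) or not self.perturbed(gid):
                raise ValueError(
                    f"grouping {gid!r} lacks a control or a perturbed sample"
                )

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> SampleInfo:
        return self.samples[sample_id]

    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def grouping_ids(self) -> list[str]:
        return list(dict.fromkeys(info.grouping_id for info in self.samples.values()))

    def controls(self, grouping_id: str | None = None) -> list[str]:
        return [
            s
            for s, info in self.samples.items()
            if info.condition == "control"
            and (grouping_id is None or info.grouping_id == grouping_id)
        ]

    def perturbed(self, grouping_id: str | None = None) -> list[str]:
        return [
            s
            for s, info in self.samples.items()
            if info.condition == "perturbed"
            and (grouping_id is None or info.grouping_id == grouping_id)
        ]

    def restrict(self, grouping_id: str) -> "SampleDesign":
        return SampleDesign(
            {s: i for s, i in self.samples.items() if i.grouping_id == grouping_id}
        )

    def swap_conditions(self) -> "SampleDesign":
        """Relabel control<->perturbed (used by antisymmetry checks)."""
        flipped = {}
        for s, i in self.samples.items():
            flipped[s] = SampleInfo(
                condition="perturbed" if i.condition == "control" else "control",
                perturbation_sign=i.perturbation_sign,
                replicate_id=i.replicate_id,
                grouping_id=i.grouping_id,
            )
        return SampleDesign(flipped)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        samples = {}
        for _, row in df.iterrows():
            samples[str(row["sample_id"])] = SampleInfo(
                condition=row["condition"],
                perturbation_sign=row.get("perturbation_sign", "loss"),
                replicate_id=str(row.get("replicate_id", "1")),
                grouping_id=str(row.get("grouping_id", "main")),
            )
        return cls(samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s,
                    "condition": i.condition,
                    "perturbation_sign": i.perturbation_sign,
                    "replicate_id": i.replicate_id,
                    "grouping_id": i.grouping_id,
                }
                for s, i in self.samples.items()
            ]
        )


def derive_protein_junction_map(
    model: GeneModel,
    transcript_id: str,
    protein_sequence: str | None = None,
    genome: Mapping[str, str] | None = None,
) -> ProteinIsoform:
    """Project a transcript's intron positions onto protein coordinates.

    Each junction between consecutive coding exons maps to residue
    ``floor(cumulative_coding_nt / 3)`` with phase
    ``cumulative_coding_nt mod 3``.  The protein sequence may be supplied
    directly or translated from ``genome`` (a chrom -> sequence mapping);
    the CDS length must be an exact multiple of 3.
    """
    tx = model.transcripts[transcript_id]
    coding = tx.coding_intervals()
    if not coding:
        raise ValueError(f"transcript {transcript_id} has no annotated CDS")
    lengths = [e - s for s, e in coding]
    total = sum(lengths)
    if total % 3 != 0:
        raise ValueError(
            f"transcript {transcript_id}: CDS length {total} is not a multiple of 3"
        )
    junction_map = []
    cum = 0
    for ln in lengths[:-1]:
        cum += ln
        junction_map.append((cum // 3, cum % 3))
    if protein_sequence is None:
        if genome is None:
            raise ValueError("need protein_sequence or genome to build a ProteinIsoform")
        from Bio.Seq import Seq

        chunks = []
        for s, e in coding:
            seq = genome[model.chrom][s:e]
            if model.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            chunks.append(seq)
        protein_sequence = str(Seq("".join(chunks)).translate()).rstrip("*")
    n_res = total // 3
    if len(protein_sequence) not in (n_res, n_res - 1):  # -1: CDS includes stop codon
        raise ValueError(
            f"protein length {len(protein_sequence)} inconsistent with CDS length {total}"
        )
    return ProteinIsoform(
        gene_id=model.gene_id,
        isoform_id=transcript_id,
        sequence=protein_sequence,
        junction_map=junction_map,
    )


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------


class ScoreTrack:
    """Per-base score arrays keyed by chromosome; NaN marks missing positions."""

    def __init__(self, arrays: Mapping[str, np.ndarray] | None = None):
        self.arrays: dict[str, np.ndarray] = {
            c: np.asarray(a, dtype=float) for c, a in (arrays or {}).items()
        }

    def add(self, chrom: str, length: int) -> np.ndarray:
        arr = np.full(length, np.nan)
        self.arrays[chrom] = arr
        return arr

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); raises if out of bounds."""
        arr = self.arrays[chrom]
        if start < 0 or end > len(arr):
            raise IndexError(
                f"interval [{start},{end}) outside track bounds for {chrom} (len {len(arr)})"
            )
        return arr[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.arrays


# ---------------------------------------------------------------------------
# Motif sets
# ---------------------------------------------------------------------------


@dataclass
class MotifSet:
    """A set of fixed-length (hexamer) motifs over the DNA/RNA alphabet.

    Motifs are normalised to DNA (U->T) and upper case on construction.
    """

    motifs: list[str]

    def __post_init__(self) -> None:
        norm = [m.upper().replace("U", "T") for m in self.motifs]
        if not norm:
            raise ValueError("motif set must be non-empty")
        k = len(norm[0])
        if any(len(m) != k for m in norm):
            raise ValueError("all motifs must share the same length")
        if any(set(m) - set("ACGT") for m in norm):
            raise ValueError("motifs must be over the ACGU/T alphabet")
        self.motifs = norm

    @property
    def k(self) -> int:
        return len(self.motifs[0])

    def as_set(self) -> frozenset[str]:
        return frozenset(self.motifs)
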