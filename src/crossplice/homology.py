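"""Cross-species gene orthology and homologous-exon clustering.

Gene level: pairwise orthology evidence from three source families
(OMA-like and Multiparanoid-like cluster co-membership, BlastP-like
reciprocal-top-3) is accepted when at least 2 of the 3 sources support
a pair; clusters are the connected components of the accepted-pair
graph (guilt-by-association).

Exon level: protein isoforms are globally aligned in a pairwise manner
(BLOSUM62, affine gaps) and the intron positions of each species are
intercalated into the alignment as (column, phase) markers.  A pair of
exons is homologous "automatically" when the alternative exon and at
least one flanking constitutive exon align with >20% similarity and
both flanking intron positions are conserved with identical phase
within 3 alignment columns; borderline cases (exactly one clause
failing) are flagged for manual review rather than silently promoted.
Exon clusters are again connected components over accepted pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .model import ProteinIsoform

# ---------------------------------------------------------------------------
# Gene-level orthology
# ---------------------------------------------------------------------------

SOURCES = ("oma", "multiparanoid", "blastp")


@dataclass(frozen=True)
class OrthologyEvidence:
    gene_a: str
    gene_b: str
    source: str

    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # unordered semantics


def blast_reciprocal_rule(
    hits: Mapping[str, Sequence[tuple[str, float]]],
    top_n: int = 3,
) -> set[OrthologyEvidence]:
    """Reciprocal top-N BlastP evidence.

    ``hits`` maps each query gene to its ranked hit list in the other
    species as (gene, score) pairs, best first.  Hits tied with the
    N-th best score all count as within the top N.  Evidence is emitted
    iff b is in a's top N and a is in b's top N; queries without a
    reciprocal list are skipped.
    """

    def top_set(gene: str) -> set[str]:
        ranked = sorted(hits.get(gene, []), key=lambda h: -h[1])
        if not ranked:
            return set()
        cutoff = ranked[min(top_n, len(ranked)) - 1][1]
        return {g for g, s in ranked if s >= cutoff}

    out: set[OrthologyEvidence] = set()
    for a, ranked in hits.items():
        for b in top_set(a):
            if b not in hits:
                continue  # no reciprocal list for b
            if a in top_set(b):
                ga, gb = sorted((a, b))
                out.add(OrthologyEvidence(ga, gb, "blastp"))
    return out


def build_gene_clusters(
    evidence: Iterable[OrthologyEvidence],
    genes: Iterable[str] = (),
    min_sources: int = 2,
) -> list[set[str]]:
    """Connected components over pairs supported by >= min_sources sources."""
    support: dict[tuple[str, str], set[str]] = {}
    g = nx.Graph()
    g.add_nodes_from(genes)
    for ev in evidence:
        support.setdefault(ev.pair(), set()).add(ev.source)
    for (a, b), sources in support.items():
        g.add_nodes_from((a, b))
        if len(sources) >= min_sources:
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# Structure-aware pairwise alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignScoring:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    similarity_mode: str = "similarity"  # similarity (positive-scoring) | identity


def _aligner(scoring: AlignScoring, mode: str = "global"):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    # non-standard residues score as the wildcard
    return "".join(c if c in alphabet else "X" for c in seq.upper())


@dataclass
class AlignedStructure:
    """A pairwise protein alignment with intercalated intron markers.

    ``markers_*`` hold one (alignment_column, phase) per intron; the
    column is that of the residue immediately downstream of the
    junction.  ``res2col_*`` map residue index -> alignment column.
    """

    iso_a: ProteinIsoform
    iso_b: ProteinIsoform
    gapped_a: str
    gapped_b: str
    markers_a: list[tuple[int, int]]
    markers_b: list[tuple[int, int]]
    res2col_a: list[int]
    res2col_b: list[int]
    scoring: AlignScoring = field(default_factory=AlignScoring)

    def degapped(self) -> tuple[str, str]:
        return self.gapped_a.replace("-", ""), self.gapped_b.replace("-", "")


def _gapped_from_coordinates(seq_a: str, seq_b: str, coords: np.ndarray) -> tuple[str, str]:
    rows = ["", ""]
    seqs = (seq_a, seq_b)
    for k in range(coords.shape[1] - 1):
        span = coords[:, k + 1] - coords[:, k]
        width = int(span.max())
        for r in (0, 1):
            if span[r] == 0:
                rows[r] += "-" * width
            else:
                rows[r] += seqs[r][int(coords[r, k]) : int(coords[r, k + 1])]
    return rows[0], rows[1]


def align_with_structure(
    iso_a: ProteinIsoform,
    iso_b: ProteinIsoform,
    scoring: AlignScoring | None = None,
) -> AlignedStructure:
    """Global pairwise alignment of two isoforms with projected introns."""
    scoring = scoring or AlignScoring()
    if not iso_a.sequence or not iso_b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(scoring, "global")
    alphabet = str(aligner.substitution_matrix.alphabet)
    sa, sb = _sanitize(iso_a.sequence, alphabet), _sanitize(iso_b.sequence, alphabet)
    aln = aligner.align(sa, sb)[0]
    ga, gb = _gapped_from_coordinates(sa, sb, np.asarray(aln.coordinates))

    def res2col(gapped: str) -> list[int]:
        return [i for i, c in enumerate(gapped) if c != "-"]

    r2c_a, r2c_b = res2col(ga), res2col(gb)

    def project(junctions: list[tuple[int, int]], r2c: list[int]) -> list[tuple[int, int]]:
        out = []
        for r, phase in junctions:
            col = r2c[r] if r < len(r2c) else len(ga)
            out.append((col, phase))
        return out

    return AlignedStructure(
        iso_a=iso_a,
        iso_b=iso_b,
        gapped_a=ga,
        gapped_b=gb,
        markers_a=project(iso_a.junction_map, r2c_a),
        markers_b=project(iso_b.junction_map, r2c_b),
        res2col_a=r2c_a,
        res2col_b=r2c_b,
        scoring=scoring,
    )


def exon_residue_spans(iso: ProteinIsoform) -> list[tuple[int, int]]:
    """Residue span of each coding exon, boundary residues assigned to the
    downstream exon (junction residue index convention)."""
    bounds = [0] + [r for r, _ in iso.junction_map] + [len(iso.sequence)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# Exon-homology rules
# ---------------------------------------------------------------------------


@dataclass
class ExonVerdict:
    status: str  # automatic | manual_flag | none
    similarity: float  # percent, alt-exon pairwise similarity
    flank_exon_significant: bool
    introns_conserved: tuple[bool, bool]  # upstream, downstream


def _pair_similarity(
    structure: AlignedStructure,
    span_a: tuple[int, int],
    span_b: tuple[int, int],
) -> float:
    """Percent of aligned (both non-gap, both in-span) columns that are
    identical or positively scoring; gap columns are excluded from the
    denominator."""
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load(structure.scoring.matrix)
    cols_a = set(structure.res2col_a[span_a[0] : span_a[1]])
    cols_b = set(structure.res2col_b[span_b[0] : span_b[1]])
    shared = sorted(cols_a & cols_b)
    if not shared:
        return 0.0
    hits = 0
    for col in shared:
        ca, cb = structure.gapped_a[col], structure.gapped_b[col]
        if structure.scoring.similarity_mode == "identity":
            ok = ca == cb
        else:
            ok = ca == cb or matrix[ca, cb] > 0
        hits += ok
    return 100.0 * hits / len(shared)


def _local_similarity(pep_a: str, pep_b: str, scoring: AlignScoring) -> float:
    """Similarity of a local realignment of two exon peptides, normalised
    by the longer exon's length (used to break ties among multiple >20%
    candidates; a short fortuitous overlap must not outrank a full-length
    match)."""
    from Bio.Align import substitution_matrices

    if not pep_a or not pep_b:
        return 0.0
    aligner = _aligner(scoring, "local")
    alphabet = str(aligner.substitution_matrix.alphabet)
    sa, sb = _sanitize(pep_a, alphabet), _sanitize(pep_b, alphabet)
    alns = aligner.align(sa, sb)
    if len(alns) == 0:
        return 0.0
    aln = alns[0]
    matrix = substitution_matrices.load(scoring.matrix)
    ga, gb = _gapped_from_coordinates(sa, sb, np.asarray(aln.coordinates))
    aligned = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
    if not aligned:
        return 0.0
    if scoring.similarity_mode == "identity":
        hits = sum(x == y for x, y in aligned)
    else:
        hits = sum(x == y or matrix[x, y] > 0 for x, y in aligned)
    return 100.0 * hits / max(len(sa), len(sb))


def assess_exon_homology(
    structure: AlignedStructure,
    exon_index_a: int,
    candidate_indices_b: Sequence[int] | None = None,
    min_similarity: float = 20.0,
    max_marker_offset: int = 3,
) -> dict[int, ExonVerdict]:
    """Apply the exon-homology rules to one alt exon against candidates.

    For each candidate exon in species B the verdict is:

    * ``automatic`` — alt-exon similarity > 20%, at least one flanking
      constitutive exon also aligns significantly, and both flanking
      intron positions are conserved with identical phase within 3
      alignment columns;
    * ``manual_flag`` — exactly one of the sequence clause / structure
      clause fails (borderline, for operator review);
    * ``none`` — otherwise.

    When several candidates exceed the similarity cutoff, a local
    realignment of the exon peptides is performed and only the highest-
    similarity candidate keeps its verdict.
    """
    spans_a = exon_residue_spans(structure.iso_a)
    spans_b = exon_residue_spans(structure.iso_b)
    if candidate_indices_b is None:
        candidate_indices_b = range(len(spans_b))
    span_alt_a = spans_a[exon_index_a]
    if span_alt_a[0] >= span_alt_a[1]:
        return {j: ExonVerdict("none", 0.0, False, (False, False)) for j in candidate_indices_b}

    verdicts: dict[int, ExonVerdict] = {}
    for j in candidate_indices_b:
        span_b = spans_b[j]
        sim = _pair_similarity(structure, span_alt_a, span_b)

        # flanking constitutive exons: upstream vs upstream, downstream vs downstream
        flank_sig = False
        for da in (-1, +1):
            ia, jb = exon_index_a + da, j + da
            if 0 <= ia < len(spans_a) and 0 <= jb < len(spans_b):
                if _pair_similarity(structure, spans_a[ia], spans_b[jb]) > min_similarity:
                    flank_sig = True
        # flanking intron positions: identical phase within the column tolerance
        def intron_ok(side: int) -> bool:
            ka = exon_index_a - 1 if side < 0 else exon_index_a
            kb = j - 1 if side < 0 else j
            if not (0 <= ka < len(structure.markers_a) and 0 <= kb < len(structure.markers_b)):
                return False
            col_a, phase_a = structure.markers_a[ka]
            col_b, phase_b = structure.markers_b[kb]
            return phase_a == phase_b and abs(col_a - col_b) <= max_marker_offset

        up_ok, down_ok = intron_ok(-1), intron_ok(+1)
        seq_clause = sim > min_similarity and flank_sig
        struct_clause = up_ok and down_ok
        if seq_clause and struct_clause:
            status = "automatic"
        elif seq_clause and not struct_clause:
            status = "manual_flag"
        elif struct_clause and not (sim > min_similarity):
            status = "manual_flag"
        else:
            status = "none"
        verdicts[j] = ExonVerdict(status, sim, flank_sig, (up_ok, down_ok))

    # multiple significant candidates: local realignment picks the winner
    significant = [j for j, v in verdicts.items() if v.similarity > min_similarity]
    if len(significant) > 1:
        sa, sb = structure.degapped()
        pep_a = sa[span_alt_a[0] : span_alt_a[1]]
        best_j, best_sim = None, -1.0
        for j in significant:
            pep_b = sb[spans_b[j][0] : spans_b[j][1]]
            ls = _local_similarity(pep_a, pep_b, structure.scoring)
            if ls > best_sim:
                best_j, best_sim = j, ls
        for j in significant:
            if j != best_j:
                verdicts[j] = ExonVerdict(
                    "none",
                    verdicts[j].similarity,
                    verdicts[j].flank_exon_significant,
                    verdicts[j].introns_conserved,
                )
    return verdicts


# ---------------------------------------------------------------------------
# Exon clusters
# ---------------------------------------------------------------------------

ExonKey = tuple[str, str, str]  # (species, gene_id, exon_id)


@dataclass
class ExonCluster:
    cluster_id: str
    members: set[ExonKey]
    conflicts: list[tuple[ExonKey, ExonKey]] = field(default_factory=list)

    def species_set(self) -> set[str]:
        return {sp for sp, _, _ in self.members}


def build_exon_clusters(
    accepted_pairs: Iterable[tuple[ExonKey, ExonKey]],
    all_exons: Iterable[ExonKey] = (),
) -> list[ExonCluster]:
    """Guilt-by-association assembly of homologous exon clusters.

    Components are kept even when conflicting (two distinct exons of the
    same gene in one component); conflicts are flagged in the output.
    Exons in ``all_exons`` without any accepted pair become singletons.
    """
    g = nx.Graph()
    g.add_nodes_from(all_exons)
    g.add_edges_from(accepted_pairs)
    clusters = []
    for i, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        members = set(comp)
        by_gene: dict[tuple[str, str], list[ExonKey]] = {}
        for m in members:
            by_gene.setdefault((m[0], m[1]), []).append(m)
        conflicts = []
        for group in by_gene.values():
            if len(group) > 1:
                group = sorted(group)
                conflicts.extend((a, b) for a, b in zip(group, group[1:]))
        clusters.append(ExonCluster(cluster_id=f"EC{i + 1:05d}", members=members, conflicts=conflicts))
    return clusters
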