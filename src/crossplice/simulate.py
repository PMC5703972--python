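"""Synthetic multi-species gene families with known ground truth.

The generator emulates the data structures the comparative pipeline
consumes: gene families with conserved exon-intron architecture across
a labelled species tree (with per-branch exon gain/loss and per-site
sequence divergence), replicate PSI tables with planted factor-dependent
inclusion shifts sampled through binomial (optionally beta-binomial)
read noise, negative-binomial expression counts with planted fold
changes, genomic sequence with scenario-consistent planted motifs, and
smooth per-base score tracks.  Every generated entity is recorded in a
:class:`SimTruth` object so downstream stages can be scored against
ground truth.

Simplifications (documented in the methods note): protein evolution is
i.i.d. per-residue substitution with no indels inside exons; exon gains
and losses are frame-preserving and never touch the focal alternative
exon or its immediate neighbours; the focal exon is the only
alternative exon per family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from io import StringIO
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AsEvent,
    GeneModel,
    MotifSet,
    ProteinIsoform,
    PsiTable,
    SampleDesign,
    SampleInfo,
    ScoreTrack,
    Transcript,
    derive_protein_junction_map,
    tier_from_reads,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

# one representative codon per amino acid (deterministic back-translation)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass
class SimParams:
    """Knobs of the synthetic study; defaults are the study conditions
    assumed throughout the test suite."""

    n_families: int = 50
    n_exons_range: tuple[int, int] = (5, 7)
    exon_len_range: tuple[int, int] = (60, 180)       # nt, constitutive exons
    alt_exon_len_range: tuple[int, int] = (60, 150)   # nt, rounded to codons
    intron_len_range: tuple[int, int] = (300, 700)    # nt
    flank_len: int = 100                              # nt outside the gene
    p_sub: float = 0.05          # per-site substitution probability per branch
    p_gain: float = 0.0          # per-branch exon gain probability
    p_loss: float = 0.0          # per-branch exon loss probability
    p_constitutive: float = 0.1  # per-species chance the focal exon is constitutive
    frac_dependent: float = 0.5  # fraction of alternative focal exons that respond
    frac_enhanced: float = 0.5   # among dependent exons
    frac_direct: float = 0.6     # among dependent exons
    dpsi_true: float = 30.0      # planted |effect| in PSI units
    psi_beta: tuple[float, float] = (2.0, 2.0)  # control PSI ~ 100*Beta(a,b)
    depth: float = 60.0          # expected total reads per event
    depth_model: str = "constant"  # constant | lognormal
    depth_sigma: float = 0.5     # log-sd for the lognormal depth model
    ensure_headroom: bool = True  # resample control PSI so the planted
    # loss-of-function shift fits in [0,100] and the effect size is exact
    overdispersion_rho: float = 0.0  # beta-binomial intra-class correlation
    expr_log_mean: float = 5.0   # ln-scale mean of true expression (reads)
    expr_log_sd: float = 1.0
    library_size: float = 1e6    # nominal total mapped reads per sample; the
    # simulated families are a subsample of a transcriptome of this size
    expr_dispersion: float = 0.1  # NB dispersion
    frac_de: float = 0.2          # fraction of genes with planted fold change
    de_fold: float = 3.0
    random_strand: bool = True


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class ExonTruth:
    family: int
    species_present: list[str]
    alternative: dict[str, bool]           # per species
    esrp_dependent: bool
    direction: str | None                  # enhanced | silenced
    dpsi_true: float
    effective_dpsi: dict[str, float] = field(default_factory=dict)  # after clamping
    direct: bool | None = None
    event_ids: dict[str, str] = field(default_factory=dict)


@dataclass
class GeneTruth:
    family: int
    gene_ids: dict[str, str]
    expr_level: float
    fold_change: float                     # perturbed/control, 1.0 = no change
    de: bool


@dataclass
class SimTruth:
    exons: list[ExonTruth] = field(default_factory=list)
    genes: list[GeneTruth] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"exons": [asdict(e) for e in self.exons], "genes": [asdict(g) for g in self.genes]},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            exons=[ExonTruth(**e) for e in raw["exons"]],
            genes=[GeneTruth(**g) for g in raw["genes"]],
        )


# ---------------------------------------------------------------------------
# Gene-family evolution along a species tree
# ---------------------------------------------------------------------------


@dataclass
class _ExonState:
    exon_id: str
    peptide: list[str]
    codons: list[str]

    def dna(self) -> str:
        return "".join(self.codons)


@dataclass
class _GeneState:
    exons: list[_ExonState]
    introns: list[str]
    alt_id: str

    def alt_index(self) -> int:
        return next(i for i, e in enumerate(self.exons) if e.exon_id == self.alt_id)

    def copy(self) -> "_GeneState":
        return _GeneState(
            exons=[_ExonState(e.exon_id, list(e.peptide), list(e.codons)) for e in self.exons],
            introns=list(self.introns),
            alt_id=self.alt_id,
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _ancestral_gene(rng: np.random.Generator, params: SimParams, family: int) -> _GeneState:
    n_exons = int(rng.integers(params.n_exons_range[0], params.n_exons_range[1] + 1))
    alt_index = n_exons // 2
    lengths = []
    for i in range(n_exons):
        if i == alt_index:
            lo, hi = params.alt_exon_len_range
            ln = int(rng.integers(lo, hi + 1))
            ln -= ln % 3  # frame-preserving cassette exon
        else:
            ln = int(rng.integers(params.exon_len_range[0], params.exon_len_range[1] + 1))
        lengths.append(max(ln, 9))
    # total coding length must be a codon multiple
    excess = sum(lengths) % 3
    if excess:
        lengths[-1] += 3 - excess
    # build the full CDS once, then cut per-exon nt chunks (codon boundaries
    # may straddle exon junctions, giving non-zero intron phases)
    total_res = sum(lengths) // 3
    full_pep = [AA[j] for j in rng.integers(0, len(AA), size=total_res)]
    full_dna = "".join(_CODON[a] for a in full_pep)
    exons = []
    pos = 0
    for i, ln in enumerate(lengths):
        exons.append(_ExonState(exon_id=f"F{family}e{i}", peptide=[], codons=[full_dna[pos : pos + ln]]))
        pos += ln
    introns = [
        _random_seq(rng, int(rng.integers(params.intron_len_range[0], params.intron_len_range[1] + 1)))
        for _ in range(n_exons - 1)
    ]
    return _GeneState(exons=exons, introns=introns, alt_id=f"F{family}e{alt_index}")


def _mutate_dna(rng: np.random.Generator, seq: str, p: float) -> str:
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _mutate_coding(rng: np.random.Generator, dna: str, p: float) -> str:
    """Codon-level substitution: each codon is replaced by the canonical
    codon of a different residue with probability p (frame preserved)."""
    if p <= 0:
        return dna
    codons = [dna[i : i + 3] for i in range(0, len(dna) - len(dna) % 3, 3)]
    tail = dna[len(codons) * 3 :]
    aas = list(AA)
    for i, c in enumerate(codons):
        if rng.random() < p:
            codons[i] = _CODON[aas[int(rng.integers(0, len(aas)))]]
    return "".join(codons) + tail


def _evolve_branch(rng: np.random.Generator, state: _GeneState, params: SimParams) -> _GeneState:
    st = state.copy()
    alt_i = st.alt_index()
    # substitution
    cds = "".join(e.codons[0] for e in st.exons)
    cds = _mutate_coding(rng, cds, params.p_sub)
    pos = 0
    for e in st.exons:
        ln = len(e.codons[0])
        e.codons = [cds[pos : pos + ln]]
        pos += ln
    st.introns = [_mutate_dna(rng, s, params.p_sub) for s in st.introns]
    # exon loss: never the focal exon or its neighbours, never terminal exons
    if params.p_loss > 0 and rng.random() < params.p_loss:
        candidates = [
            i
            for i in range(1, len(st.exons) - 1)
            if abs(i - alt_i) > 1 and len(st.exons[i].codons[0]) % 3 == 0
        ]
        if candidates:
            i = int(rng.choice(candidates))
            del st.exons[i]
            merged = st.introns[i - 1] + st.introns[i]
            st.introns[i - 1 : i + 1] = [merged[: len(st.introns[i - 1])]]
    # exon gain: frame-preserving, inserted by splitting an intron
    if params.p_gain > 0 and rng.random() < params.p_gain:
        alt_i = st.alt_index()
        slots = [i for i in range(len(st.introns)) if i not in (alt_i - 1, alt_i)]
        if slots:
            i = int(rng.choice(slots))
            ln = int(rng.integers(params.exon_len_range[0], params.exon_len_range[1] + 1))
            ln -= ln % 3
            new = _ExonState(
                exon_id=f"gain{int(rng.integers(0, 10**9))}",
                peptide=[],
                codons=["".join(_CODON[AA[j]] for j in rng.integers(0, len(AA), size=ln // 3))],
            )
            intron = st.introns[i]
            half = len(intron) // 2
            st.exons.insert(i + 1, new)
            st.introns[i : i + 1] = [intron[:half], intron[half:]]
    return st


def _parse_tree(newick: str):
    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    leaves = [t.name for t in tree.get_terminals()]
    if len(leaves) < 2:
        raise ValueError("species tree must have at least 2 leaves")
    return tree, leaves


# ---------------------------------------------------------------------------
# Emission into package data structures
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSpecies:
    species: str
    genome: dict[str, str] = field(default_factory=dict)
    models: dict[str, GeneModel] = field(default_factory=dict)
    isoforms: dict[str, list[ProteinIsoform]] = field(default_factory=dict)
    events: dict[str, AsEvent] = field(default_factory=dict)
    # genomic coordinates of the scan-universe features per event, for editing
    event_geometry: dict[str, dict] = field(default_factory=dict)


@dataclass
class Simulation:
    species: dict[str, SimulatedSpecies]
    truth: SimTruth
    params: SimParams


def _emit_gene(
    rng: np.random.Generator,
    sp: SimulatedSpecies,
    state: _GeneState,
    family: int,
    params: SimParams,
) -> tuple[str, str, int]:
    """Lay the gene onto its own chromosome; returns (gene_id, event_id, exonic length)."""
    gene_id = f"{sp.species}_G{family:04d}"
    chrom = gene_id
    strand = "+" if (not params.random_strand or rng.random() < 0.5) else "-"
    # transcript-oriented construction
    parts = [_random_seq(rng, params.flank_len)]
    exon_ivs_t: list[tuple[int, int]] = []  # transcript-oriented chrom coords
    pos = params.flank_len
    for i, ex in enumerate(state.exons):
        dna = ex.codons[0]
        parts.append(dna)
        exon_ivs_t.append((pos, pos + len(dna)))
        pos += len(dna)
        if i < len(state.introns):
            parts.append(state.introns[i])
            pos += len(state.introns[i])
    parts.append(_random_seq(rng, params.flank_len))
    seq_t = "".join(parts)
    L = len(seq_t)
    if strand == "+":
        chrom_seq = seq_t
        exon_ivs = exon_ivs_t
    else:
        chrom_seq = _revcomp(seq_t)
        # mapped intervals stay in transcript (5'->3') order: descending genomic
        exon_ivs = [(L - e, L - s) for s, e in exon_ivs_t]
    sp.genome[chrom] = chrom_seq
    cds_lo = min(s for s, _ in exon_ivs)
    cds_hi = max(e for _, e in exon_ivs)
    tx_id = f"{gene_id}.t1"
    model = GeneModel(
        gene_id=gene_id,
        species=sp.species,
        chrom=chrom,
        strand=strand,
        transcripts={
            tx_id: Transcript(transcript_id=tx_id, exons=exon_ivs, cds_start=cds_lo, cds_end=cds_hi)
        },
        mappable_length=sum(e - s for s, e in exon_ivs),
    )
    model.validate()
    sp.models[gene_id] = model
    iso = derive_protein_junction_map(model, tx_id, genome=sp.genome)
    sp.isoforms[gene_id] = [iso]
    # focal event
    alt_i = state.alt_index()
    event_id = f"{sp.species}_EV{family:04d}"
    event = AsEvent(
        event_id=event_id,
        gene_id=gene_id,
        type="AltEx",
        alt_interval=exon_ivs[alt_i],
        upstream_exon=exon_ivs[alt_i - 1],
        downstream_exon=exon_ivs[alt_i + 1],
    )
    sp.events[event_id] = event
    sp.event_geometry[event_id] = {"strand": strand, "alt_index": alt_i}
    return gene_id, event_id, model.mappable_length


def _revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_gene_families(
    species_tree: str,
    params: SimParams | None = None,
    seed: int = 0,
) -> Simulation:
    """Evolve ``params.n_families`` gene families along a newick species
    tree; deterministic given (params, seed)."""
    params = params or SimParams()
    tree, leaves = _parse_tree(species_tree)
    rng = np.random.default_rng(seed)
    species = {name: SimulatedSpecies(species=name) for name in leaves}
    truth = SimTruth()
    for fam in range(params.n_families):
        anc = _ancestral_gene(rng, params, fam)
        # depth-first descent from the root
        states: dict[str, _GeneState] = {}

        def descend(clade, state):
            st = _evolve_branch(rng, state, params)
            if clade.is_terminal():
                states[clade.name] = st
            else:
                for child in clade.clades:
                    descend(child, st)

        for child in tree.root.clades:
            descend(child, anc)
        if not states:  # single-clade root edge case
            descend(tree.root, anc)

        dependent = rng.random() < params.frac_dependent
        direction = None
        direct = None
        if dependent:
            direction = "enhanced" if rng.random() < params.frac_enhanced else "silenced"
            direct = bool(rng.random() < params.frac_direct)
        exon_truth = ExonTruth(
            family=fam,
            species_present=sorted(states),
            alternative={},
            esrp_dependent=dependent,
            direction=direction,
            dpsi_true=params.dpsi_true if dependent else 0.0,
            direct=direct,
        )
        gene_truth = GeneTruth(
            family=fam,
            gene_ids={},
            expr_level=float(np.exp(rng.normal(params.expr_log_mean, params.expr_log_sd))),
            fold_change=1.0,
            de=False,
        )
        if rng.random() < params.frac_de:
            gene_truth.de = True
            up = rng.random() < 0.5
            gene_truth.fold_change = params.de_fold if up else 1.0 / params.de_fold
        for name in sorted(states):
            gene_id, event_id, _ = _emit_gene(rng, species[name], states[name], fam, params)
            gene_truth.gene_ids[name] = gene_id
            exon_truth.event_ids[name] = event_id
            exon_truth.alternative[name] = bool(rng.random() >= params.p_constitutive)
        truth.exons.append(exon_truth)
        truth.genes.append(gene_truth)
    return Simulation(species=species, truth=truth, params=params)


# ---------------------------------------------------------------------------
# PSI tables
# ---------------------------------------------------------------------------


def default_design(n_replicates: int = 2, sign: str = "loss") -> SampleDesign:
    samples = {}
    for r in range(1, n_replicates + 1):
        samples[f"ctrl_{r}"] = SampleInfo("control", sign, str(r), "main")
        samples[f"pert_{r}"] = SampleInfo("perturbed", sign, str(r), "main")
    return SampleDesign(samples)


def _draw_depth(rng: np.random.Generator, params: SimParams) -> int:
    if params.depth_model == "lognormal":
        return max(1, int(round(np.exp(rng.normal(np.log(params.depth), params.depth_sigma)))))
    return max(1, int(round(params.depth)))


def simulate_psi_tables(
    sim: Simulation,
    design: SampleDesign,
    seed: int = 0,
) -> dict[str, PsiTable]:
    """Sample observed PSI tables per species under the planted truth.

    Perturbed-condition true PSI is the control PSI shifted by
    -dPSI_true (enhanced) or +dPSI_true (silenced) for loss-of-function
    samples, with the sign flipped for gain-of-function; shifts are
    clamped to [0, 100] and the effective (post-clamp) shift recorded in
    the truth.  Observed inclusion reads are Binomial(total, PSI/100),
    or beta-binomial when overdispersion is enabled.
    """
    import pandas as pd

    params = sim.params
    rng = np.random.default_rng(seed)
    tables: dict[str, PsiTable] = {}
    for sp_name, sp in sim.species.items():
        events_rows, data_rows = [], []
        for et in sim.truth.exons:
            if sp_name not in et.event_ids:
                continue
            event_id = et.event_ids[sp_name]
            ev = sp.events[event_id]
            if et.alternative[sp_name]:
                psi_ctrl = 100.0 * rng.beta(*params.psi_beta)
            else:
                psi_ctrl = 100.0
            shift = 0.0
            if et.esrp_dependent and et.alternative[sp_name]:
                shift = -et.dpsi_true if et.direction == "enhanced" else et.dpsi_true
                if params.ensure_headroom:
                    for _ in range(200):
                        if 0.0 <= psi_ctrl + shift <= 100.0:
                            break
                        psi_ctrl = 100.0 * rng.beta(*params.psi_beta)
            events_rows.append(
                {
                    "event_id": event_id,
                    "gene_id": ev.gene_id,
                    "type": ev.type,
                    "coord": f"{sp.models[ev.gene_id].chrom}:{ev.alt_interval[0]}-{ev.alt_interval[1]}",
                }
            )
            psi_pert_loss = float(np.clip(psi_ctrl + shift, 0.0, 100.0))
            if et.esrp_dependent and et.alternative[sp_name]:
                et.effective_dpsi[sp_name] = psi_ctrl - psi_pert_loss
            for sample_id in design.sample_ids():
                info = design[sample_id]
                if info.condition == "control":
                    true_psi = psi_ctrl
                elif info.perturbation_sign == "loss":
                    true_psi = psi_pert_loss
                else:  # gain-of-function: shift reversed
                    true_psi = float(np.clip(psi_ctrl - shift, 0.0, 100.0))
                total = _draw_depth(rng, params)
                p = true_psi / 100.0
                if params.overdispersion_rho > 0:
                    rho = params.overdispersion_rho
                    a = p * (1 - rho) / rho
                    b = (1 - p) * (1 - rho) / rho
                    if a > 0 and b > 0:
                        p = rng.beta(a, b)
                inc = int(rng.binomial(total, p))
                exc = total - inc
                psi_obs = round(100.0 * inc / total, 2) if total else float("nan")
                data_rows.append(
                    {
                        "event_id": event_id,
                        "sample_id": sample_id,
                        "psi": psi_obs,
                        "tier": tier_from_reads(total),
                        "inc": inc,
                        "exc": exc,
                        "b5": float("nan"),
                        "b3": float("nan"),
                    }
                )
        events = pd.DataFrame(events_rows).set_index("event_id")
        data = pd.DataFrame(data_rows, columns=PsiTable.DATA_COLUMNS)
        tables[sp_name] = PsiTable(events, data, design.sample_ids())
    return tables


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------


def simulate_expression_counts(
    sim: Simulation,
    design: SampleDesign,
    seed: int = 0,
):
    """Negative-binomial gene counts per species with planted fold changes."""
    import pandas as pd

    params = sim.params
    rng = np.random.default_rng(seed)
    tables = {}
    for sp_name, sp in sim.species.items():
        rows = []
        for gt in sim.truth.genes:
            if sp_name not in gt.gene_ids:
                continue
            gene_id = gt.gene_ids[sp_name]
            mappable = sp.models[gene_id].mappable_length
            for sample_id in design.sample_ids():
                info = design[sample_id]
                mu = gt.expr_level
                if info.condition == "perturbed":
                    fc = gt.fold_change
                    if info.perturbation_sign == "gain" and fc != 1.0:
                        fc = 1.0 / fc
                    mu *= fc
                d = params.expr_dispersion
                if d > 0:
                    n_nb = 1.0 / d
                    p_nb = n_nb / (n_nb + mu)
                    reads = int(rng.negative_binomial(n_nb, p_nb))
                else:
                    reads = int(rng.poisson(mu))
                rows.append(
                    {
                        "gene_id": gene_id,
                        "sample": sample_id,
                        "reads": reads,
                        "mappable_length": mappable,
                    }
                )
        tables[sp_name] = pd.DataFrame(rows)
    return tables


# ---------------------------------------------------------------------------
# Motif planting / scrubbing
# ---------------------------------------------------------------------------

#: Default GU-rich hexamer set used by the simulator (stand-in motif list;
#: any hexamer set can be supplied instead).
DEFAULT_MOTIFS = MotifSet(
    [
        "GTGGTG", "TGGTGG", "GGTGGT", "GTGTGG", "TGTGGG", "GGGTGG",
        "TGGGTG", "GGTGTG", "GTGGGT", "TGGTGT", "GGTGGG", "TGTGGT",
    ]
)

from .motifs import (  # noqa: E402  (shared region constants)
    ACCEPTOR_EXCLUSION_NT,
    EXON_JUNCTION_NT,
    INTRON_FLANK_NT,
    SPLICE_SITE_5P_NT,
    scan_motifs,
)


def _scrub(rng: np.random.Generator, seq: str, motifs: MotifSet, max_iter: int = 200) -> str:
    """Mutate bases until the sequence contains no motif occurrence."""
    s = list(seq)
    for _ in range(max_iter):
        hits = scan_motifs("".join(s), motifs)
        if not hits:
            break
        for h in hits:
            j = h + motifs.k // 2
            cur = s[j]
            s[j] = str(rng.choice([b for b in "ACGT" if b != cur]))
    return "".join(s)


def plant_motifs(
    sim: Simulation,
    motifs: MotifSet | None = None,
    scenario: str = "restricted",
    n_plant: int = 2,
    seed: int = 0,
) -> list[dict]:
    """Edit genomes so motif placement matches the planted truth.

    Direct enhanced targets receive ``n_plant`` motifs in the
    scenario-consistent enhanced region (first 250 nt of the downstream
    intron, past the 5' splice-site span); direct silenced targets in
    the silenced regions (alternative exon / last 250 nt of the upstream
    intron).  Indirect targets have every motif occurrence scrubbed from
    the scan universe, so classifiers must label them indirect.  Returns
    a BED-like list of planted sites.  Regions shorter than one motif
    are skipped and recorded with a null position.
    """
    motifs = motifs or DEFAULT_MOTIFS
    if scenario not in ("restricted", "expanded"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    planted: list[dict] = []
    for et in sim.truth.exons:
        if not et.esrp_dependent:
            continue
        for sp_name in et.species_present:
            sp = sim.species[sp_name]
            event = sp.events[et.event_ids[sp_name]]
            model = sp.models[event.gene_id]
            edit = _GenomeEditor(sp, model, event)
            if et.direct:
                used: set[tuple[str, int]] = set()
                for _ in range(n_plant):
                    motif = motifs.motifs[int(rng.integers(0, len(motifs.motifs)))]
                    rec = edit.plant(rng, motif, et.direction, used)
                    rec.update(event_id=event.event_id, species=sp_name)
                    planted.append(rec)
            else:
                edit.scrub_universe(rng, motifs)
    return planted


class _GenomeEditor:
    """Transcript-oriented read/write access to an event's scan universe."""

    def __init__(self, sp: SimulatedSpecies, model: GeneModel, event: AsEvent):
        self.sp = sp
        self.model = model
        self.event = event
        self.strand = model.strand

    def _iv(self, which: str) -> tuple[int, int]:
        alt, up, dn = self.event.alt_interval, self.event.upstream_exon, self.event.downstream_exon
        if which == "alt_exon":
            return alt
        if self.strand == "+":
            return {"up_intron": (up[1], alt[0]), "dn_intron": (alt[1], dn[0])}[which]
        return {"up_intron": (alt[1], up[0]), "dn_intron": (dn[1], alt[0])}[which]

    def read(self, which: str) -> str:
        s, e = self._iv(which)
        seq = self.sp.genome[self.model.chrom][s:e]
        return _revcomp(seq) if self.strand == "-" else seq

    def write(self, which: str, t_offset: int, payload: str) -> int:
        """Write a payload at a transcript-oriented offset; returns the
        genomic start of the edit."""
        s, e = self._iv(which)
        if self.strand == "+":
            g = s + t_offset
            chrom = self.sp.genome[self.model.chrom]
            self.sp.genome[self.model.chrom] = chrom[:g] + payload + chrom[g + len(payload) :]
            return g
        g_end = e - t_offset
        g = g_end - len(payload)
        chrom = self.sp.genome[self.model.chrom]
        self.sp.genome[self.model.chrom] = chrom[:g] + _revcomp(payload) + chrom[g_end:]
        return g

    def _pick_offset(
        self,
        rng: np.random.Generator,
        region: str,
        lo: int,
        hi: int,
        k: int,
        used: set[tuple[str, int]] | None,
    ) -> int | None:
        """Uniform offset in [lo, hi] avoiding overlap with prior plants."""
        if hi < lo:
            return None
        for _ in range(50):
            off = int(rng.integers(lo, hi + 1))
            if used is None or all(r != region or abs(off - o) >= k for r, o in used):
                if used is not None:
                    used.add((region, off))
                return off
        return None

    def plant(
        self,
        rng: np.random.Generator,
        motif: str,
        direction: str,
        used: set[tuple[str, int]] | None = None,
    ) -> dict:
        k = len(motif)
        if direction == "enhanced":
            # first 250 nt of the downstream intron, past the 5' splice site
            L = len(self.read("dn_intron"))
            off = self._pick_offset(
                rng, "dn_intron", SPLICE_SITE_5P_NT, min(INTRON_FLANK_NT, L) - k, k, used
            )
            if off is None:
                return {"region": "dn_intron_5p", "pos": None}
            g = self.write("dn_intron", off, motif)
            return {"region": "dn_intron_5p", "pos": g, "chrom": self.model.chrom}
        # silenced: alternative exon or last 250 nt of the upstream intron
        if rng.random() < 0.5 and len(self.read("alt_exon")) >= k:
            L = len(self.read("alt_exon"))
            off = self._pick_offset(rng, "alt_exon", 0, L - k, k, used)
            if off is not None:
                g = self.write("alt_exon", off, motif)
                return {"region": "alt_exon", "pos": g, "chrom": self.model.chrom}
        L = len(self.read("up_intron"))
        off = self._pick_offset(rng, "up_intron", max(0, L - INTRON_FLANK_NT), L - k, k, used)
        if off is None:
            return {"region": "up_intron_3p", "pos": None}
        g = self.write("up_intron", off, motif)
        return {"region": "up_intron_3p", "pos": g, "chrom": self.model.chrom}

    def scrub_universe(self, rng: np.random.Generator, motifs: MotifSet) -> None:
        for which in ("alt_exon", "up_intron", "dn_intron"):
            seq = self.read(which)
            clean = _scrub(rng, seq, motifs)
            if clean != seq:
                self.write(which, 0, clean)
        # junction-proximal exon ends
        up = self.read_exon("upstream")
        clean = up[:-EXON_JUNCTION_NT] + _scrub(rng, up[-EXON_JUNCTION_NT:], motifs)
        if clean != up:
            self.write_exon("upstream", clean)
        dn = self.read_exon("downstream")
        clean = _scrub(rng, dn[:EXON_JUNCTION_NT], motifs) + dn[EXON_JUNCTION_NT:]
        if clean != dn:
            self.write_exon("downstream", clean)

    def read_exon(self, which: str) -> str:
        iv = self.event.upstream_exon if which == "upstream" else self.event.downstream_exon
        seq = self.sp.genome[self.model.chrom][iv[0] : iv[1]]
        return _revcomp(seq) if self.strand == "-" else seq

    def write_exon(self, which: str, payload: str) -> None:
        iv = self.event.upstream_exon if which == "upstream" else self.event.downstream_exon
        chrom = self.sp.genome[self.model.chrom]
        out = payload if self.strand == "+" else _revcomp(payload)
        self.sp.genome[self.model.chrom] = chrom[: iv[0]] + out + chrom[iv[1] :]


# ---------------------------------------------------------------------------
# Orthology evidence
# ---------------------------------------------------------------------------


def simulate_orthology_evidence(
    sim: Simulation,
    seed: int = 0,
    p_source_missing: float = 0.1,
):
    """Emit pairwise orthology evidence for the true gene families.

    Each true cross-species gene pair is supported by each of the three
    source families independently with probability ``1 - p_source_missing``
    (so most pairs meet the 2-of-3 acceptance rule).
    """
    from .homology import SOURCES, OrthologyEvidence

    rng = np.random.default_rng(seed)
    evidence: set[OrthologyEvidence] = set()
    for gt in sim.truth.genes:
        species = sorted(gt.gene_ids)
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                ga, gb = sorted((gt.gene_ids[a], gt.gene_ids[b]))
                kept = [s for s in SOURCES if rng.random() >= p_source_missing]
                if not kept:
                    kept = [SOURCES[int(rng.integers(0, len(SOURCES)))]]
                for s in kept:
                    evidence.add(OrthologyEvidence(ga, gb, s))
    return evidence


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------


def simulate_score_track(sim_species: SimulatedSpecies, seed: int = 0, smooth: int = 25) -> ScoreTrack:
    """Smooth per-base scores in [0,1] over each chromosome (moving-average
    filtered uniform noise)."""
    rng = np.random.default_rng(seed)
    track = ScoreTrack()
    kernel = np.ones(smooth) / smooth
    for chrom, seq in sim_species.genome.items():
        raw = rng.random(len(seq))
        sm = np.convolve(raw, kernel, mode="same")
        track.arrays[chrom] = np.clip(sm, 0.0, 1.0)
    return track
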