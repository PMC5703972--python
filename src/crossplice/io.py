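"""Readers and writers for every external format the pipeline touches.

Formats: the PSI TSV dialect (one row per event; per sample a PSI column
and a quality column ``tier@inc,exc[,b5,b3]``), GTF/GFF3 gene models,
FASTA, gene-level counts TSV, bedGraph score tracks, BED6, plain-text
motif lists and JSON run manifests.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    GeneModel,
    MotifSet,
    PsiTable,
    ScoreTrack,
    Transcript,
    tier_rank,
)

META_COLUMNS = ["EVENT", "GENE", "TYPE", "COORD"]


@dataclass
class PsiDialect:
    """Layout of the PSI table dialect (vast-tools-style, self-contained)."""

    quality_suffix: str = ".Q"
    sep: str = "\t"
    na_value: str = "NA"
    consistency_tol: float = 0.05


@dataclass
class RowReport:
    """Per-row validation outcome for rejected PSI rows."""

    line: int
    event_id: str
    reason: str


# ---------------------------------------------------------------------------
# PSI tables
# ---------------------------------------------------------------------------


def _parse_quality(cell: str) -> tuple[str, int, int, float, float]:
    tier, _, counts = cell.partition("@")
    parts = counts.split(",")
    if len(parts) not in (2, 4):
        raise ValueError(f"malformed quality cell {cell!r}")
    inc, exc = int(parts[0]), int(parts[1])
    b5 = float(parts[2]) if len(parts) == 4 else float("nan")
    b3 = float(parts[3]) if len(parts) == 4 else float("nan")
    tier_rank(tier)  # validates the label
    return tier, inc, exc, b5, b3


def _format_quality(tier: str, inc: int, exc: int, b5: float, b3: float) -> str:
    base = f"{tier}@{int(inc)},{int(exc)}"
    if not (np.isnan(b5) and np.isnan(b3)):
        base += f",{int(b5)},{int(b3)}"
    return base


def read_psi_table(
    path: str,
    dialect: PsiDialect | None = None,
    expected_samples: Sequence[str] | None = None,
) -> PsiTable:
    """Read a PSI table; invalid rows are dropped and reported.

    The returned table carries the rejection report as ``table.rejected``
    (a list of :class:`RowReport`).  A missing PSI or quality column for
    an expected sample is a hard error naming the sample.
    """
    dialect = dialect or PsiDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[: len(META_COLUMNS)] != META_COLUMNS:
        raise ValueError(f"PSI table must start with columns {META_COLUMNS}")
    sample_cols = [c for c in cols[len(META_COLUMNS) :] if not c.endswith(dialect.quality_suffix)]
    for s in sample_cols:
        if s + dialect.quality_suffix not in cols:
            raise ValueError(f"missing quality column for sample {s!r}")
    if expected_samples is not None:
        for s in expected_samples:
            if s not in sample_cols:
                raise ValueError(f"missing sample column {s!r}")

    events_rows, data_rows, rejected = [], [], []
    for i, row in df.iterrows():
        event_id = row["EVENT"]
        parsed, bad = [], None
        for s in sample_cols:
            psi_cell = row[s]
            q_cell = row[s + dialect.quality_suffix]
            try:
                tier, inc, exc, b5, b3 = _parse_quality(q_cell)
            except ValueError as e:
                bad = str(e)
                break
            psi = float("nan") if psi_cell == dialect.na_value else float(psi_cell)
            if not np.isnan(psi) and not (0.0 <= psi <= 100.0):
                bad = f"sample {s}: PSI {psi} outside [0,100]"
                break
            total = inc + exc
            if total > 0 and not np.isnan(psi):
                if abs(psi - 100.0 * inc / total) > dialect.consistency_tol:
                    bad = (
                        f"sample {s}: PSI {psi} inconsistent with reads "
                        f"{inc}/{total} ({100.0 * inc / total:.2f})"
                    )
                    break
            parsed.append((s, psi, tier, inc, exc, b5, b3))
        if bad is not None:
            rejected.append(RowReport(line=int(i) + 2, event_id=event_id, reason=bad))
            continue
        events_rows.append(
            {"event_id": event_id, "gene_id": row["GENE"], "type": row["TYPE"], "coord": row["COORD"]}
        )
        for s, psi, tier, inc, exc, b5, b3 in parsed:
            data_rows.append(
                {
                    "event_id": event_id,
                    "sample_id": s,
                    "psi": psi,
                    "tier": tier,
                    "inc": inc,
                    "exc": exc,
                    "b5": b5,
                    "b3": b3,
                }
            )
    events = pd.DataFrame(events_rows, columns=["event_id", "gene_id", "type", "coord"]).set_index(
        "event_id"
    )
    data = pd.DataFrame(data_rows, columns=PsiTable.DATA_COLUMNS)
    table = PsiTable(events, data, sample_cols)
    table.rejected = rejected  # type: ignore[attr-defined]
    return table


def write_psi_table(table: PsiTable, path: str, dialect: PsiDialect | None = None) -> None:
    """Write the canonical dialect: PSI as %.2f, quality as tier@inc,exc[,b5,b3]."""
    dialect = dialect or PsiDialect()
    idx = table.data.set_index(["event_id", "sample_id"])
    with open(path, "w") as fh:
        header = list(META_COLUMNS)
        for s in table.samples:
            header += [s, s + dialect.quality_suffix]
        fh.write(dialect.sep.join(header) + "\n")
        for event_id, meta in table.events.iterrows():
            cells = [str(event_id), meta["gene_id"], meta["type"], meta["coord"]]
            for s in table.samples:
                r = idx.loc[(event_id, s)]
                psi = r["psi"]
                cells.append(dialect.na_value if np.isnan(psi) else f"{psi:.2f}")
                cells.append(
                    _format_quality(r["tier"], int(r["inc"]), int(r["exc"]), r["b5"], r["b3"])
                )
            fh.write(dialect.sep.join(cells) + "\n")


# ---------------------------------------------------------------------------
# Gene models (GTF / GFF3)
# ---------------------------------------------------------------------------


def read_gene_models(
    path: str,
    species: str = "unknown",
    gene_attr: str = "gene_id",
    transcript_attr: str = "transcript_id",
) -> dict[str, GeneModel]:
    """Parse exon/CDS features from GTF or GFF3 into validated gene models.

    Coordinates are converted to 0-based half-open; exons are re-ordered
    into transcript orientation at parse time.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    cds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes[gene_attr][0]
        tid = feat.attributes[transcript_attr][0]
        if gid not in genes:
            genes[gid] = GeneModel(gene_id=gid, species=species, chrom=feat.seqid, strand=feat.strand)
        iv = (feat.start - 1, feat.end)  # 1-based inclusive -> 0-based half-open
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault((gid, tid), []).append(iv)
    for (gid, tid), ivs in exons.items():
        model = genes[gid]
        ivs = sorted(ivs)
        if model.strand == "-":
            ivs = ivs[::-1]
        c = cds.get((gid, tid))
        model.transcripts[tid] = Transcript(
            transcript_id=tid,
            exons=ivs,
            cds_start=min(s for s, _ in c) if c else None,
            cds_end=max(e for _, e in c) if c else None,
        )
    for (gid, tid) in cds:
        if (gid, tid) not in exons:
            raise ValueError(f"transcript {tid} has CDS features but zero exons")
    for model in genes.values():
        model.validate()
    return genes


def write_gene_models(models: Mapping[str, GeneModel], path: str, source: str = "crossplice") -> None:
    """Write gene models as GTF (1-based inclusive, exon + CDS features)."""
    with open(path, "w") as fh:
        for model in models.values():
            for tx in model.transcripts.values():
                attrs = f'gene_id "{model.gene_id}"; transcript_id "{tx.transcript_id}";'
                for s, e in sorted(tx.exons):
                    fh.write(
                        f"{model.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t{attrs}\n"
                    )
                for s, e in sorted(tx.coding_intervals()):
                    fh.write(
                        f"{model.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{model.strand}\t0\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Counts, BED, bedGraph, motif lists, manifests
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = ["gene_id", "sample", "reads", "mappable_length"]


def read_counts_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns {missing}")
    if (df["mappable_length"] <= 0).any():
        bad = df.loc[df["mappable_length"] <= 0, "gene_id"].tolist()
        raise ValueError(f"non-positive mappable length for genes {bad[:5]}")
    return df


def write_counts_table(df: pd.DataFrame, path: str) -> None:
    df[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed6(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def write_bed6(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str, chrom_lengths: Mapping[str, int]) -> ScoreTrack:
    """Load a bedGraph into dense per-base arrays; uncovered bases are NaN."""
    track = ScoreTrack()
    for chrom, length in chrom_lengths.items():
        track.add(chrom, length)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for _, row in df.iterrows():
        track.arrays[row["chrom"]][int(row["start"]) : int(row["end"])] = row["value"]
    return track


def write_bedgraph(track: ScoreTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.arrays.items():
            start = None
            for i in range(len(arr) + 1):
                v = arr[i] if i < len(arr) else np.nan
                if start is not None and (i == len(arr) or np.isnan(v) or v != arr[start]):
                    fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:g}\n")
                    start = None
                if start is None and i < len(arr) and not np.isnan(v):
                    start = i
    return None


def read_motif_list(path: str) -> MotifSet:
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                motifs.append(line)
    return MotifSet(motifs)


def write_motif_list(motifs: MotifSet, path: str) -> None:
    with open(path, "w") as fh:
        for m in motifs.motifs:
            fh.write(m + "\n")


def read_evidence_table(path: str) -> set:
    from .homology import OrthologyEvidence

    df = pd.read_csv(path, sep="\t")
    return {
        OrthologyEvidence(r["gene_a"], r["gene_b"], r["source"]) for _, r in df.iterrows()
    }


def write_evidence_table(evidence: Iterable, path: str) -> None:
    rows = sorted((e.gene_a, e.gene_b, e.source) for e in evidence)
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"]).to_csv(path, sep="\t", index=False)


EVENT_COLUMNS = [
    "event_id", "gene_id", "type",
    "alt_start", "alt_end", "up_start", "up_end", "dn_start", "dn_end",
]


def write_events_table(events: Mapping[str, "AsEvent"], path: str) -> None:
    rows = []
    for ev in events.values():
        up = ev.upstream_exon or (-1, -1)
        dn = ev.downstream_exon or (-1, -1)
        rows.append(
            {
                "event_id": ev.event_id, "gene_id": ev.gene_id, "type": ev.type,
                "alt_start": ev.alt_interval[0], "alt_end": ev.alt_interval[1],
                "up_start": up[0], "up_end": up[1], "dn_start": dn[0], "dn_end": dn[1],
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events_table(path: str) -> dict[str, "AsEvent"]:
    from .model import AsEvent

    df = pd.read_csv(path, sep="\t")
    events = {}
    for _, r in df.iterrows():
        events[r["event_id"]] = AsEvent(
            event_id=r["event_id"],
            gene_id=r["gene_id"],
            type=r["type"],
            alt_interval=(int(r["alt_start"]), int(r["alt_end"])),
            upstream_exon=None if r["up_start"] < 0 else (int(r["up_start"]), int(r["up_end"])),
            downstream_exon=None if r["dn_start"] < 0 else (int(r["dn_start"]), int(r["dn_end"])),
        )
    return events


def write_exon_clusters(clusters, path: str) -> None:
    rows = []
    for cl in clusters:
        for sp, gene, exon in sorted(cl.members):
            rows.append({"cluster_id": cl.cluster_id, "species": sp, "gene_id": gene, "exon_id": exon})
    pd.DataFrame(rows, columns=["cluster_id", "species", "gene_id", "exon_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_exon_clusters(path: str):
    from .homology import ExonCluster

    df = pd.read_csv(path, sep="\t")
    clusters = []
    for cid, sub in df.groupby("cluster_id", sort=True):
        members = {(r["species"], r["gene_id"], r["exon_id"]) for _, r in sub.iterrows()}
        clusters.append(ExonCluster(cluster_id=cid, members=members))
    return clusters


def write_gene_clusters(clusters: Iterable[set], path: str) -> None:
    rows = []
    for i, cl in enumerate(sorted(clusters, key=lambda c: sorted(c)[0])):
        for g in sorted(cl):
            rows.append({"cluster_id": f"GC{i + 1:05d}", "gene_id": g})
    pd.DataFrame(rows, columns=["cluster_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
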