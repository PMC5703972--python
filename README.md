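# crossplice

Comparative analysis of splicing-factor-dependent exon programs across
species, as used to study Esrp-regulated alternative splicing in
development. The package re-implements, as a tested and reusable
pipeline, the computational chain that turns quantified RNA-seq tables
into cross-species conclusions:

1. **Differential splicing** — calling factor-dependent alternative
   splicing (AS) events from percent-spliced-in (PSI) tables with read
   coverage tiers: an event is called when |ΔPSI| between condition
   averages reaches the species threshold (15 for zebrafish/mouse, 10
   for sea urchin) *and* every pairwise control × perturbed comparison
   shows |ΔPSI| ≥ 5 in one direction. Intron-retention events must also
   pass a two-sided exact binomial read-imbalance test (p ≥ 0.05) in
   every sample. A multi-grouping combination mode handles designs that
   mix knockdown and overexpression experiments (opposite-direction
   rule, pooled-read merged samples), and a rescue rule re-admits
   events with one low-coverage replicate when a homologous exon is
   called in another species.
2. **Differential expression** — cRPKM
   (reads / (mappable kb) / (million mapped reads)) with minimum
   expression, read-support, average-fold and all-pairwise-fold
   filters.
3. **Exon homology** — orthologous gene clusters from 2-of-3 evidence
   sources plus guilt-by-association; pairwise global protein
   alignments (BLOSUM62, affine gaps) with intron positions and phases
   intercalated as alignment markers; exon pairs accepted automatically
   when the alternative exon and ≥1 flanking constitutive exon align
   with >20% similarity and both flanking intron positions are
   conserved with identical phase within 3 alignment columns;
   borderline cases are flagged for manual review, never silently
   promoted.
4. **RNA regulatory maps** — hexamer motif coverage (51-nt sliding
   window) over a standardized exon-centric region schema (75-nt exon
   ends, 250-nt intron ends), Restricted/Expanded-scenario
   direct/indirect target classification, one-sided Fisher tests for
   shared-regulation enrichment, and smoothed conservation-score
   profiles over exons with 150-nt flanks.
5. **Cross-species bookkeeping** — NH/NC/shared-set partitioning of
   called exons, genome-presence / constitutive / alternative homolog
   status, and the cross-species GO category-selection rule.

Because the original multi-species RNA-seq compendia are not required,
the package ships a first-class synthetic-data generator
(`crossplice.simulate`) that evolves gene families along a species
tree, plants factor-dependent ΔPSI effects sampled through binomial
read noise, plants scenario-consistent motifs, and records complete
ground truth — so every stage is testable end to end.

## Worked example

```bash
crossplice run-all --outdir run --seed 7
```

simulates 50 gene families across `((human,mouse),zebrafish)`, runs
every stage, writes inputs, per-stage result tables and a checksummed
manifest under `run/`, and prints recovery metrics against the planted
truth:

```json
{
  "diffexpr":   {"false_call_rate": 0.054, "sensitivity": 0.718},
  "diffsplice": {"false_call_rate": 0.0, "n_negative": 78, "n_positive": 72, "sensitivity": 1.0},
  "exon_clusters": {"f1": 1.0, "precision": 1.0, "recall": 1.0},
  "target_classes": {"accuracy": 1.0, "n": 72}
}
```

Reading: all 72 planted factor-dependent exons were recalled with no
false calls at the default thresholds; homologous-exon clusters were
reconstructed exactly; every called exon's direct/indirect status was
recovered from its planted motif placement. Differential expression is
harder by design — a 3-fold planted change against negative-binomial
noise with two replicates and strict pairwise-fold filters yields ~72%
sensitivity at a ~5% false-call rate.

Individual stages are also available as subcommands (`simulate`,
`diffsplice`, `diffexpr`, `exonhom`, `maps`, `scenarios`, `compare`)
and as plain library functions; see `docs/methods.md` for the model
and parameter reference.

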