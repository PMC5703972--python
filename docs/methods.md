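# Methods

This note documents the models, rules and parameter choices behind
`crossplice`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Conventions

All genomic intervals are 0-based half-open. Strand handling happens
once, at parse time: exon lists, event geometry and every extracted
sequence are in transcript orientation, so "upstream/downstream" means
5′/3′ on the mRNA throughout. PSI is a percentage in [0, 100]; ΔPSI is
always reported in loss-of-function orientation
(`mean(control) − mean(perturbed)`), so positive ΔPSI means the factor
enhances inclusion.

Read-support tiers follow the ordinal scale N < VLOW < LOW < OK < SOK.
When tiers must be (re)computed from read counts — synthetic tables,
pooled merged samples — the mapping is: N < 5 reads, VLOW 5–14,
LOW 15–24, OK 25–99, SOK ≥ 100 total reads. The upstream quantifier
that defines these labels does not publish its boundaries, so this
explicit mapping is a documented, configurable stand-in chosen for
reproducibility; all gating logic depends only on the *ordering*, plus
the VLOW floor.

## Differential splicing

Per species, an event is called iff

* every compared sample is quantified at tier ≥ VLOW (coverage gate);
* |ΔPSI| between condition averages ≥ `min_dpsi` (default 15; 10 is
  the sea-urchin-style setting for noisier material);
* every control × perturbed pairwise ΔPSI is ≥ +5 or every one ≤ −5
  (mixed signs fail — "same direction" is interpreted strictly);
* for intron retention, a two-sided exact binomial test of the 5′/3′
  intron-boundary read split against 0.5 is non-significant (p ≥ 0.05)
  in *every* sample; events with no boundary reads in some sample fail
  the gate (no evidence of balance). A one-sided variant is available
  by configuration; two-sided is the default since the direction of an
  imbalance artefact is not known a priori.

Boundary conventions: the average-ΔPSI cutoff is inclusive (≥) by
default, matching the "minimum ΔPSI of 15" phrasing; the multi-source
combination mode uses strict inequalities (> 15, > 5), matching its
"|ΔPSI| > 15" phrasing. Both are exposed as `dpsi_inclusive`.

Multi-source designs (the human-style setting with heterogeneous
experiments) are expressed as *groupings* of *comparisons*. A grouping
calls an event when every comparison in it passes; a comparison may
pool replicate reads into a merged pseudo-sample (PSI and tier
recomputed from summed inclusion/exclusion reads); groupings that pair
loss-of-function with gain-of-function comparisons require the raw
ΔPSI values to point in opposite directions (equivalently, to agree
after orienting each comparison to loss-of-function). The combined
call set is the union over groupings, with provenance recorded.

Rescue rule: an event that failed the coverage gate, in a species where
its homologous exon cluster contains an exon called elsewhere, is
re-admitted iff exactly one sample is below VLOW and that sample still
has ≥ 2 supporting reads; it is then re-evaluated under the unchanged
ΔPSI cutoffs.

Alt5/Alt3/IR events use the same ΔPSI semantics as cassette exons
(inclusion of the alternative sequence); no type-specific thresholds.

## Differential expression

cRPKM = reads / (uniquely mappable positions / 10³) / (mapped reads /
10⁶). Filters, in order: cRPKM > 2 in both replicates of ≥ 1
condition; ≥ 50 raw reads in ≥ 1 sample; fold difference between
condition means ≥ `min_avg_fold` (default 2); fold difference ≥
`min_pairwise_fold` (default 1.5) for *all* cross-condition replicate
pairs in a consistent direction. Fold differences are symmetric
(max/min) with direction tracked separately; a pseudo-cRPKM floor of
0.01 guards ratios against zeros (config-exposed). Fold changes
compare means of per-replicate cRPKM, not pooled reads (the
alternative is a flag).

## Exon homology

Gene level: pairs supported by ≥ 2 of 3 evidence sources (OMA-like,
Multiparanoid-like cluster co-membership, BlastP-like reciprocal
top-3) are accepted; clusters are connected components. BlastP rank
ties at the third-best score are counted inclusively (deterministic).

Exon level: the longest isoform of each gene is globally aligned
(BLOSUM62, gap open 10, extend 0.5 — pinned defaults, config-exposed)
and each intron is projected to the alignment column of the residue
downstream of its junction, carrying its phase (coding nt 5′ of the
intron mod 3). For an alternative exon of species A against candidate
exons of species B:

* *similarity* = percent of alignment columns where both species have
  an in-exon, non-gap residue and the pair is identical or
  positively scoring under the matrix (identity-only mode available).
  Gap columns are excluded from the denominator — the "aligned
  columns" reading of an ambiguous definition; the full-exon-length
  alternative is not implemented at the pair level but governs the
  realignment tie-break below.
* *sequence clause*: alt-exon similarity > 20% and ≥ 1 flanking
  constitutive exon also > 20% (the same threshold reused, since no
  second threshold is defined for "significant" flank alignment).
* *structure clause*: both flanking intron markers exist in both
  species with identical phase within ≤ 3 alignment columns.
* verdict: `automatic` if both clauses hold; `manual_flag` if the
  sequence clause holds but the structure clause fails, or the introns
  are conserved but the alt-exon similarity is low; `none` otherwise.
  Flagged pairs go to a review file and can be whitelisted through an
  approvals file; the automated path never promotes them.
* when several B exons exceed 20%, the exon peptides are locally
  realigned and only the highest-similarity candidate keeps its
  verdict. The realignment score is normalised by the longer exon's
  length, so a short fortuitous overlap cannot outrank a full-length
  match (overlap-normalised scores saturate at 100% for 3-residue
  overlaps, which inverts the intended ranking).

Exon clusters are connected components over accepted pairs
(guilt-by-association); two distinct exons of one gene landing in one
component are flagged as conflicts, not merged away. liftOver-style
secondary rescue of unmatched exons is out of scope; externally
produced extra pairs can be injected through the accepted-pairs input.

A real-data caveat: exon indices for the structure clause are taken
over coding exons, which coincides with transcript exons here because
simulated genes are fully coding; genes with UTR-only exons would need
the CDS-relative index.

## Regulatory maps and target classification

Region schema per event (transcript orientation): 75 nt from the 5′
end of the upstream exon, 250 nt from each end of both flanking
introns, 75 nt from both alternative-exon ends, 75 nt from the 3′ end
of the downstream exon. Features shorter than the requested span are
*neglected* (dropped, never padded); the two segments of a 400-nt
intron overlap by 100 nt by construction. The flanking-exon segments
are the event-distal ends, implemented verbatim from the schema's
wording; a `junction_proximal_flanks` switch selects the
junction-proximal ends instead, since the verbatim reading may be a
transcription slip — it is a switch, not a silent correction.

Coverage profiles: exact hexamer matching (T/U equivalent, overlaps
included); per position, the fraction of a 51-nt window covered by any
motif, the window truncated at segment ends with the actual span as
denominator (no padding, so edges are not artificially suppressed);
averaged across events per segment, with contributor counts reported.
Positions with zero contributing events are absent, not zero.

Direct/indirect classification scans a fixed universe — the
alternative exon, the first and last 250 nt of both introns, the last
25 nt of the upstream exon, the first 25 nt of the downstream exon —
and counts motif *start positions* (overlaps included) in the allowed
regions of the direction and scenario:

* Restricted, silenced: alternative exon + first 6 nt of the
  downstream intron (the 5′ splice-site span) + last 250 nt of the
  upstream intron.
* Restricted, enhanced: first 250 nt of the downstream intron
  *excluding* that same 6-nt span (the two definitions partition the
  donor region consistently).
* Expanded adds: first 250 nt of the upstream intron (silenced);
  last 25 nt of the upstream exon, the scanned upstream intron minus
  its final 50 nt (3′ splice-site exclusion), and the last 250 nt of
  the downstream intron (enhanced). The upstream-intron clause is
  evaluated within the scan universe, which is where motifs are
  counted in the first place.

`direct` iff the summed count over allowed regions ≥ `min_motifs`
(1–4; sums across regions, not per region). `indirect` iff not direct
and zero motifs in the direction's giveaway regions (silenced:
upstream intron + alternative exon; enhanced: downstream intron + last
250 nt of the upstream intron). Everything else is `discarded`.
Region nesting guarantees restricted-direct ⇒ expanded-direct, and
raising `min_motifs` never turns an exon direct.

Shared-regulation enrichment uses a one-sided Fisher exact test
(direct vs indirect × shared vs not).

Conservation profiles: per exon, the score track over the exon ± 150
nt, smoothed by a 10-position *trailing* mean (the window anchor is
unstated upstream; a centred mode is available), then averaged across
exons anchored at the upstream-flank start with per-position
contributor counts — exons of unequal length simply stop contributing
beyond their extent.

## Synthetic data

The generator evolves `n_families` gene families along a labelled
newick species tree. Per family: 5–7 exons (constitutive 60–180 nt,
the focal cassette exon 60–150 nt rounded to codons), introns 300–700
nt, 100-nt outer flanks; one focal internal cassette exon per family.
Coding sequence is built from a random peptide through one canonical
codon per residue; per branch, each codon substitutes to a different
residue with probability `p_sub` (i.i.d., no indels inside exons — so
alignment-rule tests stay interpretable) and intron bases substitute
at the same rate. Exon gain/loss (`p_gain`, `p_loss`, default 0) is
frame-preserving and never touches the focal exon or its immediate
neighbours, keeping the focal event well-defined in every species.
Genes land on their own chromosome with a random strand, exercising
the orientation code end to end.

PSI model: control PSI of alternative exons ~ 100·Beta(2, 2);
constitutive homologs sit at 100. A fraction `frac_dependent`
(default 0.5) of focal exons respond to the factor with
|ΔPSI_true| = 30 (enhanced or silenced, 50/50); `frac_direct`
(default 0.6) of those are direct targets. Perturbed-condition true
PSI is shifted by −ΔPSI (enhanced) / +ΔPSI (silenced) for
loss-of-function, sign-flipped for gain-of-function, clamped to
[0, 100] with the effective shift recorded in the truth. By default
(`ensure_headroom`) the control PSI of dependent exons is
rejection-sampled so the loss-oriented shift fits without clamping —
the planted effect size is then exactly the stated one rather than
silently smaller; gain-of-function samples may still clamp. Observed
inclusion reads ~ Binomial(total, PSI/100) at expected depth 60
(constant by default; log-normal optional; beta-binomial
overdispersion via `overdispersion_rho`); tiers follow the read-count
mapping above.

Expression: per-gene level ~ LogNormal(ln-mean 5, sd 1) expected
reads — centred well above the 50-read detectability floor, as for
moderately expressed genes — with NB dispersion 0.1; `frac_de` = 0.2
of genes carry a 3-fold planted change. cRPKM normalisation uses a
nominal library size of 10⁶: the simulated families are a subsample of
a transcriptome, so the library total is an external constant, not the
sum of the table (which would be dominated by a handful of genes).

Motif planting edits genomes after family generation: direct targets
receive 2 non-overlapping motifs in a scenario-consistent region
(enhanced: downstream intron positions 6–244; silenced: alternative
exon or last 250 nt of the upstream intron); indirect targets have
every chance motif occurrence scrubbed from the scan universe by point
mutation, so "indirect" is true by construction, not merely likely.
Planting edits genomic sequence only; emitted protein isoforms
represent the coding simulation and are authoritative for homology.
Conservation tracks are moving-average-smoothed uniform noise in
[0, 1] — smooth and geometry-matched, carrying no biological signal.

What the generator does **not** emulate: indels and splice-site
evolution, overdispersed or correlated replicate noise by default,
paralogy and gene duplication, incomplete annotations, UTRs, biased
motif backgrounds (scrubbing makes indirect targets cleaner than real
indirect targets), or realistic conservation structure. Passing
recovery tests therefore demonstrates correctness of the decision
rules under their stated noise model — not expected performance on
real RNA-seq, where coverage, annotation and homology are all messier.

## Numerical and procedural choices

* PSI/read-count consistency tolerance: 0.05 PSI units (absorbs
  2-decimal printing).
* Exact tests via `scipy.stats` (`binomtest`, `fisher_exact`); both
  are verified against exhaustive enumeration in the test suite.
* Degenerate inputs: events with zero boundary reads fail IR gating;
  empty event classes yield absent (not zero) profiles; exons
  overrunning a score track are skipped and counted; all-zero Fisher
  tables return p = 1; genes with zero mappable length are rejected.
* Determinism: every generator is a pure function of (params, seed);
  run directories carry a manifest with SHA-256 checksums of all
  inputs and outputs, and repeated runs reproduce them bit-exactly.
* Problem sizes in the shipped tests (200-family homology recovery,
  ~600-event recovery studies, 1000-case oracle comparisons) were
  chosen to make the statistical assertions stable across seeds while
  keeping the default suite fast on one CPU.

## Known limitations

* Manual-review homology calls require an operator approvals file;
  the automated pipeline treats them as unpaired.
* The multi-candidate realignment resolves ties deterministically in
  candidate order.
* `combine_groupings` reports the grouping with the largest |ΔPSI| as
  the representative statistic; per-grouping statistics are not all
  retained in the output table.
* GO enrichment itself is external; only the cross-species selection
  rule on precomputed tables is implemented.
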