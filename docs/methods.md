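# Methods

## Enhancer calling

Inputs are interval calls of actively transcribed regions, one table per
cell line and replicate, each carrying an RPKM. Coordinates are BED-style
0-based half-open throughout.

**RPKM filter.** Replicate calls of a cell line over the same region are
averaged; a region is kept when the mean RPKM is ≥ 1 for cell lines with
replicates and ≥ 2 for those without. The stricter unreplicated cutoff
compensates for the missing averaging.

**Genic exclusion.** Calls overlapping any *exclusion zone* are removed
whole (subtractive, `intersect -v`-style; no truncation). Zones are the
gene body plus ±5 kb windows around both gene termini. The 5′/3′ "UTR
regions" are represented by their anchor coordinates (transcription start
and end); this anchor-based reading is a design choice — annotated UTR
intervals would differ only for genes with long annotated UTRs.

**Merging.** Filtered calls from all cell lines are merged
strand-agnostically (eRNA transcription is bidirectional) by transitive
closure of "edge distance ≤ 500 bp", boundary inclusive; overlap counts as
distance 0. Each catalog interval spans its component calls; per-cell-line
activity is the mean RPKM of that line's component calls, and absent lines
are recorded as inactive (NaN). Merging is idempotent and independent of
input order. Because the RPKM filter and genic exclusion are both per-call
predicates, their order does not change the catalog; the emitted averaged
RPKM follows the filter-then-exclude order.

**Classification.** An enhancer active in exactly one cell line is
*specific*, in all profiled lines *common*, otherwise *intermediate*.
"Active" means the line contributed at least one post-filter call — the
RPKM cutoff is the only activity threshold used.

**Conservation profiling.** Mean per-window score (e.g. phastCons) is
computed in 50 bp windows tiling each region center ± (half the mean
region length + 2.5 kb flank); bases absent from the track are excluded
from the means. The background is a count-matched set of regions of the
rounded mean enhancer length, sampled uniformly from chromosome space with
a recorded seed and no exclusions (pure uniform sampling is the simplest
defensible background; matched GC or gene-distance backgrounds are out of
scope).

## Enhancer–gene pairing

Candidates are all same-chromosome (enhancer, gene) pairs with
edge-to-edge distance ≤ 500 kb. An external pair list (GeneHancer-like)
can only add pairs (union semantics); its regions are matched to catalog
enhancers by overlap or nearest edge within 500 bp, ties to the leftmost
start. The same 500 bp rule maps external eRNA-profile entries onto
catalog enhancers when eRNA activity comes from a published profile
rather than the catalog's own calls.

Per cancer type and modality, Pearson r and its two-sided p (t
distribution with n − 2 df) are computed over pairwise-complete samples;
records with < 3 observations or a zero-variance vector are flagged
not-evaluable rather than silently scored, and a missing modality row
yields an explicit missing flag, never zeros. BH q-values are computed
within each (cancer type × modality) family — a global family would let
one cohort's p-value mass distort another's threshold. *Functional* means
q < 0.05 and |r| ≥ 0.3, applied per record; the magnitude gate is
sign-blind so methylation pairs (negative r) pass on |r|.

Gene-skip counts use the span between the enhancer's edge and the target's
nearest edge; a skipped gene is one whose whole body lies inside that
span. Differential expression uses Welch's t-test (the safe default when
the variance structure is unknown) with BH correction and a fold-change
gate (FC > 1.5, q < 0.05); cohorts with fewer than five normal samples
fall back to a pooled-normal mean comparison that is flagged descriptive
(fold change only, no test).

## Enhancer effect score

For gene set G in one cancer type,

    EES_s = (-log2 p_enrich) * sum_i RPKM_i(s) |Cor_max|_i / sum_i RPKM_i(s)

- p_enrich: hypergeometric upper-tail P(X ≥ k) for the overlap k between
  the cancer type's enhancer target genes and G, drawn from the analysis
  universe. The universe is the set of genes that entered the candidate
  screen with expression data — the pool targets could have come from.
  A floor of 1e−300 precedes the log so numerically zero p-values cannot
  produce infinite scores.
- |Cor_max|_i: the maximum of |r| over gene i's functional pairs, across
  enhancers and modalities, within the same cancer type by default (a
  pan-cancer maximum is available via `cor_max_per_gene(..., None)`).
- Set members with no functional pair have no defined Cor_max and are
  dropped from both sums; the enrichment term already penalizes sparse
  coverage. Treating them as zero-correlation members is available behind
  `include_unpaired=True`.

The weighted mean lies in [0, 1], so 0 ≤ EES ≤ −log₂(p_floor); the score
is invariant to rescaling any sample's RPKM vector and monotone in each
|Cor_max|. Samples whose weights all vanish are flagged rather than
scored. EES–infiltration correlations are reported per infiltration
column with raw p < 0.05 as the significance rule (no FDR), matching how
such per-cell-type panels are usually read.

## Modulator search

Samples are sorted by the candidate modulator's expression (stable sort,
ties broken by sample id for determinism); the bottom and top ⌊N/4⌋
samples form the low/high groups (count-based quartiles). The pair
correlation is recomputed in each group; Diffcor is reported both signed
(r_high − r_low) and absolute, and the |·| ≥ 0.5 rule flags candidates —
the magnitude form treats gain and loss of correlation symmetrically.
Groups need ≥ 3 complete observations (N ≥ 12) to be evaluable; the
split itself is defined from N ≥ 4. The scanned pair's target gene is
excluded, as are degenerate (all-tied) splits. Downstream motif and
protein-interaction screening of top candidates is out of scope.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not the biochemistry: no reads, no run-on chemistry, no HMM segmentation.

**Genome.** Genes (5–15 kb) are laid non-overlapping on evenly sized slots
per chromosome (default 4 × 10 Mb); an infeasible layout raises a capacity
error. Planted enhancers (0.8–2 kb) are placed in intergenic zones with
≥ 5.5 kb clearance from all exclusion zones and ≥ 1.6 kb spacing so
planted loci never merge, each anchored next to its paired gene so the
500 kb window always reaches the target.

**Calls.** Each planted enhancer is called (RPKM 2.5–8) in its designated
cell lines — by default a rotation of common / specific / intermediate
patterns. Noise calls cover the three failure modes, one per filter:
sub-threshold RPKM (mean 0.6 replicated, 1.5 unreplicated), genic-proximal
(2–3 kb from a gene terminus, inside the exclusion zone), and
"singleton" calls — genuine intergenic signal in one cell line that
correctly survives as an extra specific catalog entry. Cell lines
alternate replicated/unreplicated so both cutoffs are exercised; one
synthetic cell line corresponds to one synthetic cancer type.

**Cohort.** Correlations are planted through a shared standard-normal
latent: for a pair with target ρ, activity latent a and gene latent
ρ·a + √(1−ρ²)·ε. Emitted values are affine maps truncated to their
natural range — expression and ATAC/eRNA signal as max(0, 5 + z)
(truncation mass ≈ 3 × 10⁻⁷), methylation as clip(0.5 − 0.12·a, 0, 1) so
measured methylation correlations carry the expected negative sign. The
affine emission preserves the planted Pearson correlation on the emitted
scale exactly (up to truncation), which is what makes the recovery
tolerances in the tests meaningful; a log-normal emission was rejected
because exponentiation attenuates Pearson r by an amount that depends on
the latent variance. Requested |ρ| > 0.999 is rejected. Unplanted
enhancer–gene combinations share no latent and are null by construction.

**Modulators.** A gated pair's gene is rebuilt with a per-sample mixing
weight: cor_low in the modulator's bottom expression quartile, cor_high in
the top, their mean in between, so the within-quartile correlations
approach the configured gates as N grows.

**Immune set and infiltration.** The immune gene set alternates strong
(|r| = 0.9) and weak (|r| = 0.35) planted pairs; the strong members load
(λ = 0.8) on a shared immune factor f, making the expression-weighted EES
increase with f. Coupled infiltration columns are c·f + √(1−c²)·noise with
c = `infiltration_coupling`; the rest are independent. This yields a
positive EES–infiltration correlation whose strength is controlled by c.

All draws use seeded generators; a fixed seed gives byte-identical output
files. What passing tests show about real data is limited: the generator
has no batch effects, no heavy-tailed expression, no missing values, no
copy-number or purity confounding, and its noise levels are chosen for
plausibility (unit latent noise, RPKM ≈ 5 ± 1), not estimated from any
cohort. Recovery rates on synthetic data are therefore upper bounds on
what identical settings would achieve on real cohorts.

## Problem sizes and tolerances

The test suite and acceptance script use desk-scale studies chosen to make
the planted effects statistically decisive: the main screen uses 5 cancer
types × 200 samples with 30 planted pairs at |r| = 0.6 among ~600
candidate genes-within-window (planted-pair p ≈ 10⁻²⁰ at that n, so ≥ 90%
recovery is expected with room to spare); modulator recovery uses one
cohort of 2000 samples (quartile correlations then have SE ≈ 0.03,
against a ±0.1 tolerance on the planted gate difference of 0.8); the
EES–infiltration check uses 500 samples with coupling 0.8 and a
200-replicate null-column rate compared to a binomial 95% band around 5%.
Oracle-equivalence checks (merge vs union-find, exclusion vs all-pairs
scan, Pearson and BH vs direct formulas, hypergeometric vs exhaustive
enumeration on universes ≤ 12) are exact to 1e−12.
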