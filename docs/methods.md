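# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `haplocis`. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The allele-specific calling model

For a gene or accessible chromatin region (ACR) with per-SNP maternal /
paternal read counts (mᵢ, tᵢ−mᵢ), the caller proceeds in four steps.

1. **Null fitting.** The null distribution of maternal counts is
   beta-binomial, parameterized by the mean marginal probability of success
   π and the intra-class overdispersion ρ ∈ [0, 1):
   a = π(1−ρ)/ρ, b = (1−π)(1−ρ)/ρ, so Var(m) = tπ(1−π)(1+(t−1)ρ) and ρ→0
   recovers the binomial. (π̂, ρ̂) maximize the likelihood over WGS allelic
   counts restricted to the same feature class (gene spans for genes, peaks
   for ACRs). WGS reads have no true allelic signal, so π̂ absorbs
   reference-mapping bias — reads carrying the non-reference allele map
   slightly worse, pushing the null mean off 0.5 — and ρ̂ absorbs
   extra-binomial noise. The optimizer is Nelder–Mead over
   (logit π, logit ρ), started at the method-of-moments estimate; the
   moment estimates are always reported as an independent cross-check, and
   become the result (flagged) if the optimizer fails. Fitting needs ≥ 50
   observations.

2. **Per-SNP effects.** Each SNP's two-sided tail probability
   p = min(1, 2·min(P(X ≤ m), P(X ≥ m))) under BB(t; π̂, ρ̂), with ties at
   the observed count included in both tails, maps to a signed
   z = sign(m/t − π̂)·Φ⁻¹(1 − p/2). The transformation is exact for the
   test that follows because the null replicates pass through the same
   lookup; z is *not* claimed to be N(0,1) at finite depth.

3. **Pooling and significance.** Feature statistic Z = Σzᵢ/√n (Stouffer).
   Features with < 2 SNPs (after removing SNPs with < 10 reads) are
   untestable. Significance is a parametric bootstrap: n_sims replicates
   redraw mᵢ ~ BB(tᵢ; π̂, ρ̂) at the observed depths, recompute Z, and
   p = (#{|Z₀| ≥ |Z|} + 1)/(n_sims + 1), never zero. Per-feature random
   streams derive from the master seed and the feature's rank in sorted
   order, so results are independent of execution order. n_sims defaults
   to 10,000 (1,000 in fast-mode runs).

4. **Calls.** Benjamini–Hochberg within each replicate; a gene is called
   ASE iff q < α (default 0.05) in *every* replicate with agreeing log2FC
   sign; ACRs, with a single ATAC library, use the one-replicate rule.
   Replicate BH adjustment is separate, matching the consistency-across-
   replicates design; joint adjustment would be the alternative.

Descriptive effect size is log2((Σm + 1)/(Σ(t−m) + 1)); the pseudocount
keeps it finite and makes a fully balanced zero-count feature exactly 0.

## Ancestry within phase blocks

Haplotype labels are arbitrary between blocks. SNPs at which the two
parents are homozygous for alternate alleles (ancestry-informative,
~10% of heterozygous SNPs at realistic divergence) pin each block's
haplotypes to a parent. Classification per block, from the ordered hap1
ancestry vector of informative SNPs:

* no informative SNPs → unclassified (nothing imputed);
* unanimous → non-recombinant; all SNPs inherit the haplotype ancestry;
* majority ≥ threshold (default 0.75) → discordant minority filtered
  (treated as phasing errors), block non-recombinant. Exact ties never
  filter — a majority is not fabricated;
* below threshold with 2 ancestry runs → recombinant: one true ancestry
  change along the block; only informative SNPs keep labels, since
  imputation cannot know where the crossover falls between them;
* ≥ 3 runs → excluded_switching: repeated haplotype switching indicates a
  phasing failure and the block is dropped from ancestry-dependent output.

SV ancestry: in non-recombinant blocks the SV's haplotype inherits the
block ancestry; in recombinant blocks a majority vote over the ≤ 5 nearest
labeled SNPs on each side of the SV midpoint decides, ties → unknown. The
midpoint anchor is a choice; any fixed anchor gives the same answer except
for SVs comparable in size to the inter-SNP spacing.

Switch errors are quantified per haplotype as discordant SNPs / evaluable
SNPs against an independent label source (simulation truth, or parental
homozygous SNPs), over blocks contributing ≥ 2 jointly labeled SNPs; a
lone SNP carries no phase information and is skipped. This per-SNP flip
rate matches the generator's error model (below) and is exactly binomial,
which gives it clean confidence intervals.

## The factor matrix and elastic nets

56 chromatin factors = 7 data types (ATAC, H3K4me3, H3K36me3, H3K56ac,
H3K27me3, DNA methylation, WGS coverage) × 4 gene-relative regions ×
{overall level, allelic log2(maternal/paternal)}; appended covariates are
maternal/paternal promoter-deletion indicators and dN/dS (supplied as an
input column — computing it from alignments is out of scope). Regions:
genic = the annotated span (exons and introns); promoter = [TSS−1 kb, TSS)
strictly, strand-mirrored; upstream/downstream regulatory regions = the
ACR intervals within 5 kb of the promoter's far edge / the gene end,
*absent* when no ACR lies in the window; all intervals clipped to the
chromosome. Missingness rules, in fixed order: the per-SNP coverage filter
runs first; an allelic cell is NA when its region has no phased SNP or its
SNP read total falls below the 10th percentile of that factor × region
(computed over genes that have the cell at all); genes whose genic WGS
allelic log-ratio lies beyond 1.5× IQR are dropped entirely as mapping
artifacts. Missing is encoded NA, never 0. The matrix sidecar reports the
median per-gene missing fraction; on the default simulation it is
dominated by genes lacking regulatory-window ACRs, and is reported, not
asserted.

The elastic net grid-searches the mixing parameter α ∈ {0.1, …, 1.0} and a
100-point geometric λ path (λ_max from the standardized working matrix at
the smallest mix, down 3 decades) with 5-fold CV. Standardization and mean
imputation (zero on the standardized scale) are computed inside each
training fold — no leakage; rows are sorted by gene id before fold
assignment so row order cannot change the fit. Mean imputation is unbiased
under ignorable missingness; missingness-indicator columns are a possible
extension, off by default. λ_1SE is the largest λ whose CV MSE is within
one standard error (over folds) of the minimum; the reduced model's
support can only shrink. R is the Pearson correlation of predicted vs
observed; in-sample and cross-validated R are both reported because they
answer different questions, and the CV variant is the honest one for
generalization.

## Permutation engines

All permutation p-values use the +1/+1 estimator and are one-sided for
enrichment; depletion appears as fold < 1, reported descriptively.

* **TE overlap.** Null sets are drawn from the universe of ACRs by greedy
  nearest-length matching without replacement in random visit order; this
  preserves the query's total length within a few percent per draw, so the
  null controls for region size. TE classes filter by RepeatMasker-style
  prefix ("DNA", "LTR", or full "Class/Family" strings).
* **SV-in-promoter.** The statistic is the number of ASE-gene promoters
  overlapping ≥ 1 deletion; nulls draw equally many genes from the
  ASE-*testable* set, which is the correct exchangeable universe.
* **Trait SNPs in ACRs.** Query = SNPs below Bonferroni (0.05 / #SNPs).
  Background bins are MAF deciles × distance-to-nearest-gene quintiles
  with edges from the background distribution; each permutation redraws
  the query's bin profile from the background pools. Query SNPs in empty
  bins are reported unmatched; > 20% unmatched aborts with diagnostics.
  An empty query returns a typed no-query result rather than crashing.
* **Hedges' G label permutation** for the promoter-deletion effect:
  g = (x̄_a − x̄_b)/s_pooled · J with J = 1 − 3/(4(n_a+n_b) − 9); the
  permuted statistic is g itself.

LD blocks: r² is the squared Pearson correlation of 0/1/2 dosages
(pairwise-complete over missing) within ±1 Mb of a lead SNP; the block is
the [min, max] position of SNPs with r² > 0.8. SV genotypes from insertion
allele frequency: [0.25, 0.75] → heterozygous, > 0.95 → homozygous
insertion, < 0.25 with supporting reads → homozygous reference, the
(0.75, 0.95] gap → no-call.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
reads or sequence. Defaults describe a desk-scale heterozygous genome:
3 chromosomes × 2 Mb, 300 genes (1–4 kb), 400 ACRs (0.5–2 kb), 45 phase
blocks (~130 kb), 4 SNPs/kb, 10% ancestry-informative SNPs, 500 deletions
with log-normal lengths (mean 332 bp, clipped to 41–11,084 bp), TEs tiling
~30% of the genome with 2× odds of SV overlap, and 154 accessions for the
genotype matrix. Per-SNP depth is negative-binomial (mean 60, dispersion
0.3), chosen so both sides of the 10-read filter occur; maternal counts
are beta-binomial with logit(π) = logit(π_ref) + ln2·log2FC for SNPs in
features with a true effect. WGS always draws at π_ref — it is the
mapping-bias calibration track. 30% of genes carry a true |log2FC| in
[0.5, 2]; ACRs and histone marks near an imbalanced gene couple to it at
0.8× (H3K27me3 with opposite sign); a promoter deletion boosts the
deletion-carrying allele by 0.5 log2 units. Two RNA replicates share true
effects with independent counting noise, because calls require
cross-replicate consistency. Overall expression satisfies
log2TPM = 4 + Σ coef·z + N(0, 0.5²) over latent standardized region
factors (ATAC/H3K4me3/H3K36me3/H3K56ac genic positive, H3K27me3 genic and
promoter methylation negative), which are also emitted as the
region-coverage table.

Switch errors are isolated single-SNP label flips at the configured
per-SNP rate — the dominant error mode of read-backed phasing, and the
only i.i.d. model under which the block classification stays mostly clean
at a ~3% error rate while the estimated rate is exactly binomial.
Long-range switches exist in real data but are far rarer; a block
dominated by them lands in excluded_switching, which is the desired
behavior.

Trait SNPs: significant GWAS SNPs are placed inside ACRs with probability
fold × (genomic ACR fraction), i.e. the injected "fold" is a ratio of
in-ACR fractions, which is what the matched-background estimator measures;
non-significant p-values are uniform above the Bonferroni cut and MAF ≥
0.03. Genotype dosages follow a latent-uniform copying process so r²
decays with distance (~50 kb scale). The methylation table injects
differential sites at rate 0.05 with a 0.5 methylation-fraction gap, at
coverage straddling the ≥ 10 filter.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (the mapping bias here is a
clean global π shift, not locus-specific), LD between heterozygous sites
and assay counts, correlated noise across assays from shared library
effects, genuine TE biology in AS-ACR placement, isoform-level effects,
and any sequence content. Coverage distributions for the assays are free
parameters of the emulation.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF3 is converted at the
  file boundary, distances are edge-to-edge gaps (0 when touching).
* "Nearest" ties break toward the smaller feature id, deterministically.
* ρ < 1e-12 switches the beta-binomial to its binomial limit to avoid
  overflow in the Beta parameters.
* The probability of differential methylation is operationalized as
  1 − p of a one-sided Fisher exact test sided toward the observed
  difference, with calls requiring combined coverage ≥ 10 and probability
  ≥ 0.7; sites with zero coverage on a haplotype are skipped.
* Degenerate cases return typed results, not crashes: empty queries,
  monomorphic LD leads, < 3 ACR:gene pairs (correlation undefined), zero
  pooled variance (Hedges' G undefined), constant elastic-net response
  (error), all-NA factor columns (dropped with a warning).
* Master seed → per-stage seeds via a CRC of the stage name; adding a
  stage never perturbs another stage's stream. Per-feature bootstrap
  streams spawn from the feature's sorted rank.

## Problem sizes

Tests and the acceptance script run at the sizes the statistics need, not
larger: null calibration at 2,000 features × 1,000 bootstrap replicates;
beta-binomial recovery at 2,000 SNPs per grid point; elastic-net recovery
at 1,900 genes × 56 factors; enrichment calibration at 200 seeds ×
199 permutations and fold recovery at 500 query SNPs × 1,000 permutations;
the end-to-end pipeline at the default 300-gene study. The full suite
completes in a few minutes on one CPU.

## Known limitations

* The per-SNP "effect size" is the signed z from the beta-binomial tail;
  other allele-specific callers print unitless effect sizes on different
  scales, so magnitudes are not directly comparable across tools.
* Separate-per-replicate BH adjustment plus the consistency rule is
  conservative relative to a joint hierarchical model.
* Mean imputation in the elastic net attenuates coefficients when
  missingness correlates with the response (non-ignorable missingness).
* The matched-background enrichment can be residually confounded when the
  injected signal correlates with the matching covariates inside bins;
  bin counts (10 × 5) trade resolution against empty-bin rates.
* The discordance threshold (0.75) and the tie rule in block
  classification are design choices worth a sensitivity analysis on real
  data; both are exposed as parameters.
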