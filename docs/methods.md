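# Methods

This note documents the models, statistics, and design choices behind
`crelink`, what the synthetic data generator does and does not emulate, and
the numerical conventions used throughout.

## Candidate causal variants

A locus's credible set is the lead variant plus every variant passing either
rule against the lead:

* **Likelihood-ratio rule.** Two-sided p-values are converted to 1-df
  chi-square statistics; the variant's likelihood relative to the lead is
  `exp((χ²_v − χ²_lead)/2)`, and variants with ratio ≥ 1e-3 (the 1:1000
  convention) are kept. This is the standard approximate credible-set
  construction when only p-values are available.
* **LD rule.** R² to the lead above 0.8. Ties at the threshold are resolved
  inclusively after rounding R² to six decimals, so a reported "0.800000"
  enters the set deterministically.

Studies that publish only LD proxies use the R² rule alone; independent
conditional signals without proxies enter as singletons. Loci are merged
when their CCV footprints (the [min, max] span of member positions) overlap
by any base pair, and variants are deduplicated by (chrom, pos, ref, alt).

## Peak annotation and specificity

Annotation precedence is promoter > exonic > intronic > intergenic with a
promoter window of TSS ± 3,000 bp (strand-aware TSS). Variant positions are
1-based and peaks 0-based half-open; a variant at position *p* overlaps a
peak iff `start < p ≤ end`, with the conversion applied exactly once at the
boundary.

The quartile specificity rule: a peak detected in a single cell type is
assigned to it; a peak whose detected types all share one category is
assigned to that category; otherwise category *c* is assigned iff the
detected count strictly exceeds `0.75 · n_c` (with the default taxonomy:
epithelial > 6 of 8, immune > 5.25 of 7, endothelial and stromal > 3 of 4),
with multiple categories allowed when several pass. A per-category
"depleted" flag records counts strictly below the 25th percentile; it is
informational only and plays no role in assignment, because the only
worked case that pins the rule's semantics uses the 75th percentile alone.
Locus-level category calls use unanimity over the locus's CCV-colocalized
cCREs (configurable to majority): any disagreement yields "mixed".

## Allelic TF analysis

**Scoring.** Position *i*, base *b* contributes `ic_i · log2(p_i(b)/bg_b)`
where `ic_i` is the position's information content in bits; N bases score as
the background-frequency average. A sequence's score is min–max scaled
against the motif's extreme attainable scores, so the consensus scores
exactly 1 and the anti-consensus exactly 0. The best match for an allele is
the maximum over both strands and all placements covering the variant.
The allelic comparison scores *both alleles at the same placement* — the
strand/offset whose better allele attains the overall best match — so the
delta measures disruption of one binding site rather than a shift to an
unrelated match elsewhere in the window. The 0.7 delta threshold applies to
the scaled [0, 1] scores, the convention of scaled-score motif-disruption
tools.

**Match p-values** are exact for a quantized score: per-position scores are
rounded on a lattice of 1e-4 of the motif's score range, and the full
distribution of the quantized score under the background model is obtained
by dynamic programming (per-position convolution). For motifs of length ≤ 8
the distribution is verified against exhaustive enumeration of all k-mers.
Reported relative scores and deltas use full precision; only the p-value is
defined on the lattice.

**Abundance.** A candidate (TF, cell type) pair is "abundant" iff the TF is
expressed in more than half of the type's cells and its mean expression
there exceeds the 75th percentile of mean expression over all candidate
pairs (strictly, so a constant expression landscape yields no abundant
pairs). TFs without a gene mapping are reported, never silently dropped.

**Footprinting.** Observed insertion counts summed over motif sites and the
expected sequence-bias track are each normalized to mean 1 over the outer
flanks (200–250 bp from the motif centre); the corrected profile is their
pointwise difference. The footprint statistic is the mean corrected signal
over the 50 bp bands flanking the motif core minus the mean over the core,
so TF protection makes it positive. Significance is a one-sided z-test at
α = 0.05 with a site-level bootstrap standard error (multinomial resampling
of sites, 200 replicates). This replaces by-eye assessment of
flanking-region enrichment with an explicit, calibrated statistic: on
bias-only tracks with 200 sites the false-positive rate is at or below the
nominal 5 %, and a planted 40 % core depletion is detected essentially
always (its statistic concentrates near 0.4, the depletion times the unit
flank level).

## Co-accessibility, links, and tiers

**Metacells.** Sparse per-cell accessibility is summed over k-nearest-
neighbor neighborhoods (k = 10 by default; the neighborhood includes the
anchor, so k = 1 is the identity) on an LSI embedding (TF-IDF + truncated
SVD, first depth-correlated component dropped). Anchors are visited in
random order and accepted only if the neighborhood shares at most 10 % of
its members with every accepted metacell; ~2,000 cells yield ~200 metacells.
One contract note: the operation rejects k < 1 but accepts k = 1, since the
identity aggregation is well defined and useful in tests.

**Co-accessibility.** Within 500 kb sliding windows (250 kb step), the
correlation matrix of log1p metacell profiles is fed to a graphical lasso
with an elementwise penalty `0.1 + (d/window)²` growing with genomic
distance *d*; the score of a peak pair is the partial correlation implied by
the estimated precision matrix, averaged over the windows containing it.
The block-coordinate-descent solver accepts an arbitrary penalty matrix
(scalar-penalty implementations cannot express the distance schedule) and is
numba-accelerated. Modules are Louvain communities (seeded, deterministic;
ties broken by lowest member id) of the graph thresholded at 0.32;
singletons are discarded; "directly co-accessible" pairs are edges above
0.5. On independent peaks with 200 metacells, 99 % of in-range pairs score
below 0.1 in magnitude.

A structural caveat worth recording: partial correlations inside an
equicorrelated block of p peaks cannot exceed 1/(p−1) regardless of how
strong the common factor is (0.25 for five peaks), so "module" evidence is
inherently chain-like — strong scores concentrate on conditionally adjacent
pairs, and communities assemble from those chains. The synthetic module
generator reflects this (see below).

**Peak–gene links.** For each gene, candidate peaks lie within ±1 Mb of the
TSS and are detected in ≥ 10 cells; Pearson correlation between log-
normalized accessibility and expression is z-scored against the r-values of
200 background peaks nearest in the standardized (GC, mean accessibility,
width) space, with a one-sided normal p. Links are retained at p < 0.05 and
|r| > 0.05. Features constant in raw counts are excluded (per-cell
normalization would otherwise make them vary with depth) and logged. Under a
null with no planted structure the empirical type-I error at p < 0.05 is
0.05 within Monte-Carlo error.

**Tiers.** For a variant-bearing cCRE *e* and each gene *g* within ±1 Mb:
level 1 — *e*'s module contains a promoter cCRE of *g*; level 2 — *e* is
directly co-accessible (> 0.5) with a promoter cCRE of *g*; level 3 — *e*
is itself annotated as *g*'s promoter; level 4 — *e*'s module contains a
cCRE linked to *g*; level 5 — *e* is directly co-accessible with a cCRE
linked to *g*; level 6 — *e* itself is linked to *g*. For the indirect
levels (1/2/4/5) the partner cCRE must differ from *e*: a promoter cCRE does
not grant itself levels 1–2 (level 3 covers that case) and an expression-
linked cCRE does not grant itself levels 4–5 (level 6 covers it). The
toy-enumeration test freezes these conventions.

## Trait relevance scores

Flat per-locus variant weights (1/m for each of a locus's m CCVs) are summed
into peak weights. Per-cell deviations follow the chromVAR recipe
(observed weighted counts minus the depth expectation `cell_total ·
peak_total / grand_total`), z-scored against 50 background weight vectors
that reassign each weighted peak's weight within equal-frequency bins over
(GC, mean accessibility) (~50 bins on a 7×7 quantile grid). The top 5 % of
cells by z seed a random walk with restart (restart probability 0.05,
L1 tolerance 1e-6) on a mutual kNN graph (k = 30) over the LSI embedding;
walk mass is renormalized each step so isolated nodes cannot absorb it.
Final scores are min–max scaled onto [0, max]; the propagated scores live in
walk-probability units, so only orderings and group contrasts — not absolute
magnitudes — are meaningful, and the package reports group means and ranks.

## Reporter (MPRA) statistics

Per variant, activity ratios (RNA TPM / DNA TPM over 25 tags × 5
transfection batches per allele/strand) are fit by OLS as
`Ratio = Allele + Strand + Batch`; tags enter only as rows (fixed-effects
formula, no random effect). The allele coefficient is tested by a two-sided
Wald test under an HC0 sandwich covariance (HC1–HC3 available), and
p-values are Benjamini–Hochberg corrected across variants. Rank-deficient
designs (e.g. allele confounded with batch) raise an identifiability error
rather than returning an arbitrary solution.

## The synthetic multiome

Defaults emulate the study conditions: 23 cell types in 4 categories
(8 epithelial, 7 immune, 4 endothelial, 4 stromal), 87 cells per type
(~2,000 cells), 400 peaks at 5 kb spacing on one synthetic chromosome,
60 genes, ~35 % cell-type-private peaks plus ~25 % category-restricted ones
(matching the observation that roughly a third of peaks are single-type).

* **ATAC counts** are Bernoulli × Poisson per peak × cell with a per-cell
  log-normal depth factor: a peak is open with a probability set by its
  detection pattern (uniform 0.15–0.5 base rate where detected, hard zero
  elsewhere) and open events receive Poisson counts (mean 1.5 × depth).
* **RNA counts** are negative binomial (dispersion 10) with cell-type-
  specific log-normal means.
* **Planted links** (default loading 0.5) share a standard-normal latent
  factor between the gene's NB log-mean and the peak's accessibility
  propensity. Sparse accessibility is nearly binary after normalization, so
  the latent acts on the open-probability logit as well as the Poisson
  log-mean; a link whose peak anchors a planted module uses the module's
  root factor as its latent — the module's co-activity drives the gene,
  which is also what makes module partners carry level-4 evidence.
* **Planted modules** (default: three 3-peak modules whose first members are
  the link peaks) modulate member open-probabilities with a chained latent
  (adjacent correlation 0.9, logit scale 4.0). The chain, rather than a
  single shared factor, is deliberate: it produces the conditionally
  adjacent structure that partial-correlation scores can actually exceed the
  0.32 module threshold on (see the equicorrelation ceiling above).
* **LD blocks** use a first-order Markov copying process over haplotypes
  (copy probability `exp(−decay · distance_kb)`, default decay 0.05/kb over
  50 variants, 500 diploid individuals); R² is the squared Pearson
  correlation of genotype dosages. Association p-values come from marginal
  regressions of a phenotype with a planted effect (0.5 standardized) at the
  lead; the noise substream is re-drawn (bounded, deterministic given the
  seed) until the lead attains the minimum p, so each block is a well-formed
  single-signal locus.
* **Motif scenes** plant a PWM with one near-deterministic core position
  (probability 0.997, where the variant falls) and weakly informative flanks
  (0.6): the only shape under which a single-base change can move the
  min–max-scaled score by more than 0.7 while the full match stays rare
  (match p ≈ 1.5e-5) under the background model.
* **Footprint tracks** draw per-site Poisson insertions under a smooth
  multiplicative sequence bias shared across sites, with the motif-core rate
  reduced by the configured depletion; the bias track is emitted alongside
  as the correction input.
* **Reporter tables** shift the alternate allele's mean ratio by the
  configured effect with strand and batch nuisance shifts (SD 0.2) and
  residual noise (SD 0.3).

Seeding: one integer seed fans out to named child streams per component
(keyed by CRC32 of the stream name), so adding a component never perturbs
the draws of the others, and identical configs give byte-identical outputs.

**What the generator does not emulate:** read-level sequencing artifacts,
doublets and ambient contamination, batch effects, realistic gene-gene
covariance, genome-wide LD beyond a single block, or the empirical
distributions of real peak widths and GC content. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery on
data satisfying the model's assumptions — not robustness to the failure
modes of real multiome data. The null configuration used for link-test
calibration removes cell-type co-structure (all peaks shared); with
cell-type structure present, peak–gene correlations through shared cell-type
identity are real dependencies, not type-I errors.

## Problem sizes and numerical conventions

Test and acceptance runs use the default ~2,000-cell study (10 seeds for
recovery rates), a ~1,000-cell / 500-peak / 50-gene null for calibration,
200 simulations for footprint calibration and power, 500 for the reporter
null, and 20 seeds for TRS ranking — sizes at which every Monte-Carlo
tolerance in the suite is resolvable in a few minutes on one CPU. The
graphical lasso converges at mean absolute change 1e-4 (relative to mean
|S|) with inner coordinate-descent tolerance 1e-6; the RWR converges at L1
1e-6; degenerate inputs (zero-variance features, empty backgrounds,
monomorphic variants) are skipped and logged or raise typed errors, as
documented per function.

## Known limitations

* Tier-6 gene sets include the expected ~5 % chance links among cis genes;
  the planted genes are guaranteed (by the recovery tests) to be present,
  not to be alone.
* Printed group-level TRS magnitudes from real studies are not reproducible
  from synthetic data; only orderings are asserted.
* The co-accessibility solver scores pairs only within the sliding-window
  span (500 kb); cross-window long-range co-accessibility is out of reach by
  construction.
* The footprint bias model is a supplied expected-insertion track; k-mer
  bias estimation from a genome is out of scope.
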