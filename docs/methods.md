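# Methods

This note documents the statistical model, the numerical choices, and
what the synthetic studies do and do not establish.

## LD-weighted annotation scores

Membership of a SNP in an annotation is a poor proxy for whether the
SNP *tags* association signal inside it, so per-SNP affiliation scores
are LD-weighted: score_i = Σ_j δ_j r²_ij over reference-panel SNPs j on
the same chromosome with |pos_i − pos_j| ≤ 1 Mb, where r² is the
squared Pearson correlation of genotype dosages, values below 0.2 are
set to zero, and every SNP carries r² = 1 with itself.  TotLD is the
same sum with δ ≡ 1 and uses the same floor ("the same procedure" read
literally).  Consequences used as invariants throughout the tests:
TotLD ≥ 1, TotLD ≥ score for every category, an isolated SNP scores
exactly its raw 0/1 indicator, and with the floor raised above 1 every
score collapses to its raw indicator.

Conventions. SNP positions are 1-based; BED intervals 0-based
half-open; a SNP at 1-based q is inside [s, e) iff s < q ≤ e.  The
"within 1 Mb" window is read as a ±1 Mb flank (window_bp is
configurable for the ±500 kb reading).  r² is the composite genotype
correlation, not a phased-haplotype estimator.  The 100 kb
gene-proximity rule of the intergenic definition is measured from
interval boundaries by interval expansion (distance 0 inside).

Knife-edge floor pairs: with integer dosages r² can land exactly on
0.2, where last-ulp rounding legitimately differs between computation
orders.  The oracle tests bracket the floor at ±1e-9 and require exact
agreement away from the bracket; such pairs are rare (< 0.1% of
entries) and shift any single score by at most one floored r².

## Intergenic SNPs and λ_GC

Intergenic SNPs have exon/intron/5'UTR/3'UTR scores exactly zero and no
neighborhood partner (self included) within 100 kb of a protein-coding
gene or inside ncRNA/TFBS/miRNA-binding-site tracks.  λ_GC = median
over 100 LD-pruning iterations of the pruned set's median z², divided
by the χ²₁ median (computed at runtime from the inverse CDF, not
hard-coded).  Pruning is greedy over a seeded random visiting order; a
SNP is kept iff its r² with every kept SNP is below the threshold.  The
pruning r² threshold defaults to 0.2 — the only LD threshold the method
defines — and the aggregation is the median of per-iteration medians
(robust and symmetric; pooling is a config alternative).  Within the
implementation the isolated/contested split of the pruning graph is a
property of the graph, not of the visiting order, so it is computed
once per λ estimate and only the greedy sweep over contested SNPs is
repeated; results are identical to the reference single-call path.

Whether downstream analyses use raw or GC-corrected z² is a
configuration choice and is **off** by default: the estimation
procedure is well defined, but applying the correction everywhere is a
separate modelling commitment.  `apply_gc` divides z² by λ and
recomputes p (optionally never inflating when λ ≤ 1).

Important caveat, visible in the README example: under a polygenic
architecture intergenic SNPs still tag causal signal through LD, so
λ_GC > 1 does not imply confounding.  The calibration claims below are
therefore made under a *signal-free* generator.

## Fold-enrichment curves

SNPs are stratified at affiliation score 1 (the isolated-in-region
score).  The "cumulative distribution" is implemented as the
upper-tail exceedance fraction of −log10(p): fold(x) =
S_stratum(x)/S_all(x) with S(x) = fraction of the set with −log10 p ≥
x, ties included by ≥.  A lower-tail CDF would flatten to 1 exactly
where enrichment lives, contradicting the intended "positive deflection
above 1" reading, so exceedance is the implemented orientation.  SNPs
at or beyond genome-wide significance (−log10 p ≥ 7.3) are removed
before the curves are formed.  Exact identities: fold ≡ 1 when the
stratum is everything; w·fold_in + (1−w)·fold_out = 1 with w the
stratum fraction.  The default grid is 200 equally spaced points on
[0, 7.3).

## PLSR of squared z-scores

The descriptor block X holds the per-SNP scores in the order intron,
exon, 3'UTR, 5'UTR, evolutionary category, brain, TotLD; the response y
is the squared z-score.  Both are mean-centered and scaled to unit
standard deviation.  The fit is single-response NIPALS: each latent
variable maximizes descriptor–response covariance, X is deflated, and
coefficients are mapped back via b = W(PᵀW)⁻¹q.  The model order A is
the smallest number of latent variables whose cumulative
descriptor-block variance explained exceeds 0.99 (capped at the number
of covariates).  At full order on a full-rank design PLSR equals OLS,
which the tests verify against a normal-equations solve and against an
independent PLS implementation.  Coefficients are reported on the
standardized scale (the "non-centered standardized" convention of
published enrichment tables, read as: coefficients of centered+scaled
variables without re-added intercepts); a raw-scale back-transform is
exposed as `coefficients_raw`.

### Jackknife inference

SNPs are partitioned into 50 folds along LD blocks — connected
components of the floored-r² graph, the weakest faithful reading of
"the LD matrix was used for partitioning" that prevents leakage —
dealt whole to folds round-robin in seeded shuffled order.  For each
fold the model is refit (same A, refit data re-centered) with the fold
held out; the jackknife variance per covariate is ((k−1)/k)·Σ_f(b_(−f)
− b̄)², t = b_full/sd, two-sided p from t with k−1 = 49 degrees of
freedom.  A refit spread of exactly zero yields the documented sentinel
t = ±∞, p = 0.  Fold relabeling leaves the sd unchanged.

Leverage caveat: the jackknife t is approximately calibrated only when
the covariate's leverage is spread over many folds.  For very sparse
annotations (a few hundred scoring SNPs concentrated in a handful of LD
blocks — the HAR-like regime) the t statistic is visibly overdispersed
and p-values should be read qualitatively; the synthetic calibration
study therefore uses the SD-like annotation, whose genome fraction
(~5%) spreads leverage adequately.

### Residual-vs-TotLD summaries

Squared z-scores are residualized on a PLSR model without TotLD (and
optionally without the evolutionary score), TotLD is cut into
equal-count bins, and mean residual z² is reported per bin for the
category / non-category / all strata, on the raw z² scale.

## MHC reruns

The analyses repeat with SNPs in chr6:25,652,429–33,421,466 (hg19,
bounds inclusive) excluded, and with only those SNPs.  In degenerate
subsets (constant covariates, too few LD blocks for 50 folds) the
pipeline logs and emits NaN rows rather than aborting; the fold count
is reduced to the block count when necessary.

## Matched control sets

Matching replicates the joint (MAF, TotLD) distribution of the SNPs
physically inside an annotation: MAF in 25 equal-width bins on
(0, 0.5], TotLD in deciles of the pooled distribution (quantiles adapt
to TotLD's heavy tail), exact per-cell counts, sets disjoint from the
source.  Without replacement an undersupplied cell is an error listing
the deficient cells; with replacement an *empty* pool cell borrows the
nearest nonempty cell in bin space (sampling cannot conjure SNPs from
nothing).  The envelope across sets is the pointwise median and
2.5/97.5 percentiles of the fold curves.

## Synthetic data generator

The generator emulates the structure the method assumes, not human
demography:

- **Panel.**  Haplotypes are blockwise: all sites in a block copy a
  shared Bernoulli(p_b) haplotype and flip independently at a rate
  solved (by bisection) so that the pairwise dosage r² matches the
  target — the naive (1−2ε)⁴ formula ignores that flips shift the
  allele frequency and badly undershoots at low MAF.  Block MAFs are
  log-uniform on (0.01, 0.5); block extents follow a renewal process
  with 50 kb mean; blocks are independent, so LD is exactly
  block-diagonal and the brute-force oracle and LD-fold construction
  are exact.  Monomorphic sites are repaired by a single haplotype
  flip.
- **Tracks.**  Non-overlapping gene models whose 5'UTR/exon/intron/
  3'UTR parts tile the gene body exactly; brain-gene and ohnolog-like
  subsets of gene bodies; short HAR-like intervals (3/Mb × 400 bp — the
  realistically tiny HAR genome fraction); SD-like intervals at 1.2/Mb
  × ~40 kb (~5% genome fraction, the accepted figure for human
  segmental duplications; sparse SD settings concentrate jackknife
  leverage and visibly miscalibrate the t-test, which is a property of
  the method worth knowing about, not a bug); sparse ncRNA/TFBS/miRNA
  tracks; one contiguous MHC-like region (middle 12% of chromosome "6")
  with 3× gene density.
- **Summary statistics.**  β_j ~ N(0, base_h2_per_snp + Σ_c τ_c a_jc)
  with a_jc the raw indicator; z = √n·Rβ + ε, ε ~ N(0, inflation·R)
  blockwise with R the empirical dosage correlation (jittered Cholesky
  for near-singular blocks).  τ is on the causal-variance scale: a
  planted annotation adds ≈ n_gwas·τ per unit LD-weighted burden to
  expected z².  Defaults: 20,000 SNPs on two 50 Mb chromosomes, 100
  panel samples, n_gwas = 50,000, base_h2_per_snp = 1e-5 (mean z² ≈
  2.5 at typical TotLD, a realistically polygenic GWAS), no planted τ,
  no inflation.  Everything is deterministic per seed and the planted
  truth is written alongside the data.

What the generator does **not** emulate: realistic recombination maps
and inter-block LD, allele-frequency–dependent effect sizes,
imputation error, strand issues, population structure beyond a scalar
inflation.  Passing tests therefore establish the machinery's
correctness and the inferential calibration under block LD — not
performance guarantees on real cohorts.

## Study conditions used by the acceptance checks

- LD-scoring oracle: 20 panels of 300 variants, 50 samples, two 1.5 Mb
  chromosomes (small enough for an all-pairs double loop).
- λ_GC calibration: 55,000 LD-free SNPs on one 275 Mb chromosome with
  near-empty annotation (≥ 50,000 intergenic), signal-free; 20
  z-replicates per inflation setting sharing the panel (the panel is
  ancillary to λ; z is what varies).
- Jackknife calibration/power: the default 20,000-SNP block-LD study;
  200 signal-free replicates for type-I error (base_h2 = 0, so the
  "coefficient = 0" null holds exactly; with a polygenic baseline the
  floored TotLD covariate cannot perfectly absorb the unfloored r²
  signal aggregation and the partial null is only approximate), 50
  replicates with τ_SD = 2e-4 — twenty times the polygenic baseline,
  the stated "strong effect" condition — for power and sign recovery.
- Matched controls: 30 sets matched to the raw SD SNPs; envelope
  coverage assessed over 20 signal-free z-replicates.

## Known limitations

- Dense per-chromosome correlation is computed in windowed chunks;
  biobank-scale panels (millions of variants × thousands of samples)
  would need a streamed implementation.
- The jackknife t for very sparse annotations is overdispersed (see
  above); a block bootstrap would be the next step.
- INDELs and multi-allelic sites are skipped; no liftover or
  imputation; strand-ambiguous alleles are kept by default and should
  be dropped (`drop_ambiguous`) for real multi-platform data.
- p = 0 rows are dropped (visible in the read log) rather than floored
  unless a floor is requested.
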