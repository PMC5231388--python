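# evoenrich

Covariate-modulated polygenic enrichment of GWAS associations in
evolutionary annotation regions.

## The problem

Are trait associations enriched in regions of the genome that mark
particular periods of evolutionary history — human accelerated regions
(HAR), segmental duplications (SD), ohnologs (genes retained from
ancient whole-genome duplications)?  A naive overlap count answers the
wrong question: SNPs tagging these regions also tag exons, introns,
UTRs and brain-expressed genes, and carry more total linkage
disequilibrium (LD) than average, all of which are themselves enriched
for associations.  `evoenrich` implements an analysis pipeline that
asks the conditional question — is there evolutionary enrichment *after
controlling for* genic context and LD burden — for any user-supplied
GWAS summary statistics, LD reference panel and interval annotations.

## The method

For SNP *i* and an annotation with membership indicator δ_j over
reference-panel SNPs, the LD-weighted affiliation score is

    LDscore_i = Σ_j δ_j · r²_ij

with r² the squared Pearson correlation of genotype dosages, r² < 0.2
set to 0, r²_ii = 1, and *j* restricted to ±1 Mb of *i*.  TotLD is the
same sum with δ ≡ 1 (a per-SNP LD burden, ≥ 1).  An isolated SNP inside
a region scores exactly 1.  On top of these scores the pipeline
computes:

- **λ_GC from intergenic SNPs** — SNPs with zero genic scores and no LD
  partner near genes or inside ncRNA/TFBS/miRNA-binding-site tracks
  form an empirical null set; λ_GC is the median squared z-score of
  LD-pruned intergenic sets across 100 pruning iterations, divided by
  the χ²₁ median (≈ 0.455).
- **Conditional fold-enrichment curves** — split SNPs at affiliation
  score 1 and compare −log10(p) exceedance fractions,
  fold(x) = S_stratum(x)/S_all(x), below genome-wide significance
  (−log10 p < 7.3).
- **PLSR with jackknife t-tests** — regress squared z-scores on the
  scores (intron, exon, 3'UTR, 5'UTR, evolutionary category, brain,
  TotLD; all centered/scaled) by partial least squares, model order =
  smallest number of latent variables explaining > 99% of descriptor
  variance; significance from a 50-fold cross-validation jackknife
  whose folds respect LD-block boundaries.
- **MHC reruns** — every analysis repeats with the MHC region
  (chr6:25,652,429–33,421,466, hg19) excluded and with only that region.
- **MAF/TotLD-matched control sets** — random SNP sets replicating an
  annotation's minor-allele-frequency and TotLD profile, measuring how
  much enrichment LD and frequency structure alone produce.

A synthetic-data generator (block-LD haplotype panel, gene models with
exon/intron/UTR parts, planted per-annotation effects on the causal
variance scale, controllable genomic inflation) makes every stage
testable without downloads and states its planted truth in JSON.

## Worked example

```python
import evoenrich as ev
from evoenrich import plsr as P
from evoenrich.enrichment import stratified_curves
from evoenrich.inflation import estimate_lambda

cfg = ev.GeneratorConfig(
    n_snps=20_000, n_samples=100,
    chrom_lengths={"1": 50_000_000, "6": 50_000_000},
    tau={"SD": 2e-4},   # planted SD enrichment, causal-variance scale
    seed=1,
)
study = ev.generate_study(cfg)
index = ev.align(study.stats, study.panel)
table, nbhd = ev.build_score_table(study.panel, index, study.tracks)
S = nbhd.tag_submatrix()

lam = estimate_lambda(index.z, table["intergenic"].to_numpy(), S, seed=1)
print(f"lambda_GC = {lam.lambda_gc:.3f}  ({lam.n_intergenic} intergenic SNPs)")

cin, _ = stratified_curves(table, index.p, "SD")
print(f"SD fold enrichment at -log10(p)=2: {cin.fold_at(2.0):.2f}")

design = P.build_design(table, index.z, evo_category="SD")
folds = P.ld_folds(S, k=50, seed=1)
fit = P.jackknife_ttest(design, P.fit_plsr(design), folds)
for name, b, t, p in zip(fit.names, fit.coefficients, fit.t_stat, fit.p_value):
    print(f"  {name:8s} beta = {b:7.3f}   t = {t:6.2f}   p = {p:.2e}")
```

prints

```
lambda_GC = 2.942  (10260 intergenic SNPs)
SD fold enrichment at -log10(p)=2: 1.52
  intron   beta =  -0.019   t =  -0.94   p = 3.52e-01
  exon     beta =  -0.028   t =  -3.02   p = 4.01e-03
  utr3     beta =   0.006   t =   0.33   p = 7.42e-01
  utr5     beta =  -0.030   t =  -3.44   p = 1.21e-03
  SD       beta =   0.359   t =   2.13   p = 3.80e-02
  brain    beta =  -0.034   t =  -2.04   p = 4.71e-02
  tot_ld   beta =   0.313   t =   6.18   p = 1.26e-07
```

Reading the output: λ_GC ≈ 2.9 is not an artifact — this study plants a
polygenic baseline in *every* SNP, and intergenic SNPs tag that signal
through LD, exactly the "likely null, not exactly null" caveat of
genomic control (under a signal-free generator λ_GC calibrates to 1.00;
see `scripts/acceptance.py`).  The stratified curve shows 1.5-fold
enrichment of small p-values among SD-affiliated SNPs, and the PLSR
recovers the planted SD effect (β = 0.36, p = 0.04) while attributing
the rest of the enrichment to TotLD — the covariate-modulated question
the pipeline exists to answer.

## Command line

```bash
evoenrich run-all -c configs/synthetic.yaml --seed 1
```

runs annotate → λ_GC → enrichment curves → PLSR (+ MHC exclude/only
reruns) → matched controls from one YAML config and writes TSV/JSON
artifacts plus a `manifest.json` with a content hash of every output;
rerunning the same config reproduces the numeric tables byte for byte.
Individual verbs (`simulate`, `annotate`, `lambda`, `enrich`, `plsr`,
`match`) run single stages.  For real data, replace the `generator`
section with an `inputs` section naming summary-statistic TSVs, a VCF
or dosage-matrix panel and BED tracks; the PLSR output tables then have
one row per phenotype and one column per covariate with sd/t/p
companions, in the layout used for published enrichment tables.

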