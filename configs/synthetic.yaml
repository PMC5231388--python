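# Default synthetic study: one command reproduces the full analysis.
#   evoenrich run-all -c configs/synthetic.yaml --seed 1
out: runs/synthetic
seed: 1
generator:
  n_snps: 20000
  n_samples: 100
  chrom_lengths: {"1": 50000000, "6": 50000000}
  block_size_mean: 50000
  within_block_r2: 0.5
  base_h2_per_snp: 1.0e-5
  n_gwas: 50000
  inflation: 1.0
  tau: {"SD": 2.0e-4}
  seed: 1
categories: [HAR, SD, Ohno]
covariates: [intron, exon, utr3, utr5, brain, tot_ld]
window_bp: 1000000
r2_floor: 0.2
score_threshold: 1.0
pmax_log: 7.3
var_threshold: 0.99
k_folds: 50
n_lambda_iter: 100
n_matched_sets: 50
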