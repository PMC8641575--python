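# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
as a tested, reusable Python package. It covers the complete workflow of a
summary-level MR study:

- **`mrkit.synthetic_gwas`** — synthetic two-sample GWAS generator with a
  known causal effect, configurable horizontal pleiotropy (balanced or
  directional), invalid-instrument fractions, binary outcomes on the
  log-odds scale, allele-encoding corruption (swaps, strand flips,
  palindromic rewrites) and a one-mediator causal-chain generator, so every
  stage is verifiable against ground truth.
- **`mrkit.instruments`** — genome-wide-significance filtering (strict
  p < 5×10⁻⁸ by default), greedy LD clumping (r² < 0.01 within a
  10,000 kb window, lowest p wins), proxy substitution (r² > 0.8, strict),
  and the multi-instrument F statistic `F = (r²/(1−r²))·((n−k−1)/k)`.
- **`mrkit.harmonize`** — allele harmonization resolving effect/other
  swaps and strand flips; palindromic (A/T, C/G) SNPs are kept only when
  the minor allele frequency is strictly below 0.42 in both datasets and
  the frequency-implied orientations agree, otherwise dropped; full
  per-SNP audit trail.
- **`mrkit.estimators`** — Wald ratio (first- and second-order delta SEs),
  fixed and multiplicative-random-effects IVW, Cochran's Q / I²,
  MR-Egger with intercept (pleiotropy) test on t(J−2), weighted median
  with parametric-bootstrap SE, joint-normal maximum likelihood, and
  leave-one-out IVW.
- **`mrkit.mr_presso`** — simulation-based residual-sum-of-squares global
  pleiotropy test, per-SNP outlier detection (Bonferroni-adjusted
  empirical p), distortion test, and outlier-corrected IVW.
- **`mrkit.mvmr_mediation`** — multivariable MR (weighted least squares,
  no intercept) for direct effects, and difference-method mediation
  (indirect = total − direct) with delta-method CI for the proportion
  mediated.
- **`mrkit.power_report`** — analytical power (continuous and binary
  outcomes, the binary case mapping the odds ratio to the observed scale),
  Bonferroni significance classification with a suggestive band, and a
  YAML-configured end-to-end pipeline emitting report tables, forest-plot
  data and a JSON run manifest.

All tables are plain tab-separated text (`snp, chr, pos, effect_allele,
other_allele, eaf, beta, se, pval, n`; LD/proxy tables as
`snp_a, snp_b, r2`). Randomness uses NumPy's seeded `default_rng` (PCG64)
throughout; tests compare statistics, not raw streams, so they are robust
to generator changes across platforms.

## Command line

```sh
mr simulate --n-snps 50 --theta 0.2 --seed 1 \
    --exposure-out exp.tsv --outcome-out out.tsv --truth-out truth.json
mr instruments --gwas exp.tsv --ld ld.tsv --p-threshold 5e-8 --r2 0.01 --window-kb 10000
mr harmonize --exposure inst.tsv --outcome out.tsv --maf-threshold 0.42 --audit audit.tsv
mr estimate --harmonized h.tsv --methods ivw,egger,wmedian,ml --boot 5000 --seed 7
mr presso --harmonized h.tsv --nsim 1000 --seed 7
mr power --n 10000 --r2 0.02 --beta-alt 0.1
mr run --config study.yaml --out report_dir/
```

`mr run` takes a YAML config naming exposure/outcome (and optional
mediator) summary-statistic files plus LD/proxy tables, and writes
`results_primary.tsv`, `results_mvmr.tsv`, `mediation.tsv`, `forest.tsv`
and `manifest.json`; re-running with the same seed reproduces the output
byte for byte.

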