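# mrsumstats

Two-sample Mendelian randomization (MR) on GWAS summary statistics, for
epidemiologists and statistical geneticists who want a complete, offline,
reproducible analysis: instrument selection and strength diagnostics, four
causal-effect estimators, a full sensitivity suite, and a synthetic
summary-statistics generator with known ground truth so every stage can be
validated without downloading any GWAS.

## The method

Genetic variants are used as instrumental variables for an exposure X to
estimate its causal effect θ on an outcome Y from two separate GWAS.  Each
SNP j contributes a Wald ratio θ_j = β_Yj/β_Xj; the package combines these
with estimators that trade efficiency against robustness to horizontal
pleiotropy:

- **IVW** — θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj², w_j = 1/σ_Yj², with a
  multiplicative random-effects SE applied automatically when Cochran's Q
  detects heterogeneity;
- **MR-Egger** — the same weighted regression with a free intercept (the
  intercept estimates directional pleiotropy);
- **weighted median** — consistent while ≥ 50% of instrument weight is valid;
- **weighted mode** — consistent when the largest cluster of SNPs is valid
  (kernel bandwidth factor φ exposed, since it cannot be estimated).

Instruments are selected at p < 5×10⁻⁸, MAF > 5%, greedily LD-clumped
(r² > 0.001 within 10,000 kb, from a user-supplied LD table), screened
against a confounder exclusion list, and pre-filtered with MR-PRESSO.
Strength is reported as R² = Σ 2·EAF(1−EAF)β² and
F = ((N−K−1)/K)·R²/(1−R²); causal direction is checked with a Steiger-type
test.  Sensitivity: Cochran's Q, Egger intercept, MR-PRESSO
global/outlier/distortion, leave-one-out, and plot-data exports
(scatter/funnel/forest) as TSV.  Estimator p-values are compared against a
Bonferroni-corrected threshold 0.05/4 = 0.0125 for the four methods.

See `docs/methods.md` for formulas, assumptions, numerical conventions and
known limitations.

## Worked example

Generate a biobank-scale synthetic study — 475 planted instruments (25 in
LD pairs, 15 on a confounder list) plus 2,000 null SNPs, exposure
n = 454,874, case-control-scale outcome n = 462,933, true
θ = log(0.9923) — and run the full pipeline on it:

```sh
mrsumstats simulate --paperlike --out-dir demo --seed 7
mrsumstats run --exposure demo/exposure.tsv --outcome demo/outcome.tsv \
    --ld demo/ld.tsv --exclusions demo/exclusions.txt \
    --seed 7 --out-dir demo/results
```

which prints:

```
# Two-sample MR report

## SNP accounting
  read                       2475 -> 2475   exposure=2475 outcome=2475
  harmonize                  2475 -> 2475   0 flagged
  significance               2475 -> 471    p < 5e-08
  maf                         471 -> 471    MAF > 0.05
  ld_clump                   471 -> 446    r2 > 0.001 within 10000 kb
  confounder_exclusion       446 -> 431    15 excluded
  presso_prefilter           431 -> 431    0 outlier(s) removed

## Estimates (OR with 95% CI)
  ivw              variant=fixed    k=431  beta=-0.0080727 se=0.000574071 p=6.485e-45 OR=0.9920 [0.9908, 0.9931]  significant
  egger            variant=n/a     k=431  beta=-0.00624762 se=0.00194115 p=0.001289 OR=0.9938 [0.9900, 0.9976]  significant
  weighted_median  variant=n/a     k=431  beta=-0.00868016 se=0.000637838 p=3.554e-42 OR=0.9914 [0.9901, 0.9926]  significant
  weighted_mode    variant=n/a     k=431  beta=-0.0106294 se=0.00164837 p=1.13e-10 OR=0.9894 [0.9862, 0.9926]  significant

Bonferroni-corrected alpha: 0.0125

## Instrument strength
  k=431  total R2=0.105116  F=123.8518  (N=454874)
  Steiger: exposure->outcome supported=True (R2_exp=0.1051, R2_out=2.095e-05, p=4.94e-324)

## Sensitivity
  Cochran's Q = 407.0980 (df=430, p=0.7801)
  Egger intercept = -4.908e-05 (se=4.987e-05, p=0.325)
  MR-PRESSO RSSobs = 408.9659, global p = 0.8022, outliers = none
  leave-one-out: max |Δbeta| = 9.974e-05; any CI excludes full estimate: False
```

Reading the report: of 2,475 shared SNPs, 471 pass genome-wide significance
(the 475 planted instruments minus a few near the threshold), clumping
removes the weaker member of each planted LD pair, and the confounder list
removes 15 more, leaving k = 431 analysable instruments.  All four
estimators recover an odds ratio near the design value 0.9923 per unit of
exposure and stay significant at the corrected threshold; the instrument set
is strong (F ≈ 124), the Steiger test supports the assumed direction, and no
heterogeneity, pleiotropy or outliers are detected — as expected, since none
were simulated.  `demo/results/` additionally holds the estimate/ledger
tables, the harmonized instrument table, the audit log and the plot-data
TSVs.

The same analysis runs on real data by pointing `--exposure`/`--outcome` at
any delimited summary-statistics files (column names configurable through a
YAML config; see `mrsumstats run --config`).  Public GWAS summary statistics
(e.g. from the IEU OpenGWAS catalogue) can be downloaded manually, exported
to TSV, and fed in unchanged; the LD table is a 3-column `snp_a snp_b r2`
file such as plink's pairwise output.

The library mirrors the CLI one-to-one (`mrsumstats.run_mr`,
`harmonize`, `ivw`, `mr_egger`, `weighted_median`, `weighted_mode`,
`mr_presso`, `simulate_two_sample`, ...).

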