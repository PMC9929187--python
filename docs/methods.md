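# Methods

`mrsumstats` implements two-sample Mendelian randomization (MR) on GWAS
summary statistics.  The causal effect θ of an exposure X on an outcome Y is
estimated from per-SNP association pairs (β_Xj, σ_Xj) and (β_Yj, σ_Yj),
taken from two non-overlapping GWAS, under the instrumental-variable
assumptions: each SNP j is associated with X, independent of confounders of
X→Y, and affects Y only through X.

## Model and estimators

Each SNP contributes a Wald ratio θ_j = β_Yj/β_Xj with first-order SE
σ_Yj/|β_Xj|.  The combined estimators are:

- **IVW.**  θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj², w_j = 1/σ_Yj² — the
  inverse-variance-weighted meta-analysis of the Wald ratios, identical to a
  zero-intercept weighted regression of β_Y on β_X.  The fixed-effect SE is
  (Σ w_j β_Xj²)^(−1/2); the multiplicative random-effects variant multiplies
  it by max(1, √(Q/(k−1))), with Q the Cochran statistic about θ̂.  The
  `auto` variant (the pipeline default) applies the random-effects SE when
  the Q test is significant at 0.05.  The scale factor is floored at 1, so
  the random-effects interval is never narrower than the fixed one.
- **MR-Egger.**  The same weighted regression with a free intercept, after
  orienting every SNP so β_Xj ≥ 0.  The intercept estimates the average
  directional pleiotropic effect; the slope is the causal estimate, valid
  when instrument strength is independent of direct effects (InSIDE).  SEs
  carry the multiplicative scaling max(1, √(RSS/(k−2))).
- **Weighted median.**  The interpolated 50% quantile of the sorted ratios
  with normalized weights β_Xj²/σ_Yj², each SNP's percentile being its
  cumulative weight minus half its own.  Consistent while ≥ 50% of weight is
  on valid instruments.  SE by bootstrap over instruments (default 1,000
  resamples).
- **Weighted mode.**  The argmax of a normal-kernel weighted density of the
  ratios, consistent when the largest cluster of SNPs is valid.  The kernel
  bandwidth is φ · 1.4826 · MAD_w · k^(−1/5), where MAD_w is the weighted
  median absolute deviation of the ratios about their weighted median.  The
  bandwidth cannot be estimated from data, so φ (default 1) is an exposed
  tuning parameter.  The density is evaluated on a 512-point grid spanning
  the ratio range ± 3 bandwidths; when the weighted MAD is zero (all ratios
  equal) the common ratio is returned exactly.  SE by bootstrap.

All p-values are two-sided normal (a deliberate convention, consistent with
the multiplicative-scaling SEs; a t reference would differ only at very
small k).  Odds ratios are exp(θ̂) with normal-quantile CIs; they inherit
whatever outcome scale the input GWAS used.  Estimators canonically sort
instruments by identifier before estimation and bootstrap, making every
result invariant to input order and to allele relabeling (simultaneous sign
flips of β_Xj, β_Yj).

## Instrument selection and strength

Selection applies, in order: genome-wide significance (p < 5e-8, strict),
minor-allele-frequency floor (MAF > 0.05, strict; missing frequencies are
retained with a warning), greedy LD clumping (index SNP = smallest p, ties
by position then identifier; neighbours on the same chromosome within
10,000 kb with r² > 0.001 are discarded; pairs absent from the user-supplied
LD table count as r² = 0), and file-driven exclusion lists (confounder
screen stand-in, MR-PRESSO outliers).  LD is always supplied by the caller —
the package never computes it from a reference panel, keeping runs
deterministic and offline.

Strength diagnostics: per-SNP variance explained R²_j = 2·EAF_j(1−EAF_j)β_Xj²
(exact only for a standardized trait — the formula is computed as given and
this caveat is the user's to own for unstandardized inputs), total R² as the
sum, and F = ((N−K−1)/K)·(R²/(1−R²)) with K the instrument count (K = 1 for
per-SNP F).  F < 10 is the conventional weak-instrument flag.

The Steiger directionality check compares variance explained on the two
sides: direction is "exposure → outcome" when total exposure R² exceeds
total outcome R², with a p-value from a Fisher-z comparison of the implied
correlation magnitudes, using sampling variance 1/(n_exp−3) + 1/(n_out−3)
at the median per-SNP sample sizes.  The Fisher-z form is a design choice;
it treats the two R² totals as estimated correlations from independent
samples.

## Harmonization

Exposure and outcome effects are merged on shared SNP identifiers and
re-expressed on the exposure's effect allele: swapped alleles negate the
outcome beta and complement its frequency; alleles matching only under
reverse complement are re-expressed (strand flip); both may combine.
Palindromic SNPs (A/T, C/G) carry no strand information in their allele
labels, so they are oriented purely by allele-frequency agreement — and
dropped when the exposure frequency lies in [0.5−w, 0.5+w] (default
w = 0.08) or is missing.  Irreconcilable allele pairs are excluded with an
audit-log entry rather than an error.  Duplicate identifiers within a study
keep the smallest p-value.  Harmonization is involution-safe: re-harmonizing
its own output changes nothing.

## Sensitivity suite

- **Cochran's Q** about a slope θ: Q = Σ w_j(θ_j − θ)², w_j = β_Xj²/σ_Yj²,
  df = k−1.  Computed about the IVW estimate (not the Egger fit).
- **Egger intercept test**: intercept, SE, two-sided p; flagged at p < 0.05.
- **MR-PRESSO**: for each SNP the leave-one-out IVW slope θ_{−j} gives a
  residual r_j = β_Yj − θ_{−j}β_Xj; RSSobs = Σ w_j r_j² (w_j = 1/σ_Yj²).
  The null distribution comes from parametric resamples
  β*_Xj ~ N(β_Xj, σ_Xj²), β*_Yj ~ N(θ_{−j}β_Xj, σ_Yj²).  Empirical
  p-values use (1 + #exceedances)/(n_sim + 1), which cannot reach zero;
  per-SNP p-values are Bonferroni-adjusted by k.  Note the resolution
  constraint this implies: with n_sim simulations the smallest achievable
  adjusted p is k/(n_sim+1), so flagging any outlier at α = 0.05 requires
  n_sim ≳ 20k (the implementation warns otherwise).  The distortion test
  reports the percent change of the IVW slope after removing outliers, with
  an empirical p from removing equally many SNPs at random.  Default
  n_sim = 1,000; users needing small global p-values raise it.
- **Leave-one-out**: IVW on every k−1 subset, with the maximum slope
  deviation and a flag for any CI excluding the full-set estimate.
- Plot-data exports (scatter, funnel, forest, leave-one-out) as TSV for
  external plotting; no figures are rendered.

## Pipeline

`run_mr` chains read → harmonize → significance → MAF → clump → confounder
exclusions → MR-PRESSO pre-filter → diagnostics → the four estimators →
sensitivity → Bonferroni verdicts (α = 0.05/4 by default, for the four
estimation methods).  Missing optional resources (LD table, exclusion list)
skip their stage with a warning and a ledger note.  A per-stage accounting
ledger records input/output SNP counts and is monotone non-increasing.  A
single master seed deterministically derives the bootstrap and PRESSO seeds
(via `SeedSequence`), so a report is byte-reproducible from its config.

## Synthetic data generator

The generator draws, for SNP j: EAF p_j ~ U(0.05, 0.5); exposure effect
γ_j ~ N(0, gamma_sd²) (default 0.02, giving mostly-strong instruments at
biobank sample sizes); pleiotropic effect α_j = 0 for valid SNPs and
α_j = sign(γ_j)·δ_j, δ_j ~ N(mu, tau²) for the invalid fraction; true
outcome effect θγ_j + α_j; and observed effects with sampling noise
se = √(v/(2·n·p_j(1−p_j))) for a GWAS of n individuals on a trait of
variance v (v = 1 for the standardized exposure; the outcome's `var_out`
can be set to c(1−c) to emulate a 0/1 case-control trait with case
fraction c).  Defaults mirror the UK Biobank scale the package was designed
around (n_exp = 454,874, n_out = 462,933).  Planted outliers displace the
observed outcome effect by `outlier_offset` (default 10) outcome SEs.

Two deliberate modelling choices:

- *Oriented pleiotropy.*  Directional pleiotropy is applied relative to the
  exposure-raising allele (the sign(γ_j) factor).  Allele labels are
  arbitrary, and every estimator is invariant to relabeling; an unoriented
  α with a symmetric γ law would therefore average out and make "directional"
  pleiotropy undetectable by construction.  With the orientation, the Egger
  intercept converges to mu and the weighted median's 50% breakdown behaves
  as the theory says.
- *Hit-panel fixture.*  `make_paperlike_fixture` draws instrument magnitudes
  as |z| = 7 + |N(0, 4²)| at each SNP's own SE instead of the plain Normal
  law: genome-wide-significant hits are bounded away from zero by the very
  filter that defines them, and the fixture must survive its own p < 5e-8
  stage near-intact.  The fixture plants 475 instruments (25 LD pairs at
  r² = 0.5 that clumping halves, 15 confounder-listed SNPs), 2,000 null
  SNPs, biobank sample sizes, a case-control-scale outcome, and
  θ = log(0.9923), so the full pipeline ends with ~430 instruments and an
  IVW odds ratio near 0.992.

What the generator does *not* emulate: realistic LD (blocks are uniform-r²
constructs for exercising the clumping logic), sample overlap between the
two GWAS (a documented bias source; both samples are independent by
construction), case-control ascertainment (outcome betas are linear-scale),
winner's curse in `simulate_two_sample` (effects are drawn, not selected),
and population stratification.  Passing tests therefore certify the
statistical machinery under the stated model, not robustness to these
real-data features.

## Known limitations and numerical notes

- The weighted median under one-sided (directional) contamination at invalid
  fraction f < 0.5 sits at the 0.5/(1−f) weighted quantile of the valid
  ratio cloud.  This is a genuine finite-sample bias of order the
  estimator's own sampling spread (it vanishes only as instrument strength
  grows *relative to the contamination scale*); simulation tests of
  "robustness below 50%" judge recovery on the per-replicate spread, not to
  Monte-Carlo precision of a replicate mean, which no quantile estimator
  under one-sided contamination could meet.
- Simulation problem sizes in the test suite (500 replicates for
  calibration/recovery, 200 for the median breakdown, 100 for PRESSO
  detection, k between 50 and 200) were chosen to give Monte-Carlo
  tolerances comfortably below the effects being tested.
- Degenerate inputs: zero exposure effect makes a Wald ratio undefined
  (error); Egger requires k ≥ 3 and non-collinear β_X; Q and leave-one-out
  require k ≥ 2; PRESSO requires k ≥ 4.  Empirical p-values are floored at
  1/(n_sim+1); analytic p-values at the smallest positive float, keeping
  them in (0, 1].
- Clumping ties (equal p) break by position, then identifier; windows are
  closed intervals in base pairs (1-based positions).
- The per-unit scale of reported effects is the input GWAS's: the package
  does not rescale to per-SD units.
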