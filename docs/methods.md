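# Methods

## Scope and model

`omicsmr` implements a summary-statistics-only causal-inference chain for
linking molecular biomarkers (methylation, expression and protein QTL
probes) to clinical risk factors and to coronary artery disease (CAD):

1. **SMR co-localization.** For a probe with top QTL SNP effects
   (β_x, se_x) and trait effects (β_y, se_y) at the same SNP, the mediated
   effect is the Wald ratio β_SMR = β_y/β_x, tested with

       T = (Z_y² · Z_x²) / (Z_y² + Z_x²),   Z = β/se,

   which is χ²₁-distributed under the null of no mediation.  The reported
   standard error is |β_SMR|/√T (infinite at T = 0).

2. **HEIDI linkage filtering.**  A significant β_SMR is consistent with a
   shared causal variant (causality or pleiotropy) *or* with two distinct
   causal variants in LD (linkage).  HEIDI tests homogeneity of the Wald
   ratio across SNPs in intermediate LD with the top SNP.  For flanking
   SNP i, d_i = b_i − b_top where b_i = β_y(i)/β_x(i).  Delta-method
   variances and covariances are used, with cross-SNP covariance induced
   by reference-panel LD and the two cohorts independent (two-sample
   design):

       cov(b_i, b_j) = r_ij (se_y,i se_y,j + b_i b_j se_x,i se_x,j) / (β_x,i β_x,j).

   The statistic Σ z_i² (z = standardized d) follows a weighted sum of
   1-df chi-squares, weights = eigenvalues of the correlation matrix of
   the standardized differences.  The tail probability uses the two-moment
   (Satterthwaite) approximation by default; an exact Imhof
   numerical-inversion hook (`method="imhof"`) is provided.  In our
   calibration runs the two methods gave indistinguishable 5%-level
   rejection rates, so the cheaper approximation remains the default.

3. **Multi-SNP MR (GSMR-style).**  Instrument Wald ratios are combined by
   generalized least squares under the covariance above, with the variance
   evaluated at the current estimate and iterated from b_xy = 0 to a
   tolerance of 1e-8 (max 100 iterations; the update is a strong
   contraction and typically converges in fewer than 10).  With identity
   LD this reduces exactly to the classic inverse-variance-weighted
   estimator, which is asserted against an independently coded scalar
   oracle.  P-values use the normal approximation, standard for GLS with
   known covariance.  A flag (`ld_scaled=False`) treats post-clump
   instruments as independent; LD-scaled is the default.

4. **Instrument selection.**  (a) greedy LD clumping: rank by ascending p
   (ties by genomic position where available, then snp_id), accept iff
   r² < 0.05 with all accepted SNPs, significance p < 5e-8; (b) a
   pleiotropy screen retaining SNPs whose Wald-ratio heterogeneity p is
   ≥ 0.01.  The screen compares each ratio with the
   **inverse-variance-weighted median** of all candidate ratios.  A
   top-SNP reference was considered and rejected: in reverse-direction MR
   the most significant instrument is often itself a mediated (hence
   deviant) SNP, and anchoring the screen on it empties the instrument
   set; the weighted median is robust as long as deviant instruments carry
   a minority of the precision.  The screen is skipped below 3 candidates,
   where no meaningful consensus exists.

5. **Outlier removal.**  After selection, the GLS fit is refit
   iteratively, removing the single most deviant instrument whenever its
   standardized deviation |b_i − b_xy|/√(v_i − var(b_xy)) exceeds the
   two-sided normal critical value at α = 0.01 (v_i − var(b_xy) is the
   exact variance of the residual under the GLS fit, since cov(b_i, b̂)
   = var(b̂) for every i).

6. **Filtering chain.**  Per probe: co-localization pass requires
   p_SMR < 5e-8 and p_HEIDI > 0.05 (undefined HEIDI — no usable flanking
   SNPs — fails conservatively); forward MR probe→risk-factor gated at
   p < 5e-8; reverse MR risk-factor→probe excludes at p < 0.05 (raw, not
   multiplicity-adjusted); probe→CAD gated on the Bonferroni-corrected p
   (family = number of probe→CAD forward tests actually performed in the
   run, the smallest defensible family) at 0.05; CAD→probe reverse MR
   excludes at p < 0.05.  Statuses record the first failed gate.  For the
   binary disease outcome, effects are log-odds per exposure SD and the
   report shows exp(β) rounded to 2 decimals (β = 0.05 → OR 1.05).

Two HEIDI thresholds coexist deliberately: co-localization excludes at
p_HEIDI ≤ 0.05, while the instrument-stage screen uses 0.01.  Small HEIDI
p indicates heterogeneity, so instruments are *retained* when p ≥ 0.01.

## Harmonization rules

Outcome records are re-expressed on the exposure's effect allele: exact
matches kept, swapped alleles flip β and eaf, strand flips are resolved by
base complementation before comparison, and palindromic SNPs (A/T, C/G)
with either table's frequency within 0.08 of 0.5 are dropped as
unorientable.  Irreconcilable alleles (including mismatched multi-allelic
records) are dropped and counted.  Harmonization is idempotent and never
alters exposure betas.

## Synthetic data generator

Haplotypes come from a Gaussian copula: a latent AR(1) field per LD block
(correlation `block_rho` between adjacent SNPs, blocks independent),
thresholded at each SNP's MAF quantile; genotype = sum of two independent
haplotypes.  This reproduces the feature real panels contribute to the
method — blocky LD decaying with distance — and nothing else: there is no
realistic human LD map, no imputation error, no cohort overlap, and no
population stratification.  Passing tests therefore demonstrate
statistical correctness of the machinery under the stated generating
model, not robustness to those real-data complications.

Traits: exposure x = Σ γ_j g_j + e with QTL effects scaled by model
dosage variances 2p(1−p) so they explain `qtl_var` of unit variance (QTLs
are placed in distinct LD blocks, so the per-SNP variances add).  Outcome
construction per scenario (causal, pleiotropy, linkage, reverse, null) is
described in the module docstring; outcome noise is scaled against the
*empirical* variance of the systematic part, keeping total variance at 1
even when shared-SNP covariance terms appear.  Summary statistics are
per-SNP simple linear regressions with normal-approximation p-values
(per-SNP logistic regressions on a liability-threshold dichotomization
when `binary_outcome` is set; off by default since the MR algebra is
identical on the log-odds scale).

The chain generator (`simulate_chain`) adds the three-trait structure
(probe → risk factor → CAD, three disjoint cohorts) needed to exercise
the full pipeline; each downstream trait carries direct QTLs in its own
LD blocks.  This is what makes reverse-MR behave as in real data:
instruments selected on a downstream trait are dominated by its own QTLs.
Mediated instruments do enter reverse-direction candidate sets and are
eliminated by the weighted-median screen plus outlier removal.

## Standard study conditions

Chosen once as realistic desk-scale analogues of the field's setting
(QTL/GWAS cohorts of tens of thousands, reference panels of hundreds) and
used by both the test suite and `scripts/acceptance.py`:

| experiment | conditions |
|---|---|
| causal recovery | b_xy = 0.2, 10 QTLs, qtl_var = 0.1, 200 SNPs, n = 20 000, panel 854 |
| HEIDI calibration/power | 1 causal variant, qtl_var = 0.02, b_xy = 0.5, 40 SNPs (2 blocks, ρ = 0.9), linkage r² target 0.5 |
| null calibration | b_xy = 0, 5 QTLs, qtl_var = 0.1, 100 SNPs |
| pipeline chains | 300 SNPs (15 blocks), 5 QTLs per trait, variances 0.3, b(probe→risk) = 0.5, b(risk→CAD) = 0.4, three cohorts of 20 000 |

The HEIDI conditions use b_xy = 0.5 (rather than the recovery setting's
0.2) because the linkage alternative must place a detectable association
on the outcome side for the test to have anything to reject; the type-I
check uses the same value for a like-for-like comparison.  The reference
panel defaults to 854 samples, the size of the kind of in-house European
panel typically used for LD estimation in this design.

## Numerical choices and degenerate inputs

- p-values are floored at 1e-300; HEIDI variances at 1e-30; eigenvalues
  clipped at 0.
- LD matrices are symmetrized, clipped to [−1, 1], diagonal set to 1.
- Missing dosages: pairwise-complete correlation; monomorphic SNPs and
  pairs with < 2 shared samples are hard errors naming the SNP.
- Ties in p are broken by genomic position then lexicographic snp_id; the
  `.ma` format carries no positions, so they are an optional argument and
  the id fallback guarantees determinism.
- β_x = 0 makes the Wald ratio undefined and is a hard error; the
  instrument-significance filter makes it unreachable in practice.
- Duplicate or perfectly correlated instruments give a singular GLS
  covariance and raise rather than silently regularizing.
- All randomness flows through `numpy` Generators seeded from a single
  integer via `SeedSequence`; replicate seeds are derived, below 2³¹.

## Known limitations

- The HEIDI and GSMR internals follow the published structure of those
  methods but are this package's own definitions; numerical parity with
  the reference C++/GCTA implementations is not claimed.
- Plug-in standardization in HEIDI (estimated b's in the covariance) makes
  the test approximate; calibration is verified empirically at the 5%
  level under the stated conditions.
- The reverse-MR exclusion uses raw p < 0.05 without multiplicity
  adjustment.
- Binary outcomes use per-SNP logistic regressions on a liability
  threshold; case-control ascertainment and covariate adjustment are not
  modelled.
- Whole-genome windowed clumping across chromosomes is out of scope; the
  package operates on user-supplied cis-regions.
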