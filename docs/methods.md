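# Methods

This note documents the statistical models the package implements, the
design choices made where the methodology was genuinely open, what the
synthetic data do and do not emulate, and the numerical details a user
extending or auditing the code will want.

## Study design being modelled

The pipeline mirrors a two-sample MR design: genetic instruments for a
continuous pulmonary phenotype are developed in one large cohort
(exposure sample), their effects on a binary outcome (lung cancer
case/control status) are estimated in a disjoint sample, and the ratio
of outcome to exposure effects identifies the causal log odds ratio per
exposure unit under the instrumental-variable assumptions. Exposures
are analysed per 1 SD of the z-scored volume phenotypes, and per 10%
(0.1 absolute units) of the FEV1/FVC ratio kept on its natural 0–1
scale.

## Instrument development

**Spirometry QC.** The best measure per person is the maximum blow.
People with a single blow are excluded outright, since reproducibility
cannot be assessed. Remaining blows further than 0.15 L from the best
are dropped as non-reproducible; a person passes if at least one
non-best blow survives. Both FEV1 and FVC series must pass.

**Phenotypes.** Volumes are z-standardized (mean 0, SD 1) over the
QC-passing analysis sample; the FEV1/FVC ratio is left untransformed;
airflow obstruction (COPD) is flagged at ratio < 0.70.

**Variant QC.** Dosages within 0.1 of an integer are hard-called,
otherwise missing. Variants fail on a Hardy–Weinberg exact test
p < 1e-5 (computed on the control/cancer-free subset when an outcome
label exists), call rate < 95%, or MAF < 0.005. The HWE test
enumerates the conditional distribution of heterozygote counts given
the minor-allele count, summing probabilities no larger than the
observed configuration's. An imputation-INFO filter does not apply to
simulated hard genotypes and is recorded as skipped.

**Association scan.** Per-variant OLS via the Frisch–Waugh–Lovell
projection: phenotype and dosages are residualized against the
covariates (plus intercept) once, making the per-variant fit a single
dot product. p-values use the t distribution; genomic inflation is
reported as median(χ²)/0.4549.

**Selection.** Discovery associations at P < 5e-8 are LD-clumped
greedily (best remaining p becomes an index; r² ≥ 0.05 within
±10,000 kb removed; ties on p broken by position then id, making the
result order-invariant), then filtered to sign-consistent replication
at P < 0.05. Instrument weights default to the discovery betas, with
replication used only for filtering; a flag switches to replication
weights. The 70/30 discovery/replication split is a seeded random
assignment of individuals, unstratified. Per-variant strength uses the
replication z-scores: r²j = z²/(z² + n − 2), R² = Σ r²j,
F = R²(n−1−J)/((1−R²)J). Note that with J = 1 this F reduces exactly
to z², i.e. a z = 10 variant has F = 100.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: swapped
labels flip the sign and frequency; strand flips are resolved by
complementing alleles. Palindromic variants (A/T, C/G) cannot be
resolved from labels; they are retained only when MAF ≤ 0.42 in *both*
studies (the strictest reading) and the allele frequencies fall on the
same side of 0.5 after orientation, else excluded. All exclusions
carry machine-readable reasons and are counted in the output.
Irreconcilable allele sets (e.g. A/G vs A/C) are likewise excluded
with a reason rather than aborting the run, so one malformed row
cannot kill a batch harmonization.

Proxies: a variant missing from the outcome table may be replaced by
its strongest LD partner with r² > 0.90 within the window (ties toward
the smaller position). The proxy inherits the index variant's exposure
effect and contributes its own outcome effect.

The "impairment" orientation re-expresses effects per unit of
*decreased* function: alleles are flipped so every exposure effect is
non-negative toward impairment, which negates the causal estimate
exactly; the flipped rows are recorded so applying the mode twice
restores the original table.

## Estimators

All causal effects are log odds ratios per exposure unit. First-order
weights (1/σY²) are used for IVW and the weighted median; the
modified second-order weights live in the heterogeneity diagnostics.

- **IVW**: θ̂ = Σ βXβY/σY² ÷ Σ βX²/σY²; the multiplicative
  random-effects SE multiplies the fixed-effect SE by
  max(1, √(Q₁/(J−1))) — never deflating it.
- **Profile ML**: per-instrument true exposure effects are profiled
  out in closed form, leaving a 1-D likelihood in θ maximized by
  bounded Brent search over the ratio range ± 5 spreads; the SE comes
  from the numerical observed information. In the no-measurement-error
  limit (σX → 0) this equals fixed-effect IVW.
- **Weighted median**: ratios ordered, weights βX²/σY² normalized,
  cumulative weight midpoints interpolated at 0.5. SE from a
  parametric bootstrap (B = 1000 by default, seeded) resampling both
  summary effects from their sampling normals.
- **MR-Egger**: instruments jointly sign-oriented to βX ≥ 0, then WLS
  of βY on βX with a free intercept; both SEs carry
  max(1, √(Q_E/(J−2))). The slope p uses t with J−2 df (small-J
  correctness); the intercept test for directional pleiotropy is the
  z-test.
- **MR-RAPS**: standardized residuals
  r = (βY − θβX)/√(σY² + θ²σX² + τ²) enter a Huber loss (k = 1.345;
  squared loss available). θ minimizes the summed loss; the additive
  overdispersion τ² is solved so the mean loss equals its standard
  normal expectation, alternating to a joint fixed point. τ² pushed
  negative is clamped to zero, with a warning only when the deficit
  exceeds two standard errors of the mean loss (a boundary solution on
  clean data is expected, not pathological). The SE is a sandwich
  estimate from the robust score.
- **Multivariable IVW**: WLS of βY on the k exposure-effect columns
  without intercept, RE inflation max(1, √(Q/(J−k))).

## Diagnostics

**Modified-weight Q.** Q(θ) = Σ wj(θ)(θj − θ)² with
wj(θ)⁻¹ = σYj²/βXj² + θ²σXj²/βXj². The minimizer is found by the
weight-update/weighted-mean iteration from the first-order IVW start,
then polished by direct 1-D minimization — the fixed point of the
iteration is not exactly the argmin because the weights depend on θ,
and the reported θ* matches a dense grid search to 1e-5. When all
σX = 0 the statistic reduces exactly to first-order Cochran's Q.

**Outlier filtering.** The paper-style filtering rule is not uniquely
determined by any published description, so the package uses a
conservative, systematic default: iteratively remove the largest Qj
while it exceeds the χ²₁ upper-α quantile with Bonferroni α = 0.05/J,
recomputing Q each round, stopping at J = 3. Every removal is logged
with its contribution and round. A `q_alpha` override is provided. The
global Q p-value is non-decreasing across rounds, and on clean data
the expected number of removals is well under one per 30 instruments.

**I²GX** = max(0, (Q_GX − (J−1))/Q_GX) with Q_GX the heterogeneity of
exposure effects about their inverse-variance-weighted mean; values
below 0.90 indicate regression dilution in the Egger intercept test.

**Steiger.** Per-variant variance explained is approximated on the
observed scale as z²/(z² + N − 2) for both traits — for the binary
outcome this is a documented approximation; liability-scale conversion
is out of scope and flagged in the output. The aggregate comparison is
a Fisher-z difference with effective N the harmonic mean of the two
sample sizes; |z| < 1.96 is reported as indeterminate.

**Power.** power = Φ(√(N·R²·K(1−K))·|log OR| − z₁₋α/₂), the standard
noncentrality approximation for a binary outcome; the minimum
detectable OR inverts it by root finding on the log scale. Power is
monotone in N, R² and |log OR| (property-tested).

## LD-score regression

LD scores are ℓj = 1 + Σ r²adj over neighbours within the window, with
the small-sample adjustment r²adj = max(0, r² − (1−r²)/(n−2)).
Heritability comes from the weighted regression of χ² on ℓ: an
unweighted first pass gives a provisional h₂₀, the second pass weights
by 1/(ℓ·(1 + N·h₂₀·ℓ/M)²); slope·M/N is h². The intercept is free by
default (absorbing confounding-style inflation; a constrained mode
pins it). Genetic covariance replaces χ² with z₁z₂ and N with √(N₁N₂);
its intercept absorbs sample overlap; r_g = ρ_g/√(h²₁h²₂), clamped to
[−1.25, 1.25] with a warning outside [−1, 1]. Standard errors use a
delete-one block jackknife over contiguous variant blocks — 20 blocks
by default at this package's simulation scale (configurable; the
classical choice at genome scale is 200). Stratified heritability fits
E[χ²] = N·Στc·ℓ(·,c) + intercept by weighted multiple regression;
enrichment is the proportion of heritability over the proportion of
SNPs, with jackknife p-values and a Bonferroni significance flag at
8.5e-4. A coordinate exclusion list supports MHC-style region masking
(off by default for synthetic data). r_g is scale-invariant, so the
absence of liability-scale conversion does not affect cross-trait
results; the "impairment" rescaling of r_g is exactly a sign flip.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) with no global
state; ground-truth labels ride alongside the data and are never read
by inference code.

- **Genotypes**: a latent Gaussian copula thresholded at the
  allele-frequency quantile per haplotype gives Hardy–Weinberg
  genotypes; within a block the latent process is AR(1), and the
  latent coefficient for each adjacent pair is solved (inverse
  tetrachoric, by bisection on the bivariate normal rectangle
  probability) so the realized *allele* correlation matches the
  configured rho — without this step thresholding would attenuate the
  LD well below its nominal value. Unequal allele frequencies bound
  the attainable correlation; the generator then uses the closest
  achievable value. Blocks sit > 10,000 kb apart so no clumping window
  spans two blocks.
- **Cohorts**: exposure = genetic score + confounder + noise, scaled
  to unit variance with the genetic share pinned at h²x. The binary
  outcome uses a logistic model — not a liability threshold — so the
  true causal "odds ratio" is exact on the very scale MR estimates;
  the intercept is solved by bisection so the expected case fraction
  (default 0.34, the case share of the modelled outcome sample)
  matches to ±0.001. Invalid instruments receive direct log-odds
  effects, zero-mean under the balanced flag.
- **Summary-level sets**: β̂X ~ N(βX, σX²), β̂Y ~ N(θβX + α, σY²) with
  true exposure effects |N(0.1, 0.03²)| — strong instruments (per-
  variant z ≈ 10, I²GX > 0.97 territory) matching a well-powered
  instrument set. Pleiotropy magnitudes default to α-SD 0.05, a free
  parameter: the paper-scale outlier counts do not pin it down.
- **Polygenic pairs**: z-scores are drawn directly from the LD-score
  regression generative model — per-variant variance 1 + N·h²·ℓ/M,
  cross-trait covariance √(N₁N₂)·ρg·ℓ/M plus an overlap term — with
  synthetic LD scores ℓ ~ 1 + Gamma(2, 2). There is no actual LD
  between z's of neighbouring variants, only the mean–variance
  relationship the regression consumes.

Not emulated: realistic human LD maps, imputation error, ancestry
structure and relatedness, selection effects, or genuine genomic
annotation structure. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under its own
assumptions, not robustness to those real-data complications.

## Numerical choices

- Bisection/Brent tolerances: logistic intercept ±1e-4 (target
  ±0.001); modified-Q fixed point 1e-8 with a 1e-10 polish; RAPS
  alternation to 1e-7 relative in θ.
- Clumping ties: p, then position, then id — deterministic and
  order-invariant.
- Weighted-median edge masses: a query below the first (or above the
  last) cumulative midpoint returns the boundary ratio.
- Degenerate inputs raise rather than return NaN: zero-variance
  phenotypes, rank-deficient covariates or exposure matrices,
  all-equal exposure effects in Egger, non-positive heritability in
  r_g.
- Per-stage seeds in the pipeline derive from the master seed by fixed
  offsets; the weighted-median bootstrap takes an explicit seed.

## Simulation scale

The test suite and the acceptance script run the calibration studies
at: 500 replicates for the type-I error of outlier-filtered IVW-RE
(J = 100, balanced pleiotropy), 300 replicates for CI coverage,
100 replicates at m = 5,000 variants and N = 20,000 for LD-score
parameter recovery, and J = 150 for estimator agreement — sizes chosen
so the whole battery completes in well under a minute while leaving
Monte-Carlo noise comfortably inside the asserted bands. The
end-to-end pipeline demo uses 8,000 + 8,000 individuals and 300
variants.

## Known limitations

- Weights from discovery-stage betas carry winner's curse: at desk
  scale (thousands of individuals) selection at P < 5e-8 visibly
  attenuates the end-to-end causal estimate toward zero even though
  each estimator is consistent given its inputs. This is a property of
  the two-stage design, not a bug; replication weights (flag) trade it
  for different biases.
- Logistic (rather than liability) outcome generation makes the
  log-odds ground truth exact but means h² of the binary trait is not
  parameterized.
- Steiger's binary-outcome variance explained is an observed-scale
  approximation.
- The eQTL stage consumes harmonized per-gene summary tables; it does
  not model expression panels.
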