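# Methods

This note documents the statistical models implemented in `mrscreen`,
the conventions and defaults chosen where several are defensible, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Two-sample MR estimators

All estimators consume harmonized per-variant effect pairs
(β̂ₓⱼ, σₓⱼ, β̂ᵧⱼ, σᵧⱼ) for a set of instrument variants, assuming the
two GWAS come from non-overlapping samples of the same population
(violations are quantified separately, below). Binary-trait effects are
log-odds throughout; odds ratios appear only at the reporting layer.

- **Wald ratio** (single instrument): β̂ = β̂ᵧ/β̂ₓ, SE = σᵧ/|β̂ₓ| by the
  first-order delta method, which ignores exposure-side uncertainty —
  adequate when the instrument is strong (F ≫ 10).
- **IVW**: weighted regression of β̂ᵧ on β̂ₓ through the origin with
  weights 1/σᵧ². The random-effects version inflates the fixed-effect
  SE by √max(1, Q/(k−1)) — multiplicative overdispersion, never
  deflation. This matches the convention of the standard two-sample MR
  tooling; an additive between-study variance (DerSimonian–Laird) would
  be the main alternative and gives similar inference at these ks.
- **Heterogeneity**: Cochran's Q over per-variant ratios with weights
  1/se_ratio², se_ratio = σᵧ/|β̂ₓ|; I² = max(0, (Q−(k−1))/Q)·100.
- **MR-Egger**: the same weighted regression with an intercept, after
  orienting every instrument so β̂ₓ ≥ 0 (the intercept is meaningless
  under arbitrary allele coding). Slope and intercept use a t reference
  with k−2 df and the same one-sided overdispersion inflation. A
  significant intercept indicates directional horizontal pleiotropy.
- **Weighted median**: the 0.5 quantile of the inverse-variance-weighted
  distribution of per-variant ratios, using the midpoint convention
  pⱼ = (Sⱼ − wⱼ/2)/S_total with linear interpolation. The SE comes from
  a seeded parametric bootstrap (default 1,000 resamples of each ratio
  from N(ratio, se_ratio), weights fixed); the point estimate is
  deterministic.
- **MR-PRESSO**: the observed weighted residual sum of squares of
  leave-one-out IVW predictions is compared against parametric
  simulations under the no-pleiotropy model (default 1,000); per-variant
  contributions give outlier p-values, Bonferroni-corrected across
  variants at α = 0.05. The outlier-corrected IVW estimate is reported
  only when at least one outlier is flagged.
- **MR-Steiger**: per-variant correlations from the t-statistic
  transform r = t/√(t² + n − 2), r² summed over instruments per trait;
  the forward direction is called when the instruments explain more
  variance in the exposure than the outcome, with a p-value from the
  difference of Fisher-z-transformed summed correlations. For binary
  outcomes the calculation runs on the observed log-odds scale, a
  pragmatic approximation.
- **Instrument strength / sample overlap**: per-variant F = (β̂ₓ/σₓ)²,
  set-level F their mean; *relative bias* = φ·(1/F) estimates the bias
  toward the observational association when a fraction φ of samples
  overlap between the two GWAS.

## Instrument selection and harmonization

Coordinates are 1-based with inclusive windows. Clumping is greedy:
candidates below the p-threshold are visited in ascending p (ties by
position, then id, for determinism) and accepted unless in LD
(r² ≥ threshold) with an accepted variant within the window. Variants
absent from the LD panel are treated as independent rather than
discarded; the harmonization log preserves auditability. Proxy search
returns the r²-maximal available variant (ties by genomic distance,
then id) and aligns the proxy's effect through the sign of the LD
correlation — a negative r implies the proxy's effect allele tags the
query's other allele. Palindromic (A/T, C/G) variants are retained only
when both allele frequencies fall outside [0.42, 0.58] and agree in
orientation; 0.42 is a conservative common default, chosen once. The
GRCh37 MHC region (chr6:28477797–33448354) is excluded from instrument
selection because of its extreme LD.

## Colocalization

Per-variant Wakefield log approximate Bayes factors,
log ABF = ½log(1−r) + ½z²r with r = W/(W+V), feed the five-hypothesis
enumeration (H0 none, H1/H2 single-trait, H3 distinct variants, H4
shared variant) under priors p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵. All hypothesis
arithmetic is in log space (log-sum-exp; the H3 cross term uses a
log-difference), since ABFs overflow doubles in strong regions. Prior
effect SDs default to 0.15 for quantitative traits and 0.2 (log-odds)
for binary traits, the cited defaults of the conventional
implementation. The model assumes at most one causal variant per trait
in the region.

## Fine-mapping

The sum-of-single-effects model is fitted on the z-score scale with the
standard summary-statistics approximation z ~ N(Rζ, R): L single-effect
components (default 5) are updated by coordinate ascent, each a
Bayesian single-effect regression on the residual z-scores with the
other components subtracted through R. Per-variant
PIP = 1 − Πₗ(1 − αₗ). Defaults: each component's prior effect variance
is estimated by maximizing its single-effect marginal likelihood (a
component whose estimate collapses to zero is treated as null and
yields no credible set); a fixed `prior_sd` can be supplied instead, in
which case, with L = 1, the PIPs reduce exactly to the normalized
single-variant Bayes factors. A ridge of 10⁻⁶ is added to the LD
diagonal; a matrix still non-PSD afterwards raises a conditioning error
advising a larger ridge. Credible sets are the smallest per-component
variant sets reaching 95% summed posterior mass, discarded when their
minimum absolute within-set LD falls below 0.5 (purity). Convergence is
declared when the maximum absolute PIP change between sweeps drops
below `tol` (10⁻⁶): with the residual variance fixed at one, the PIPs
are the quantity all downstream outputs depend on, so their
stabilisation is the natural stopping rule at these region sizes.

## Multivariable MR

Direct effects of E joint exposures are the weighted-least-squares
coefficients of β̂ᵧ on the E columns of exposure betas (no intercept,
weights 1/σᵧ²), with multiplicative overdispersion √max(1, Q/(k−E)).
Conditional instrument strength follows the Q-based construction: each
exposure's instrument betas are regressed on the other exposures'
betas; the residual heterogeneity, weighted by the delta-method
variance under the phenotypic correlation matrix (identity when not
supplied — the correlation is an input here, not estimated from summary
data), is scaled by k−E+1 to an F-statistic. Orthogonal, individually
strong exposures reproduce their unconditional F; collinear exposures
drop toward zero. Multivariable Egger (orientation on the first
exposure, shared intercept) is provided as a secondary method.

## The screen

Step-1 gates, in order: (1) IVW p below α/m with m the number of panel
proteins; (2) I² ≤ 50%; (3) Egger intercept p ≥ 0.05 (not applicable
below 3 instruments); (4) strict sign agreement of IVW, weighted
median, Egger slope and — only when outliers were detected — the
PRESSO-corrected estimate (a zero point estimate fails); (5) reverse MR
from the protein's cis-pQTLs to the exposure not significant (the
Bonferroni denominator is exposed as a parameter, defaulting to the
number of proteins entering the reverse analysis, since it is a
study-level choice); (6) the concordance-trait MR nominally significant
(p < 0.05) with the same sign. Step-2 gates: Bonferroni across the
proteins actually testable for the outcome (those retaining cis
instruments after the one-protein-per-variant exclusivity filter and
harmonization), Egger intercept when applicable, Steiger
directionality, and colocalization PP.H4 > 0.8 around the lead
cis-pQTL. Gates are conjunctive, so evaluation order cannot change the
final set; every gate decision is recorded with its statistic, and
unevaluable proteins appear in the ledger rather than being dropped.
The mediation sign condition requires β_step1·β_step2 > 0 for a
risk-increasing exposure; for a protective exposure the product must
instead share the total effect's sign. Sex-stratified analyses are the
same pipeline run on stratified inputs; there is no separate code path.

## The synthetic-data generator

`simulate` produces summary statistics directly at the summary level —
no individual-level genotypes — because the pipeline touches only
summary data and desk-scale speed matters. Defaults encode the study
conditions the screen is designed for:

| parameter | default | meaning |
|---|---|---|
| n_instruments | 100 | genome-wide exposure instruments |
| n_exposure / n_protein / n_concordance / n_outcome | 681,275 / 35,559 / 454,633 / 628,000 | GWAS sample sizes (the outcome value is the effective n of a large case-control study) |
| gamma_sd | 0.015 | SD of standardized instrument effects; gives per-variant z around 5–25 and mean F in the hundreds |
| theta1, theta2 | 0.3, 0.2 | true mediator effects (SD/SD and log-odds/SD) |
| balanced_pleio_sd | 0.004 | balanced pleiotropy scale (mean zero) |
| directional_pleio_mean, sd | 0.005, 0.002 | directional pleiotropy, applied relative to the exposure-increasing allele |
| phi | 0 | sample-overlap fraction; implemented by correlating the two GWAS' per-variant sampling errors, which reproduces the φ/F bias mechanism |
| cis_n_variants, cis_rho, cis_block_size | 200, 0.6, 25 | cis-region size and AR(1) LD (block-diagonal, PSD by construction) |
| cis_z_protein | 10 | planted causal pQTL z-score; with theta2 = 0.2 the implied disease z is ≈ 8 |

Marginal effects are the LD rotation of the joint effects
(z_marginal = Rζ) with sampling noise of covariance R; standard errors
are exactly 1/√(2f(1−f)n), so SEs, allele frequencies and sample sizes
are mutually consistent. Directional pleiotropy is planted relative to
the exposure-increasing allele: under an arbitrary allele coding a
fixed-mean offset would cancel once instruments are oriented on the
exposure, which is why that convention is used in pleiotropy
simulations generally. The end-to-end dataset mixes true mediators,
step-1-only proteins (θ₂ = 0), wrong-sign proteins (θ₁θ₂ < 0),
directional-pleiotropy violators and nulls (the screen-scale default
uses 100-variant cis regions to keep the combined LD panel small).

What the generator does **not** emulate: real human LD maps and
allele-frequency spectra, assay-specific measurement error,
population stratification, winner's-curse selection of published
instruments, multi-causal cis architectures, or trans-pQTL networks.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the stated model, not robustness to
every artefact of real consortium data.

## Verification and problem sizes

The test suite checks every estimator against an independent oracle
(normal-equation WLS for IVW/Egger/multivariable IVW at 10⁻¹⁰, an
exhaustive weighted-CDF scan for the weighted median at 10⁻¹²,
direct enumeration for the colocalization posteriors at 10⁻⁹, the
closed-form Bayes-factor normalization for L = 1 fine-mapping at 10⁻⁸)
and the pipeline's frequentist calibration by simulation: IVW 95% CI
coverage over 500 clean replicates, Egger-intercept type-I error over
1,000 balanced-pleiotropy replicates, colocalization and fine-mapping
recovery over 100–200 planted-causal regions, Steiger direction calls
over 200 replicates, and the 20-protein end-to-end screen (one
fixed-seed recovery run plus 100 global-null seeds). These sizes keep
the whole suite at a few minutes on one CPU while leaving the binomial
noise on each estimated rate well inside the asserted bands.
`scripts/acceptance.py` recomputes the same quantities from scratch
with all randomness derived from a single `--seed`.

## Limitations

- The Wald/IVW delta-method SEs ignore exposure-side sampling error
  (NOME approximation); with F in the hundreds this is negligible, but
  it would matter for weak instruments.
- Colocalization assumes a single causal variant per trait; regions
  with allelic heterogeneity can dilute PP.H4.
- The fine-mapper fixes the residual variance at one on the z scale and
  does not implement the out-of-sample-LD diagnostics needed when the
  LD panel mismatches the GWAS sample.
- The reverse-MR Bonferroni denominator and the concordance gate's
  nominal (rather than corrected) threshold are interpretable choices
  exposed as parameters rather than fixed constants.
- No mediation-proportion estimate is produced: the two-step design
  identifies mediators, not the fraction of the total effect they
  carry.
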