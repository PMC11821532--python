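# mrscreen

Two-step proteome-wide Mendelian randomization (MR) mediation screening
from GWAS summary statistics.

## The problem

Obesity raises the risk of cardiometabolic diseases, partly by changing
the levels of circulating proteins. Which proteins actually carry that
effect? With only GWAS summary statistics — per-variant effect sizes,
standard errors and p-values for an exposure (e.g. body-mass index), a
panel of thousands of plasma proteins, and disease outcomes — a two-step
MR design can screen the proteome for mediators:

1. **Step 1 (exposure → protein).** Genome-wide significant, independent
   variants (P < 5×10⁻⁸, r² < 0.001, 10-Mb clumping window, MHC region
   excluded) instrument the exposure. The random-effects
   inverse-variance weighted (IVW) estimator gives the primary effect
   β̂ = Σⱼwⱼβ̂ₓⱼβ̂ᵧⱼ / Σⱼwⱼβ̂ₓⱼ², wⱼ = 1/σᵧⱼ², and a battery of
   sensitivity filters guards the MR assumptions: Bonferroni
   significance across the panel, Cochran's Q / I² heterogeneity
   (I² ≤ 50%), the MR-Egger intercept test for directional pleiotropy,
   sign agreement across IVW / weighted median / Egger slope /
   MR-PRESSO-corrected estimates, reverse MR from the protein's
   cis-pQTLs, and directional concordance with a second adiposity trait.
2. **Step 2 (protein → disease).** Each surviving protein is
   instrumented by its cis-pQTLs (within 1 Mb of the gene's TSS, each
   variant a pQTL for exactly one protein), estimated by Wald ratio or
   IVW, and gated by Bonferroni correction, the Egger intercept (when
   ≥ 3 instruments), the MR-Steiger directionality test, and Bayesian
   colocalization: the posterior probability of a shared causal variant
   (PP.H4, priors p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵) must exceed 0.8 in the
   500-kb window around the lead cis-pQTL.

A protein is called a **mediator** when it passes every gate in both
steps and the sign condition β_step1 × β_step2 > 0 holds (for a
risk-increasing exposure). The package also provides summary-statistics
fine-mapping with the sum-of-single-effects model (PIPs and 95%
credible sets, up to L = 5 causal variants), multivariable MR with
conditional F-statistics for joint exposures such as fat and lean mass,
and the sample-overlap bias diagnostic *relative bias = φ/F* (φ the
overlapping-sample fraction, F the instrument F-statistic).

Real consortium GWAS are not required: `mrscreen.simulate` generates
summary statistics with known causal ground truth — polygenic exposure
instruments, cis regions with AR(1) LD, mediated / pleiotropic / null
proteins, shared vs distinct causal variants, and correlated sampling
errors emulating sample overlap — so every stage is testable at desk
scale.

## Worked example

```bash
python examples/full_screen.py
```

generates a 20-protein panel with 3 planted mediators (true effects:
exposure→protein 0.3 SD/SD, protein→disease log-odds 0.2 per SD, one
shared cis causal variant) and runs the whole screen:

```
final calls by outcome:
  mediator                            3
  rejected:mediation_sign             3
  rejected:step1_bonferroni           7
  rejected:step1_egger_intercept      2
  rejected:step2_bonferroni           5

mediators called (vs planted truth):
  P001: step1 beta = +0.312, step2 OR = 1.17 (wald_ratio), PP.H4 = 1.000, truth = mediator
  P002: step1 beta = +0.256, step2 OR = 1.23 (wald_ratio), PP.H4 = 1.000, truth = mediator
  P003: step1 beta = +0.268, step2 OR = 1.28 (wald_ratio), PP.H4 = 1.000, truth = mediator
```

Exactly the three planted mediators survive: the seven null proteins
fail the Bonferroni gate, the directional-pleiotropy violators fail the
Egger intercept gate, the step-1-only proteins (no disease effect) fail
the step-2 significance gate, and the wrong-sign proteins fail the
mediation sign condition. `step1 beta` is the IVW estimate of the
exposure's per-SD effect on the protein; `step2 OR` is the
per-SD-of-protein odds ratio on the disease; `PP.H4` is the shared-
causal-variant posterior. Other examples cover the single steps:
`step1_mr_estimators.py`, `colocalization.py`, `fine_mapping.py`,
`multivariable_mr.py`.

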