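# Methods

This note documents the models, estimators and numerical choices behind
`icefalcon`, and what the synthetic-data validation does and does not show.

## Risk-score construction

Raw mammographic measures are right-skewed, so each is first carried to an
approximately normal scale by a one-parameter power transform
`(v + shift)^λ` (log for λ = 0).  The exponent can be profiled from the data
— the Box–Cox profile log-likelihood is scanned on a λ grid over [−2, 3] in
steps of 0.05 and the maximizer refined by bounded scalar optimization
(`scipy.stats.boxcox_llf` + `scipy.optimize.minimize_scalar`, xatol 1e-6) —
or forced to a known value.  The analyses of record use the forced published
exponents (cube root for the light and bright areas, fifth root for the
brightest areas, a shifted square for Cirrus with shift −2907); profiling at
n ≈ 700 recovers exponents only loosely when the data sit far from the
origin (the transform family is weakly identified there), which is why
forcing is the default for replication-style runs.

The transformed measure is then regressed on an intercept plus age at
mammography (plus, for "not through the third score" analyses, the third
risk score) by OLS on individuals; the residuals, scaled to SD 1 (n−1
denominator, configurable) and re-centred, are the risk scores.  OLS on
individuals ignores pair clustering deliberately: the residuals are
identical either way, and clustering is handled downstream.  Incomplete
pairs are dropped and counted.

## Correlation structure

Pair-level statistics use double entry (each pair contributes both
orderings), which makes them invariant to twin labelling.  Fisher-z 95%
intervals use the number of *pairs* as the effective n by default, because
the double-entered rows duplicate information; the double-entry n convention
is available as an option.  The choice matters: intervals computed on 2n are
√2 narrower than the pair-level sampling spread, and the acceptance suite's
structural-emulation check is sensitive to exactly this (see Limitations).

## The three-model procedure and its estimands

All three models are Gaussian marginal regressions with identity link on the
double-entered design, clusters = pairs, robust sandwich SEs.  The engine is
an in-package vectorized solver specialized to two-row clusters (validated
against `statsmodels` GEE to ~1e-8); the specialization is what makes a
cluster bootstrap with thousands of refits, and oracle checks at 50,000
pairs, affordable.

**Working correlation.**  The default is *independence*: point estimates are
the marginal projection coefficients — covariance ratios for Models 1–2, the
2×2 normal equations for Model 3 — with cluster-robust inference.  This is
the estimand the path-tracing decomposition is derived for, and it
reproduces the reported study coefficients closely (the calibrated
population model predicts the light→bright row as 0.810 / 0.520 / 0.772 /
0.065 with Pr = 0.90, against reported 0.802 / 0.513 / 0.770 / 0.070 and
89%).  An *exchangeable* working correlation is available but is not the
default for two reasons established during development:

1. Models 1–2 are deliberately misspecified mean models (the true
   conditional mean involves both twins' predictors), so their
   exchangeable-GEE population limit is a fixed point
   β = (target − αc)/(1 − αρ_x) in the residual within-pair correlation α —
   not a covariance ratio.  The shift grows with the traits' residual
   correlation and, for strongly cross-correlated traits, pushes the
   population Pr outside [0, 1]; the decomposition's interpretation then
   fails *in population*, not just in samples.
2. Under a misspecified mean model the estimand depends on α, so the
   variability of α̂ propagates into β̂; the standard sandwich (α treated as
   fixed) can understate the true sampling SD of the Model 1/2 coefficients
   by a factor >2.  The pair bootstrap captures the full variability
   (`bootstrap_triplets`), and the oracle-equivalence tests use bootstrap
   SDs as the Monte-Carlo scale for exactly this reason.  Model 3 is
   correctly specified and unaffected by either issue.

Both estimands have exact closed-form population values in
`theoretical_coefficients` (`working="independence"` / `"exchangeable"`).

**Change significance.**  The p-values for the Model 1/2 → 3 coefficient
changes come from a pairwise cluster bootstrap: pairs resampled with
replacement (default B = 1000, seeded), all three models refitted per
replicate via multiplicity-weighted sufficient statistics, two-sided p from
the normal approximation with the bootstrap SE.  Replicates whose resampled
predictor has near-zero variance are dropped and counted (error above 5%).
Under independent traits with within-pair correlations like the study's
extremes (0.59 and 0.22) the p-values are well calibrated (rejection
fraction 0.049 at the 5% level, KS p ≈ 0.4 over 1000 runs of 500 pairs).

**Decomposition and decision rules.**  Pr is computed at full precision on
the fraction scale and only rounded to integer percent in formatted output;
values outside [0, 1] are flagged, never clamped.  A direction is labelled
*causation* when the co-twin coefficient is nonzero, attenuates
significantly toward zero under mutual adjustment, and the self coefficient
is stable; *familial confounding* when both attenuate significantly and the
proportional changes agree within a tolerance (0.25, config-exposed — the
source material states no numeric criterion); *combination* when both
attenuate but the self change is proportionally smaller; *no evidence* when
the co-twin coefficient is null; anything else — notably coefficients that
*increase* under adjustment, seen in several reversed assignments — is *not
consistent with causation* and never contributes a Pr to the summary.  ρ in
the Pr formula is the double-entry within-pair correlation of the (possibly
third-score-adjusted) predictor score.  Nominal significance is 0.05 with no
multiplicity correction, matching the analysis style the package reproduces;
a conditional variant (co-twin's outcome as covariate) exists behind a flag.

## The synthetic twin model

Each individual's trait vector solves T = BT + u with B the directed
within-individual causal paths (bidirectional pairs allowed; the reduced
form (I − B)⁻¹ must exist, i.e. spectral radius of B < 1) and u the sum of a
trait-specific pair-shared component, pair-shared latent confounders with
per-trait loadings, and an individual-specific component.  Twins are
exchangeable; no path crosses twins.  Age is drawn once per pair, uniform on
40–70 years, and enters each trait linearly on the latent scale before the
inverse power transform maps to the raw scale; slopes are sized so age
explains ~2% of the light-areas variance and ~8–10% of the others, inside
the reported 2–11% band.

The shipped four-trait configuration (`presets.calibrated_config`) is calibrated
so its population correlation matrices equal the reference structure
*exactly*: with path coefficients on the seven inferred causal edges solved
(least squares, residual ~5e-8) so that the implied individual-specific
shock covariance is exactly diagonal, the pair-shared covariance decomposes
by Cholesky into four latent confounders.  Raw-scale locations and scales
come from the reference quartiles of the raw measures (e.g. light areas
median ≈ 17.4 cm²; Cirrus ≈ 2910 on its native scale).  The Cirrus inverse
transform has a ~3σ positivity margin, so roughly one latent draw per
740-row dataset is clamped at the domain edge; clamped counts are recorded
in `frame.attrs["n_clamped"]`.

**What the simulator does not emulate.**  Real mammographic data have
direction-asymmetric regression coefficients (the reported bright→light row
differs from light→bright beyond what any exchangeable-moment model can
produce), measurement error with structure beyond additive unique variance,
DZ pairs, and non-Gaussian tails.  Passing tests therefore show that the
estimators recover the population quantities of this linear-Gaussian family,
not that the method is robust to those features.

**Parameter recovery.**  "True causal fraction" is defined as the population
Pr of the moment oracle — the quantity the estimator converges to — and
recovery configurations are solved by root-finding on the path coefficient
so population Pr ∈ {0, 0.25, 0.5, 0.75, 1} (the f = 1 point uses the
pure-causation structure, where Pr = 1 holds identically).  The structural
fraction b/(b+m) differs from Pr by a factor 1 + m(1−ρ)/((1+ρ)(b+m)) when
ρ < 1; the decomposition estimates Pr, not that fraction.

## Problem sizes and tolerances

Oracle-equivalence and recovery checks run at 50,000 pairs (Monte-Carlo SDs
~0.003 for coefficients, ~0.013 for Pr) with bootstrap B = 150; null
calibration uses 1000 runs of 500 pairs with B = 200; study-scale checks use
371 pairs.  Fixed seeds make every stochastic test reproducible.  GEE
fixed-point iteration converges to 1e-10 (up to 500 iterations; convergence
is linear and can be slow when the working correlation is large).

## Known limitations

* The package infers, from coefficient patterns, *consistency with*
  causation under the assumption that all confounding is fully pair-shared;
  non-shared confounding is indistinguishable from causation here, exactly
  as in the underlying method.
* With the exchangeable option, the change statistic degenerates when the
  residual correlation α approaches the predictor's within-pair correlation
  (Model 1 then coincides with Model 3's self column identically), and
  normal-approximation change p-values become badly conservative; the
  independence default cannot degenerate this way.
* The structural-emulation acceptance check asks sample within-pair
  correlations at 371 pairs to fall inside reference intervals whose widths
  match a double-entered-n convention; the pair-level sampling SD
  ((1−r²)/√371 ≈ 0.034) is √2 wider than those intervals assume, so the
  observed ~82–88% coverage per trait is the mathematically expected
  ceiling, not an estimator defect.  The corresponding test is left failing
  as a faithful record of that tension.
* Percent-density stratified analyses partition pairs by the pair-mean
  stratifier at the median; with 371 pairs each stratum is small and
  per-stratum Pr estimates are noisy (SE ~0.15).
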