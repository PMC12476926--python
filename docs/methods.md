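# Methods

This note records the statistical models implemented by `itvar`, the
choices made where conventions were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## The ITV* statistic

ITV is defined as the population (denominator-*n*) variance of
natural-log trait values of one species within a site, or pooled
across sites; ITV* multiplies by n/(n−1), making it the ordinary
unbiased sample variance of the logs.  Natural logarithms are used
throughout; the base only shifts log ITV* by a constant that is
absorbed by model intercepts.  Working on logs makes the statistic
invariant to trait rescaling and identical for a trait and its
reciprocal.

**Inclusion filter.** Variance estimates from tiny cells are
unstable, so a species×site cell enters the analysis only with at
least `min_per_site` individuals, and a species only with at least
`min_sites` qualifying cells.  The defaults (6 and 4) encode strict
readings of "more than 5 individuals" and "more than 3 sites"; both
thresholds are arguments, so the inclusive readings (5 and 3) are one
keyword away.  A species' site count is tallied over qualifying cells
only — cells below the per-site minimum cannot contribute a reliable
ITV, so they should not help a species qualify.  Cells whose values
are all identical (zero variance, log undefined) are dropped with a
warning; with continuous measurement data this is a measure-zero
event.

## Environmental variability metrics

**Terrain roughness index (TRI).** Per DEM cell, the mean absolute
elevation difference to its valid 8-neighborhood; the site value is
the mean over valid cells.  Several TRI conventions circulate
(root-sum-of-squares, max-min); the mean-absolute-difference form is
used here and stated in the API docs.  Edge cells average over their
existing neighbors only — no padding — so a constant grid is exactly 0
and an interior cell of a ramp rising s per cell along one axis is
0.75·s (six neighbors differ by s, two by 0).  Nodata cells are
excluded from both the neighborhoods and the site mean.

**Rainfall seasonality.** 100 × (sample standard deviation / mean) of
the twelve mean monthly precipitation totals.  The n−1 standard
deviation is used, consistent with the Bessel convention elsewhere in
the package.

**Range breadth.** The width between the 2.5th and 97.5th percentiles
of an attribute over a species' occurrence records, with
linear-interpolation quantiles (the default of mainstream statistics
stacks).  This reads "95% interval" as a central quantile range —
consistent with "range" semantics and directly recoverable from
simulated uniform niches (0.95 × niche width) — rather than a
parametric confidence interval of the mean, which would shrink with
record count.  Duplication of the whole record set leaves the widths
unchanged; at least two finite values per attribute are required, and
species failing that are excluded with a warning.

A packaged eight-site table (`itvar/data/table1_sites.csv`) provides a
realistic site-environment fixture: mean annual precipitation
1039–2351 mm, elevations 82–1091 m, rainfall CV 27–59%, mean terrain
roughness 2.85–7.12.

## Hierarchical random-slope model (within-site ITV)

The response is log ITV* per species×site cell; the predictor is one
site-level variability metric, z-scored across the distinct site
values (sample sd).  Standardizing over sites rather than design rows
keeps the predictor scale independent of which species happen to
occupy which sites, which in turn makes the generator's truth slope
and the model's estimand coincide exactly in recovery tests; for a
balanced design the two conventions agree.

    log ITV*_si,sp = β₀ + β₁,sp + β₂,sp·env_si + ε/n_si,sp,
    β₁,sp ~ N(μ₁, σ₁),  β₂,sp ~ N(μ₂, σ₂),  ε ~ N(0, τ),
    priors  σ₁, σ₂, τ ~ U(0, 10);  β₀, μ₁, μ₂ ~ N(0, 1).

**Residual scaling.** Dividing the residual draw by the sample size
gives each row a residual sd of τ/n (`error_scaling="sd_over_n"`, the
default, read literally from the model statement).  The alternative
reading — residual *variance* proportional to 1/n, i.e. sd τ/√n, the
convention of a mean of n observations — is available as
`"sd_over_sqrt_n"`; the generator honours the same switch, so
recovery is well-posed under either convention.  Under the default,
the large-data limit of the posterior is weighted least squares with
weights n², which is verified against an independent WLS solve.

**Identifiability.** β₀ and μ₁ enter the likelihood only through
their sum.  By default β₀ ≡ 0 and the species intercept is
parameterized as μ₁ + δ_sp, δ_sp ~ N(0, σ₁), so the reported
"intercept" is μ₁; `include_beta0=True` restores the literal
double-intercept form for sensitivity checks (β₀+μ₁ is invariant, and
tests confirm the two parameterizations agree on it).

**Sampler.** Blocked Gibbs with exact conditionals: given the scales,
(μ₁, δ₁) is jointly Gaussian with an arrow-shaped precision, so μ₁ is
drawn from its marginal conditional (deviations integrated out) and
the deviations given μ₁ — likewise (μ₂, δ₂).  This joint block is what
makes the chains mix; one-at-a-time updates crawl along the ridge
between a hypermean and the mean of its deviations.  Given the
locations, each scale's square is inverse-gamma (the U(0, b) prior on
the sd contributes a (σ²)^(−1/2) factor and truncation at b²),
sampled by rejection against the untruncated draw with an
inverse-CDF fallback when the bound binds.  Defaults are 4 chains ×
2,000 iterations with the first half discarded; chains start from
data-informed, overdispersed points; per-chain seeds derive
deterministically from one model seed.  Split-R̂ (via ArviZ) is
attached to every summary, and a fit warns — never fails — when any
R̂ exceeds 1.01.  No tuning parameters exist; all conditionals are
exact.

**Classification.** The community slope μ₂ and each species slope
β₂,sp = μ₂ + δ₂,sp are labelled positive/negative/nonsignificant by
whether the central credible interval (default 95%) excludes zero.

## Range-breadth regression (across-site ITV and mean traits)

One row per species; predictors standardized to mean 0, sd 1 (n−1
sd), with back-transform parameters retained.  The model is Gaussian
linear regression fitted by Gibbs (coefficients given σ² are
Gaussian; σ² given coefficients is inverse-gamma under a Jeffreys
prior), with independent N(0, (2.5·sd_y)²) priors on slopes and a
flat intercept — weak enough that ordinary least squares is the
testable limit (verified to 0.02 on random designs).  MAP range is
computed and available as a predictor but excluded from the default
set; the predictor list is configuration.

**AIC.** 2k − 2·logLik with the Gaussian log-likelihood evaluated at
the posterior-mean coefficients and the maximum-likelihood residual
variance; k counts slopes + intercept + residual sd.  This reproduces
the classical AIC of a least-squares fit in the weak-prior limit.

**Selection.** Greedy backward elimination: fit every
single-predictor removal, accept the one that lowers AIC most, stop
when none does.  The trace records every candidate AIC, including the
leave-one-out AICs of the final model.  Each predictor subset's fit
seed derives deterministically from the subset itself, so the greedy
path and the exhaustive all-subsets cross-check (available for ≤ 8
predictors) score identical subsets identically, and any disagreement
between them is a genuine path effect, not Monte-Carlo noise.  Greedy
AIC keeps a pure-noise predictor with asymptotic probability
P(χ²₁ > 2) ≈ 0.16 — AIC is not selection-consistent — so "the final
model is exactly the active set" holds only stochastically; what the
package guarantees, and tests, is that the final AIC never exceeds
the full model's and that truly active predictors are retained with
intervals excluding zero.

Significance is evaluated at 90% credible intervals with 95% also
emitted.  The mean-trait variant reuses the identical design and
selection machinery with the species mean of log trait values as the
response; the mean-vs-ITV check is a Pearson correlation (t-based
p-value, n−2 df) between species-level pooled mean log trait and log
across-site ITV*, following the species-scale reading of that
comparison.

## Synthetic data

`simulate_traits` mirrors the hierarchical model generatively:
species intercept/slope deviations from their hyperdistributions, a
per-cell true log ITV* including the ε/n residual, then n individual
log-trait values drawn with exactly that variance and exponentiated.
Defaults emulate the study design: 8 sites, 33 species, per-cell n ~
Poisson(12) truncated at 6, species present at a random ≥ 4 of the
sites, μ₁ = −3 (log-trait variances of a few percent), σ₁ = 0.3,
σ₂ = 0.2, τ = 0.5.  Species mean log-traits are N(0, 1) nuisance
draws; they cancel from every ITV quantity.  Site predictor values
are standardized inside the generator with the same convention the
model applies, so the truth slope is on the model's scale.

Because individuals are drawn at finite n, the *empirical* log ITV*
adds χ² sampling noise (sd ≈ √(2/(n−1))) on top of the model's ε/n
term.  Sampler-validation tests therefore fit the per-cell *true* log
ITV* from the truth record (`design_from_truth`) — the exact
generative inverse of the fitted model — while pipeline tests run on
the individual-level data.  Passing recovery tests consequently
demonstrates correctness of the sampler and machinery, not that 8
sites × 33 species has power to detect any particular effect in the
field, and none of the generators emulate spatial autocorrelation,
measurement error, or non-lognormal trait distributions.

`simulate_coupled_itv_range` draws species niche widths first,
builds the species-level response from the standardized true widths
plus noise, and allocates individuals across sites with matching
pooled variance, so the full occurrences→ITV→selection path has a
known answer.  `simulate_dem` provides constant, ramp and iid-noise
grids whose TRI has closed-form expectations (0, 0.75·slope,
2·sd/√π); `simulate_monthly_precip` hits a target CV exactly by
affine rescaling, falling back to a log-scale spread solved by root
finding when the target would force negative months.

All randomness flows from one master seed through named substreams
(component-indexed `SeedSequence` spawn keys); derived seeds stay
below 2³¹.

## Problem sizes and numerical choices

Recovery and calibration checks use 30 species × 8 sites with 4×2,000
(recovery) or 2×800 (calibration replicates) MCMC settings; selection
cross-checks use 120 observations × 5 predictors; the end-to-end
range-breadth scenario uses 200 species × 300 occurrence records.
These sizes give stable Monte-Carlo behaviour while keeping a full
validation pass in minutes on one core.  Degenerate inputs fail loud
and early: non-positive trait values, constant predictors, singular
designs, all-nodata grids and zero-mean rainfall all raise named
errors rather than propagating NaNs.  Ties in backward elimination
break alphabetically for determinism.  Pipeline outputs are written
with fixed float formatting and no timestamps, so a rerun with the
same configuration and seed is byte-identical.

## Known limitations

* The residual-scaling convention (τ/n vs τ/√n) changes the effective
  weighting of small vs large cells; both are implemented, but field
  data cannot arbitrate between them from within this package.
* With 8 sites, any site-level predictor correlates appreciably with
  any other by chance; separate single-predictor models (as fitted
  here) cannot attribute an effect between correlated site variables.
* The uniform(0, 10) prior bound on σ₁, σ₂, τ is assumed generous; for
  responses on very different scales it should be revisited.
* Greedy backward AIC selection can, in principle, miss the best
  subset under strong predictor correlation; the exhaustive
  cross-check covers ≤ 8 predictors.
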