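# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `rainwin`.

## The data model

The unit of community analysis is the **plot-year**: taxon counts are
summed over a year's trapping rounds (removing intra-seasonal
variability) and vegetation covariates take the per-parameter maximum
over the year's surveys. The unit of the moving-window analysis is the
**round** (plot x year x trapping round), which preserves the temporal
resolution the window scan needs. Taxa enter the analysis only if they
are predominantly ground-dwelling and total at least 50 individuals
over the whole study (strictly fewer than 50 excludes; exactly 50
keeps). "Seasonal rainfall" is the Feb 1 - Mar 31 cumulative total —
calendar months were chosen because the growing-season definition gives
no day bounds. Empty (all-zero) plot-year rows are dropped from the
site-taxa matrix with a warning rather than raising, since drought
years plausibly produce near-empty traps.

## NB random-intercept GLMM

All count models are negative binomial with log link and the
mean-dispersion parameterization Var(y) = mu + mu^2/theta, with a plot
random intercept and, by default, year as a centred numeric covariate.
Year as a 6-level factor is available (`year="factor"`) for models in
which rainfall varies within a year; it is rejected with an explicit
error where it would alias a covariate constant within year (seasonal
rainfall in the cascade models).

The marginal likelihood integrates the random effect per plot. The
conditional log-density in b is strictly concave, so its mode is found
by damped Newton iteration; the integral is then evaluated by adaptive
Gauss-Hermite quadrature centred at the mode and scaled by the
curvature. One node (the default) is the Laplace approximation; on
study-sized data the Laplace and 9-node log-likelihoods agree to well
under 0.1%. With sigma at its lower bound the marginal likelihood
reduces *exactly* to the independent NB likelihood, which is the
oracle-agreement route the tests exercise against `statsmodels`.

Optimization is L-BFGS-B over (beta, log theta, log sigma) with
numerical gradients, started from a Poisson GLM plus a moment estimate
of theta; a perturbed start is used as a fallback when the first start
fails. theta above e^11 is flagged as the Poisson limit. Wald SEs come
from the inverse observed information of beta at the optimum (theta and
sigma held fixed, as in `lme4`). Design rows are canonically sorted, so
estimates are bit-identical under input row permutations. Because fixed
effects are located to numerical-gradient precision, quantities such as
z are reproducible to about 1e-4 under covariate rescaling (P and R^2
to 1e-6).

**Adjusted R^2.** The fixed-effects R^2 is a deviance ratio,
R^2 = 1 - D_full/D_null, with both deviances evaluated at
population-level fitted means (random effect at zero) under the full
model's theta, and the null model being intercept-only with the same
random structure; the small-sample adjustment is Ezekiel's
1 - (1-R^2)(n-1)/(n-p-1). Any monotone-equivalent definition yields the
same window-scan argmax, which is all the scan uses R^2 for; numerical
equality with other software's R^2 variants is not claimed. In the scan,
the null excludes the year term, so year's explanatory share is part of
every cell equally — a flag-free choice that leaves the argmax
untouched.

## The moving-window scan

Windows of width w in {7, 14, 30} days are slid over offsets k = 0..30
days before the trap start; the covariate sums rainfall over days
t0-k-w .. t0-k-1. Offset 0 therefore means "the window ends the day
before the traps open"; rain falling during the (roofed) trapping week
is never counted, because the scientific question is antecedent
rainfall. The windowed covariate is z-scored per cell for numerical
stability (R^2 and z are invariant to this). Cells whose GLMM does not
converge are retained in the profile but flagged and excluded from the
argmax and plateau; the plateau is the maximal contiguous run of
offsets, containing the argmax, whose R^2 stays within 95% (config-
urable) of the width's maximum. Adjacent cells warm-start each other,
which roughly halves the scan time. Ties between widths are broken
toward the smaller width. Plant cover runs through the same machinery
as pseudo-counts (percent x 10, rounded), using per-round cover values.

## Ordination

Taxon columns are scaled to unit sum of squares before Bray-Curtis.
(The alternative reading of "normalize by the margin" — row scaling —
is available by flag; column scaling is the default because taxon
magnitudes differ by orders of magnitude.) NMDS minimizes Kruskal
stress-1 by alternating isotonic regression of configuration distances
on the dissimilarity ranks (SciPy's PAVA, ties averaged within blocks)
with Guttman-transform updates, keeping the best configuration per
restart; disparities are rescaled to the configuration's sum of squares
each iteration to prevent collapse. The first restart starts from
principal coordinates, the rest from seeded Gaussian configurations;
convergence is declared when another restart matches the best solution
with Procrustes correlation >= 0.999, and the final scores are centred
and rotated to principal axes. envfit uses 1000 permutations by
default, PERMANOVA 999 (both configurable); all permutation p-values
use the add-one convention and can never be exactly zero. PERMANOVA
uses sequential (Type-I) sums of squares, so term order matters and is
taken from the caller in the listed order (year first by default);
the decomposition satisfies sum(R^2) = 1 to machine precision, and on
univariate Euclidean distances the pseudo-F equals the classical ANOVA
F exactly.

## The synthetic generator

The generator is the package's stand-in for the unpublished field data
and defines the study conditions; its defaults were chosen once, to be
realistic for the emulated system, and the planted parameters are
returned as ground truth.

* **Rainfall.** Per calendar year a seasonal (Feb-Mar) total is drawn
  log-normally with mean 56 mm and CV 1.07 (the CV implied by the
  study's published mean +/- SE over six years, 56 +/- 24.5). The total
  is disaggregated into gamma-magnitude events on days drawn from a
  weight curve peaking in late February (dry May-September), then
  quantized to the 0.5 mm gauge grid by largest-remainder allocation so
  the seasonal total is preserved exactly. The record covers one year
  before the first study year so every window has history.
* **Design.** 30 plots, years 2013-2018, two rounds per year: round 1
  in the first half of March, round 2 at least 14 days later, plus a
  0-2 day per-plot setting order (the same shift for both rounds, so
  the 14-day interval survives). Whole plot-years drop out at rate
  0.12, floored at 15 plots per year, reproducing unbalanced panels
  with N between 20 and 29.
* **Latent cascade.** Each group's per-round log-mean is
  alpha_g + gamma_g * z(log1p W_g) + links * (parent latents, centred)
  + plot intercept + year deviate, where W_g is the 7-day rainfall sum
  ending lag_g days before the trap start (lags: plants 8, herbivores
  15, predators 15, detritivores 15, omnivores 24; ants none). The
  driver is log1p-transformed — a saturating response — because a
  linear-in-mm driver under a CV-1.07 seasonal distribution produces
  biologically absurd count explosions in wet years. Links act on
  latent expected abundances (not realized counts), keeping the cascade
  acyclic and noise-separable: plants -> herbivores, plants+herbivores
  -> omnivores, herbivores+omnivores+detritivores -> predators,
  herbivores -> ants, and gravel suppresses plants. Plants additionally
  carry a per-plot-round latent "patchiness" deviate (SD 0.6) emulating
  microhabitat vegetation variation beyond the measured drivers; it
  propagates up the cascade and is what makes the bottom-up links
  identifiable over and above rainfall — without it, the gravel, plot
  and year channels are absorbed by the cascade models' own covariates
  and random effects. Counts are NB per taxon (fixed within-group
  shares); cover is gamma-distributed around its latent mean, reported
  on a 0.1-50% scale.
* **Effect sizes.** The defaults (e.g. gamma = 1.1 for the herbivores'
  direct response, 0.7 for the plant link) were set by a design sweep
  so that the generator's stated recoverability properties hold
  simultaneously at the study's size: the herbivore scan argmax lands
  within +/-3 days of the true lag in >= 90% of studies, the 7-day
  width out-explains the 30-day width, and the plant-herbivore link is
  detected in >= 90% of studies. They were frozen before the acceptance
  checks were finalized and are deliberately on the strong side of
  realistic: the generator's job is to make every downstream stage
  testable.
* **What passing tests do and do not show.** The generator reproduces
  the design's structure (seasonality, overdispersion, unbalanced
  panels, rare taxa, a non-ground-dwelling taxon) but not every feature
  of real communities: no temporal autocorrelation beyond the plot
  intercept, no zero-inflation, no taxon-level lag heterogeneity within
  groups, no spatial structure among plots, and observation noise on
  cover that is independent across rounds. Recovery results on
  synthetic data therefore demonstrate the correctness and power of the
  machinery under the planted model, not field-data effect sizes.

## Problem sizes used in the checks

The shipped test suite and acceptance script run the full study size
(30 plots x 6 years x 2 rounds) wherever a single fit or scan is
involved, and scale replicate counts to what a desk machine runs in a
few minutes: 20 replicate studies for window recovery, 30 for the null
calibration of envfit (20 for the cascade), 200 replicates for
variance-component recovery, 500 for the envfit null-rate check. These
sizes were chosen as the package's own verification budget.

## Known limitations

* Laplace (1-node) likelihoods are slightly biased for very small
  theta with few observations per plot; the node count is configurable
  where that matters.
* The adjusted-R^2 definition is one of several in circulation;
  comparisons across software should use the argmax, not the value.
* The screen's "longer gradient, better distribution" preference is
  operationalized as range, then |skewness|, then name — deterministic
  and order-independent, but a qualitative judgement in the original
  workflow.
* PERMANOVA uses raw (unrestricted) permutations; restricted
  permutation schemes for repeated measures are out of scope.
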