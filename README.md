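# rainwin

Critical-rainfall-window and multi-trophic cascade analysis for
arid-savannah arthropod communities.

In arid ecosystems, rainfall arrives in short erratic pulses, and the
biological response — a flush of annual vegetation, then waves of
herbivorous, detritivorous, omnivorous and predatory arthropods — is
lagged and trophically structured. Pitfall-trap studies measure this as
*activity density* (individuals caught per trap per round). Two
questions recur in such studies: *when* does rain matter (which window
of antecedent rainfall best explains each group's activity), and
*through which paths* (directly, or bottom-up via plants and prey)?

`rainwin` packages the full analysis chain for a multi-year, multi-plot
pitfall design, together with a seeded synthetic-data generator that
emulates the design of a six-year study in a Namibian arid savannah
(30 plots of 2 m x 2 m, two trapping rounds per year in March-early
April at least 14 days apart, daily rainfall with a February-March
maximum, per-plot soil surface texture, taxon counts classified into
herbivores / omnivores / predators / detritivores / ants). Because the
generator plants known lags, link coefficients and variance components,
every stage of the pipeline is testable end to end without field data.

## What it computes

1. **Collinearity screen** — pairwise Spearman rank correlations of the
   environmental covariates; pairs with |r_s| > 0.7 are pruned by a
   deterministic longer-gradient preference rule.
2. **Community ordination** — taxon columns scaled to unit sum of
   squares, Bray-Curtis dissimilarity, 2-D non-metric MDS minimizing
   Kruskal stress-1 (isotonic regression + Guttman updates, 20
   restarts), environmental vectors fitted by least squares with
   1000-permutation tests, and sequential-SS PERMANOVA
   (Gower-centred G = -1/2 J (D∘D) J, pseudo-F by site-label
   permutation).
3. **Moving-window scan** — for window widths w in {7, 14, 30} days and
   offsets k = 0..30 days before the trap start, the covariate
   W(t0; w, k) = sum of daily rainfall over days t0-k-w .. t0-k-1 enters
   a negative-binomial random-intercept GLMM

        y ~ NB(mu, theta),  log mu = b0 + b1 W + b2 year + u_plot,
        u_plot ~ N(0, sigma^2),

   and the fixed-effects adjusted R^2 is profiled against (w, k); the
   argmax locates each group's *critical window*.
4. **Trophic-cascade suite** — six NB mixed models (plants, herbivores,
   omnivores, predators, detritivores, ants) with bottom-up covariate
   sets (plants get rainfall and soil; consumers additionally get their
   resources; covariates not in a model are "NT"), rendered as a signed,
   starred summary table.

The NB mixed models are fitted by marginal maximum likelihood with the
random-effect integral evaluated per plot by adaptive Gauss-Hermite
quadrature (default one node, i.e. the Laplace approximation); the
engine agrees with independent NB regression exactly when sigma = 0 and
with `glmmTMB`-style fits to several decimals.

## Worked example

```python
import warnings
from rainwin import SimConfig, gen_study, scan, fit_cascade
from rainwin.cascade import render_text
from rainwin.cli import prepare_tables

bundle, truth = gen_study(SimConfig(seed=42))
retained, records, matrix, rounds = prepare_tables(bundle)

profile = scan(rounds, bundle["rainfall"], "herbivore", widths=(7, 30))
print(f"true lag: {truth.true_lags['herbivore']} d")
print(f"7-day window argmax: {profile.argmax[7]} d before trapping")
print(f"max adjusted R2: width 7 = {profile.max_r2(7):.2f}, "
      f"width 30 = {profile.max_r2(30):.2f}")
print(render_text(fit_cascade(records)))
```

prints

```
true lag: 15 d
7-day window argmax: 15 d before trapping
max adjusted R2: width 7 = 0.52, width 30 = 0.35
                    plants herbivores omnivores predators detritivores ants
seasonal_rainfall  0.29***    0.60***   0.85***     0.19*          n.s  n.s
gravel            -0.38***     -0.18*    -0.14*       n.s          n.s  n.s
cobble                 n.s        n.s       n.s       n.s          n.s  n.s
plants                  NT    0.29***   0.39***        NT          n.s  n.s
herbivores              NT         NT       n.s   0.38***           NT  n.s
omnivores               NT         NT        NT    0.26**           NT   NT
detritivores            NT         NT       n.s     0.11*           NT  n.s
```

The scan recovers the planted 15-day herbivore lag, the 7-day window
out-explains the 30-day window, and the cascade table shows the planted
bottom-up links (plants -> herbivores -> omnivores/predators) as
positive starred cells while untested covariates stay `NT`.

The same pipeline runs from the shell:

```sh
rainwin simulate --seed 1 --out study/
rainwin run-all --seed 1 --out results/        # simulate + screen + ordinate + scan + cascade
rainwin scan --traps study/traps.csv --rain study/rainfall.csv \
             --taxa study/taxa.csv --veg study/veg.csv --soil study/soil.csv \
             --groups herbivore,detritivore --out scanout/
```

`run-all` writes a reproducibility manifest (config hash, per-stage
seeds, file digests); rerunning with the same seed reproduces every
output byte for byte. `examples/config.yaml` shows the configurable
knobs.

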