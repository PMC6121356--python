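# greenwalk

Eye-level urban greenness exposure and multilevel models of walking
behavior, on a fully synthetic, reproducible pipeline.

## The problem

Most population studies measure a neighbourhood's greenness from overhead
(park area, tree counts, satellite NDVI), but what residents actually
experience is the vegetation visible at eye level from the street.  A
street-imagery approach samples points along street centerlines around each
dwelling, takes four 90°-field-of-view views per point, classifies
vegetation pixels, and scores each point with the **green view index**

```
GVI = ( Σ_{i=1..4} greenery pixels_i ) / ( Σ_{i=1..4} total pixels_i )  ∈ [0, 1],
```

a pooled pixel ratio over the four views.  A dwelling's exposure at a
neighbourhood radius r (400 m and 800 m Euclidean buffers, ≈5 and 10 minute
walks) is the unweighted mean GVI over all sampling points in the buffer.

Exposure then enters two multilevel models with participants clustered in
*street blocks* j (random intercept):

* **Walking decision** (logistic):
  `logit P(walk_ij = 1) = x_ijᵀβ + b_j`, `b_j ~ N(0, σ_u²)`, fitted by
  adaptive Gauss–Hermite quadrature; effects are reported as odds ratios
  per SD of each standardized predictor.
* **Walking time** (linear, walkers only):
  `y_ij = x_ijᵀγ + u_j + ε_ij`, fitted by profiled maximum likelihood;
  effects are standardized β.

Covariates are the usual walkability set — population density, land-use mix
(normalized entropy of commercial/office/residential area shares),
intersection density, counts of shops / recreation facilities / bus stops,
distance to the nearest rail station — plus age band, gender, household
income band, and a greenness × gender interaction (gender effect-coded in
the interaction, so post-hoc stratum slopes are `main ± interaction/2`).

Because the survey and imagery behind such analyses are not public, this
package is *synthetic-runnable end to end*: it generates a planar city
(street network, parcels, amenities, street blocks, spatially
autocorrelated vegetation field), renders streetscape tiles with exact
ground-truth vegetation masks (including green man-made confounders that
defeat color-only classification), segments them with a rule-based
shape-and-texture-aware classifier behind a pluggable interface, and
simulates walking outcomes from generating models whose coefficients are
reference effect sizes.  Every headline number is therefore a
**parameter-recovery** result: simulate at the study's sample sizes, refit,
and check the estimates come back.

## Worked example

Fit the walking-time analysis on a small synthetic cohort (800 walkers):

```
$ greenwalk fit --analysis 2 --seed 4 --n 800
Analysis 2, 400 m buffer
                       beta  ci_low  ci_high     p
intercept            -0.062  -0.258    0.135 0.539
gvi                   0.130   0.041    0.218 0.004
population_density    0.002  -0.087    0.091 0.962
...
inc_high             -0.348  -0.599   -0.096 0.007
gvi_x_gender          0.097  -0.024    0.217 0.115
AIC = 2091  BIC = 2180  -2 Log Likelihood = 2053  ICC = 0.146
```

The `gvi` row says one SD more eye-level greenness in the 400 m buffer is
associated with 0.130 SD more walking time (95% CI 0.041–0.218) — the
generating value for this radius is 0.149, and at 800 m the fit returns
0.230 against a generating 0.233.  `ICC = 0.146` is the share of residual
variation attributable to between-block differences (generating value 0.16
on the null model).

Validate the vegetation segmenter against ground-truth masks:

```
$ greenwalk validate-seg --n 20 --seed 2
n = 20  Pearson r = 0.993
```

Library use mirrors the CLI:

```python
from greenwalk import CityConfig, generate_city
from greenwalk.pipeline import walk_or_recovery

city = generate_city(CityConfig(), seed=1)
rec = walk_or_recovery(city, radius=400, n_replicates=20, seed=1)
print(rec.mean, "+-", rec.mc_se, "generating value", rec.truth)
```

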