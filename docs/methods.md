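# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limits of what the package's tests demonstrate.

## Exposure model

The green view index (GVI) of a street point is the pooled pixel ratio over
the four 90°-FOV views at that point: total vegetation pixels divided by
total pixels.  Pooling precedes division — the pooled ratio differs from a
mean of per-view ratios whenever view sizes differ, and the pooled form is
the one implemented and tested.  Points are generated per street edge at
arc-length multiples of the 50 m spacing, deduplicated at shared nodes
(coordinates rounded to 0.01 m), and kept when inside the *closed*
Euclidean disk of the buffer (400 m / 800 m defaults).  Buffer exposure is
the unweighted arithmetic mean over point values; dwellings whose buffer
contains no sampling point are excluded from analysis with a logged count.
Geometry is planar in meters throughout — every distance of interest is
sub-kilometre, so geodesy would add nothing.

Two scoring backends share this surface.  The `rendered` mode runs the full
imagery path (render four views, segment each, pool pixels).  The `field`
mode scores a point directly by the ground-truth vegetation-field density —
the expected vegetation fraction the renderer would produce there — and is
used for the cohort-scale recovery runs, where rendering millions of tiles
would add Monte-Carlo noise but no information: the regression consumes the
z-scored exposure either way.  The equivalence of the two paths is pinned
by an exact oracle: with ground-truth masks substituted for predictions,
the rendered pipeline's buffer mean equals the mean ground-truth tileset
fraction bit-for-bit.

## Synthetic city

The generator supplies every geographic layer the pipeline consumes.
Defaults (one number each, chosen once as a plausible dense district and
not revisited):

* extent 9 × 9 km; jittered ~160 m street grid with 8% diagonal
  connectors (realistic intersection-density variation, always connected);
* 300 street blocks as Voronoi cells of random seeds; dwellings occupy the
  ~200 blocks that lie at least 820 m inside the boundary, so no buffer is
  clipped by the edge of the study area;
* dwellings are pinned to *estates* (1–3 per occupied block, near street
  nodes, Dirichlet-weighted sizes).  All dwellings of an estate share one
  geocoded location, as towers of a public-housing estate do; this is the
  within-block clustering the random intercept absorbs, and it makes the
  24,773-participant exposure computation cheap (one buffer per estate);
* land-use parcels on a 200 m grid: commercial probability rises mildly
  near rail stations, offices are scattered, and commercial/office parcels
  keep 60% / 35% of the residential population weight (mixed-use towers).
  These couplings were deliberately kept weak so that the built-environment
  covariates are correlated but not collinear — the default design passes
  the variance-inflation screening (all VIF < 2) that the analysis model
  assumes; stronger station-clustering produced VIFs above 2 and an
  unusable design;
* amenities: 1500 shops (30% inside commercial parcels), 450 recreation
  facilities, 1250 bus stops on street edges, 30 rail stations spread by
  farthest-point thinning;
* vegetation field: Gaussian-filtered white noise with a 300 m correlation
  length, rescaled to mean 0.25, SD 0.12, clipped to [0, 1].  The
  correlation length makes 400 m and 800 m buffer means differ but
  correlate (r ≈ 0.9 in the default city), which is the premise of the
  two-buffer robustness design.

Everything is deterministic given `(config, seed)`.

## Streetscape rendering and segmentation

Tiles are 256 × 256 by default (the index is resolution-invariant; tests
use smaller tiles).  A tile is sky gradient + building rectangles + road
band, plus vegetation painted as ragged, textured green blobs whose painted
pixels define the ground-truth mask, and — with probability 0.3 per tile —
1–2 green *man-made* patches (trucks, painted walls): rectilinear,
untextured, ground-truth zero.  Headings are fixed at compass 0/90/180/270
with pitch 0.  The four views' target vegetation fractions scale with the
local vegetation-field density.

The segmenter is deliberately not a neural network: the pipeline's
contribution is the index and the analysis, so a deterministic rule-based
classifier sits behind a pluggable interface (a trained scene-parsing model
could be wired in with no other change).  It gates pixels on HSV hue
[0.18, 0.45], saturation ≥ 0.15, value ≥ 0.08, then filters connected
components: drop anything smaller than 12 px, anything *boxy and flat*
(bounding-box fill ≥ 0.88 with value-channel SD ≤ 0.05), and anything
essentially textureless (SD ≤ 0.012).  Canopy is ragged and textured and
survives; man-made green patches do not — which is exactly the failure
mode of color-only extraction that motivates shape-aware methods.
Thresholds were tuned on a held-out synthetic corpus, not on test fixtures.
Validation follows the expert-labeling design: per-image predicted vs
ground-truth green fractions over a 50-image corpus spanning the
vegetation range, compared by Pearson correlation (image-level, not
pixel-level).  The default segmenter reaches r ≈ 0.99 on this corpus; the
reference agreement level for this validation design is 0.91.

## Covariates

Per dwelling and radius, in the closed disk: amenity counts; intersection
density (degree ≥ 3 nodes per km², disk area πr²); population density
(parcel populations apportioned by intersected-area fraction, per km²);
land-use mix as Shannon entropy of the three area shares normalized by
ln 3 (0 = single use, 1 = even mix, with 0·ln 0 ≡ 0); Euclidean distance
to the nearest rail station, not capped at the radius.  Continuous
predictors are z-scored with the sample (n−1) SD *on the analysis sample
actually fitted* (full cohort and walkers' subsample separately), so
coefficients read "per SD".  Age (5–17 reference), gender (male reference)
and income (low reference) are dummy-coded; the income/age band edges
follow the descriptive table of the reference sample.  VIF is computed by
explicitly regressing each predictor on the others (1/(1−R²)); perfectly
collinear columns are reported as infinite.

## Generating models and cohort composition

Demographics are drawn independently from the reference margins (full
cohort: 15.2/38.2/31.9/14.7% across age bands, 51.9% female,
25.2/42.3/22.8/9.8% across income bands; the walkers' subsample is older
and more female).  The walking-decision generator is a random-intercept
logistic model whose coefficients are the reference odds ratios (log
scale); the walking-time generator is the linear analogue on the
standardized scale.  Choices the reference tables do not determine:

* **Intercepts** are 0 (≈50% marginal walking rate, consistent with the
  reference deviance magnitude; the time outcome is standardized anyway).
* **Gender coding in the interaction** is effect coding (−½ male,
  +½ female), so the main greenness slope is the gender-averaged slope and
  stratum slopes are main ± ½·interaction; the gender main effect itself
  is a female dummy.  The reference post-hoc stratum estimates straddle
  the main estimate, which is consistent with this coding; no simple
  coding reproduces them exactly, so for the post-hoc recovery experiment
  the main/interaction pair is rebuilt from the stratum values themselves.
* **Variance components**: the logistic block SD is set from the target
  latent-threshold ICC, σ_u² = ICC/(1−ICC)·π²/3 (7.9% → σ_u ≈ 0.53); the
  linear block/residual variances split a total of 0.85 in the 16:84 ratio
  so the simulated outcome variance is near 1.
* **Walking minutes** are presentation-only: minutes = 60 + 30·y, floored
  at 1 with a logged count; all fitting happens on the standardized scale.

## Model fitting

*Logistic random intercept.*  The marginal likelihood integrates the
Bernoulli likelihood over the block effect with adaptive Gauss–Hermite
quadrature: per group, a Newton search finds the conditional posterior
mode, the quadrature is centered there and scaled by the posterior
curvature, and K = 15 probabilists' nodes are combined by log-sum-exp
(K = 15 vs K = 51 agree to < 1e-6 on the test fixtures; adaptivity is what
keeps K modest with hundreds of groups).  The gradient is computed
analytically through the Fisher identity — the posterior expectation of
the complete-data score, evaluated with the same nodes reweighted to
posterior weights — which makes a 24,773 × 200-group fit take about a
second.  Optimization is L-BFGS-B on (β, log σ_u) started from a plain
IRLS logistic fit, with up to three perturbed restarts on failure.
Standard errors come from the observed information (central differences of
the analytic gradient); CIs and p-values are Wald (the reference symmetric
exp-scale intervals are consistent with Wald on the log scale; the
p-value method there is unstated, so Wald is implemented and labeled).
σ_u can be pinned to 0, which reduces exactly to plain logistic
regression.

*Linear random intercept.*  Profiled maximum likelihood: given the
variance ratio λ = σ_b²/σ_e², the GLS fixed effects and σ_e² are closed
form via per-group Woodbury identities; λ is optimized on the log scale in
one dimension, with the λ → 0 boundary (OLS) checked explicitly.  ML is
the default so AIC/BIC are comparable across fixed-effect specifications;
REML is available by flag.  σ_b = 0 can be imposed, reducing exactly to
OLS.

*ICC.*  Gaussian: σ_b²/(σ_b²+σ_e²).  Logistic: σ_u²/(σ_u²+π²/3), the
latent-threshold convention — the one compatible with quoting a single
null-model ICC for a binary outcome.

*Post-hoc simple slopes.*  Stratum slope = main + c·interaction with the
coding weight c; its SE follows exactly from the coefficient covariance
(linear combination), and equals the SE from an explicitly reparameterized
refit, which the tests verify.

## Recovery experiments and problem sizes

Each recovery experiment fixes one city and cohort design (seeded), then
redraws block effects and outcomes per replicate and refits; 20 replicates
are averaged, with the Monte-Carlo SE of the mean reported.  Sizes are the
reference analysis sizes: 24,773 participants in ~200 occupied blocks for
the decision model, 1,994 walkers in 150 blocks for the time model.  Tests
assert agreement within 4 Monte-Carlo SEs (with a small absolute floor),
which at these sizes is on the order of 2–4% of an odds ratio.

## What the synthetic data do and do not show

The generators match the reference setting in structure (spatially
autocorrelated exposure shared within estates, block clustering, the
covariate set and its screening behavior, sample composition) but not in
photographic realism, in the joint demographic distribution (margins are
drawn independently), or in any real behavioral mechanism — outcomes are
drawn from the very model family later fitted.  Passing recovery therefore
demonstrates that the pipeline and estimators are correct and unbiased at
the study's scale, not that the substantive associations would replicate
in new survey data.  Street networks carry no elevation, footbridges or
directionality; buffers are Euclidean disks, not network buffers; live
street-imagery retrieval is a stub interface by design.
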