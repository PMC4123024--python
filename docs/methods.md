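# Methods

This note documents the models, algorithms and numerical choices behind
`multilur`, and what the synthetic campaigns do and do not establish.

## The supervised stepwise procedure

The builder implements the standardized multi-area LUR protocol:

1. **Forced terms first.** Combined (multi-area) models force the regional
   background concentration; city-specific models may run with an empty
   forced set. Forced terms are exempt from sign checks, p-value pruning and
   VIF removal.
2. **Greedy forward selection under sign constraints.** Every remaining
   candidate is refitted with the current model. A candidate is eligible
   only if its own coefficient matches its a-priori direction *and* no
   non-forced incumbent's required sign flips. The eligible candidate with
   the largest adjusted-R² gain enters if the gain is ≥ `gain`
   (default 0.01, an absolute adjusted-R² increase — the "at least 1%"
   reading). Ties break on the lexicographically smallest name, for
   determinism. Constant or rank-deficient candidates are silently
   ineligible (logged at debug level).
3. **Backward p-value pruning** (`alpha` = 0.1): the non-forced term with
   the largest p-value above alpha is removed and the model refitted,
   iteratively — one-shot removal can strand newly insignificant terms.
   Incumbents whose p-value drifts above alpha *during* selection are
   handled only here, at the final stage.
4. **VIF enforcement** (`vif_max` = 3, strict): while any variance inflation
   factor reaches the bound, the worst non-forced term is dropped, the model
   refitted, and pruning re-run. If only forced terms remain and they are
   still collinear, that is a data error.

The emitted model stores terms in entry order with the partial-R² path
(cumulative raw and adjusted R², recomputed by sequential refits over the
final term set, so the path describes the model actually reported), per-term
p-values and VIFs, the training minimum/maximum of every predictor, and
provenance (pre-pruning selection path, excluded areas, options). Every
build asserts the model invariants — sign consistency, p ≤ alpha for
non-forced terms, max VIF < 3, a monotone raw-R² path — before returning.

The OLS engine is a thin numpy least-squares fit with intercept
(coefficients, two-sided t-test p-values, R², adjusted R²). The stepwise,
cross-validation and transfer layers perform tens of thousands of small
refits, so the engine avoids per-fit framework overhead; the test suite
cross-checks it against statsmodels on random designs, and the selection
path against an independent normal-equations greedy oracle.

## Buffer geometry

Buffer variables use exact planar geometry on a closed disc. The in-disc
length of a road segment solves `|P(t) − c|² = r²` for the segment's linear
parametrization, clipping t to [0, 1]; a tangent line contributes zero
(measure-zero overlap), as does a zero-length segment. Ring variables are
always evaluated as outer-disc minus inner-disc, which makes
`ring + inner = outer` an exact identity rather than a numerical
coincidence. Nearest-road queries break distance ties by the smallest
segment id. Raster class areas use cell-center inclusion
(`count × cell_size²`): the absolute error against the true intersection
area is bounded by the area of the one-cell-diagonal ring straddling the
circle, negligible when `cell_size ≪ radius` (default: 200 m cells against
≥ 1,000 m land-use buffers). No spatial index is used; scenes at the
package's scale (≈ 10² segments per area) make the exhaustive scan both
exact and fast.

## Temporal adjustment

Each site is sampled in three 2-week periods; the area's continuous
reference series spans 12 periods. The adjusted annual average subtracts the
reference's *deviation from its own annual mean* in the sampled period
(signed difference method):

    adjusted = mean_p [ sample_p − (ref_p − ref_annual_mean) ]

A constant reference leaves the plain mean unchanged, and a site sharing the
reference's temporal deviations is recovered exactly. The protocol's
"absolute differences" is implemented as the signed difference: an
absolute-value form cannot de-trend (it would re-add negative deviations
with the wrong sign), so the signed form is the only internally consistent
reading; no ratio-method variant is offered. Campaigns with fewer than three
surviving samples are computed on what remains, with a warning — failed
campaigns are not imputed.

## The synthetic campaign generator

The generator's role is to produce worlds with the statistical and
geographic structure the multi-area methodology assumes, with known ground
truth. Per area (a "city"):

* **Roads**: `n_arterials` (default 6) radial arterials from the center to
  4,000 m with lognormal intensities around 20,000 vehicles/day (floored so
  every area has qualifying high-intensity streets), plus `n_local_roads`
  (default 60) short local segments with lognormal intensities around
  800 vehicles/day inside the 2,500 m city radius. This produces the skewed
  traffic-load distributions LUR modelling assumes.
* **Sites**: the type mix (default 45% street / 35% urban background / 20%
  regional background, at least one regional-background site per area)
  controls placement. Street sites sit 5–45 m from an arterial carrying at
  least `street_min_intensity` (10,000 vehicles/day); urban-background sites
  are drawn inside the city but ≥ 75 m from arterials; regional-background
  sites are placed in an annulus ≥ 1,000 m (plus margin) from every major
  road — which also leaves their ≤ 1,000 m road buffers empty.
* **Land use**: a 200 m raster per area. Residential probability decays
  radially from the center; natural/green cover is a saturating radial trend
  (low urban core, uniformly green countryside) plus ten Gaussian park and
  forest patches at random urban and peri-urban locations. The patches are
  what keeps green cover from being a deterministic mirror of road density —
  without them the two layers are collinear (joint VIF > 3) and no selection
  procedure could separate them.
* **Concentrations**: deterministic annual value = intercept +
  `background_weight` × area background + Σ β·x, plus Gaussian site noise.
  Three seasonal samples per site add the area's sinusoidal seasonal
  deviation — shared exactly with the area's reference series, whose 12
  periods span a full cycle so deviations sum to zero — plus independent
  sampling noise. The reference series itself is noiseless (a continuous
  monitor averaged over each period).

Two calibrations tie the generator to interpretable, named conditions
rather than raw variances:

* `within_r2_target` sets the site-noise SD from the realized within-area
  SD of the local signal: `noise = s_local · sqrt((1 − t)/t)`, so the
  within-area fraction of variance explained by a correct model is ≈ t.
* `between_within_sd_ratio` sets the spread of latent area background
  effects. The local signal's per-area means already contribute between-area
  variance, so the drawn effect SD is
  `sqrt(target² − var(area means of local signal))`; the total between-area
  signal variance then matches the target in expectation. (Subtracting the
  area means instead — an earlier design — reverses the between-area slope
  of the local variables and biases their coefficients.)

Presets encode the two canonical variance structures: `pm25_like` (between
variance 3× within, within-R² target 0.55) for a regionally dominated
pollutant, and `no2_like` (between variance 0.25× within, within-R² target
0.65) for a traffic pollutant. The default true models assign each term a
contribution of roughly 1.5–2 µg/m³ SD on the generator's predictor scales,
so every true term carries comfortably more than the 1% admission gain and
no term's identifiability hinges on a borderline threshold.

All randomness flows from the single `StudyConfig.seed` through named
`SeedSequence` substreams (areas, roads, sites, raster, concentrations,
tabular), so identical configurations are byte-identical and artifacts can
be regenerated independently.

**What the generator does not emulate**: real European geography and
meteorology, chemistry-transport, spatially autocorrelated residuals (noise
is independent across sites; an exponential-decay option was considered and
deliberately left out), multi-pollutant correlation beyond shared
predictors, and population/altitude layers (the tabular mode can stand in
for those). Passing tests therefore show that the pipeline's statistical
machinery behaves as specified under the assumed generating structure — not
that any particular real-world dataset satisfies that structure.

## Evaluation conventions

* Validation R² is the **squared Pearson correlation** between predictions
  and observations. It is blind to calibration bias (a uniformly shifted or
  scaled prediction still scores 1), so the MSE-based `1 − SSE/SST` is also
  emitted as a secondary diagnostic (`r2_mse`).
* Per-area regression **slopes regress predictions on observations**: a
  slope below 1 expresses compression of predicted contrasts
  (underprediction of high observations within an area). The protocol this
  package follows does not pin down the regression direction; the convention
  here is documented rather than asserted as canonical.
* Per-area metrics require ≥ 3 sites; smaller areas are reported as missing,
  not silently dropped. IQR is the 75th − 25th percentile with
  linear-interpolation quantiles.
* **Truncation** clamps test predictors to the training range and is ON by
  default in every out-of-sample prediction. One consequence: with any
  between-area background spread, the area with the most extreme background
  is, in its own exclusion refit, *outside* the training range by
  construction, so its clamped background shifts the whole area and pooled
  LOAOCV R² cannot reach 1 even on noiseless data. The noiseless-limit test
  therefore runs the out-of-sample layers with truncation disabled; all
  stochastic tests keep the default.
* The regional background column is always computed from measured annual
  averages at each area's own regional-background sites. In exclusion
  experiments the excluded area's value is taken from its own background
  sites — the minimal measurement a genuinely new area must supply for the
  forced term to be defined — while the refit itself never sees any of the
  excluded area's observations. Refits reuse the full model's options; no
  per-refit tuning.

## Problem sizes

The test and acceptance workloads run at the campaign scales the methodology
targets (17–23 areas × 20 sites for the headline European-style runs) or at
reduced multi-area scales (6–12 areas) for properties that are
size-insensitive, with seed counts of 20–200 per property; these sizes were
chosen so the full suite completes in a few minutes while keeping Monte
Carlo error well below every asserted margin.

## Known limitations

* Tabular predictor generation matches Spearman rank correlations through a
  Gaussian copula; extreme tail dependence is not reproduced.
* The raster cell-center rule slightly under- or over-counts land-use area
  near the disc boundary (bound above); land-use polygons and network-based
  (road-distance) buffers are out of scope.
* "Major road" is taken as a given flag on input segments; the package does
  not derive it from intensity.
* No spatial residual kriging, partial-least-squares variant, or
  satellite augmentation; no uncertainty intervals on R².
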