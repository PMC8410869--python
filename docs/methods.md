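# Methods

This note documents the models, the numerical choices, what the synthetic
worlds do and do not emulate, and the known limitations.

## Species distribution models

All four families model presence probability against environmental
predictors from presence/background data with row weights (presences 1,
background n_presence/n_background, so the classes have equal total
weight — the "inverse-proportional, total weight = 1" convention).

* **GLM** — binomial logit with a linear and a quadratic term per predictor
  (standardised first).  Bidirectional stepwise selection operates on
  predictor blocks (a predictor enters or leaves with both its terms) under
  AIC; the criterion is frozen to AIC because the selection procedure's
  information criterion was an open choice.  Fitting is a direct IRLS
  solver on numpy: the stepwise search calls it thousands of times per
  species, and a 10⁻¹⁰ ridge jitter on the normal equations guards against
  exactly collinear candidate designs.  Quasi-separation is deliberately
  not an error — the linear predictor is clipped and predictions approach
  0/1, which is the desired behaviour when a niche margin is clean.
* **GAM** — binomial logit on unpenalised cubic B-spline bases with basis
  dimension 5 per predictor and no interactions.  Prediction clips new
  values to the training range of each predictor, since a spline basis is
  undefined outside its knots; this makes the GAM response flat (not
  explosive) under extrapolation, with the MESS mask flagging where that
  matters.
* **RF** — scikit-learn random forest with 750 trees, terminal node size
  10 and ⌊p/3⌋ candidate variables per split; sample weights passed
  through.
* **ANN** — scikit-learn single-hidden-layer perceptron (LBFGS, at most
  200 iterations).  Hidden size and weight decay are chosen over the
  frozen grid {2, 4, 6, 8} × {10⁻¹, 10⁻², 10⁻³} by 5-fold stratified CV on
  held-out AUC.  The implementation does not accept sample weights, so the
  1 : 0.1 weighting is realised exactly by replicating presence rows ten
  times.  The hyperparameter search runs once per species, on its first
  predictor set, and the chosen pair is reused across sets and evaluation
  splits: the sets share most predictors and the CV optimum is insensitive
  to swapping one nutrient variant for another, while a per-split search
  would multiply the dominant cost of the design forty-fold.

Evaluation uses ten (configurable) stratified 80/20 splits per species ×
algorithm × predictor set.  TSS is maximised over a 0.01-step probability
threshold grid; AUC is the weighted rank statistic.  Retention requires
mean TSS strictly above 0.30 and at least 75 presences (the "more than 75"
phrasing is frozen to ≥ 75, consistent with the presence-to-predictor
ratio argument that motivates the rule).

Failures (singular designs, one-class folds) never abort a run: the record
is flagged, the member degrades to the surviving fits, and the failure list
is part of the results object.

## Background selection

The target group is the pooled set of all species' sampling sites (the
package default, matching the standard choice; group-specific target
groups are a parameter).  Sites are stratified into 10 × 10 equal-frequency
SST × MLD bins — the stratum resolution is not a published constant, so it
is exposed as a parameter and recorded in outputs.  Background counts per
stratum follow stratum weights by largest-remainder rounding; the focal
species' own presence sites are excluded, and a stratum that runs out of
free sites falls back to sampling with replacement, always with a warning.

## Projection and change statistics

Future climatologies add the per-ESM monthly anomaly (future minus
baseline) to the observed fields.  The annual SST range is special-cased:
its delta is the difference of the ESM's annual ranges added to the
observed range, so the ESM's seasonal-cycle bias never leaks into the
observation-based field.  Log-variant predictors are recomputed after
applying deltas on the linear scale.

Richness is the sum of habitat suitabilities (potential richness), annual
means are taken over months with data (polar-winter gaps drop out of the
mean rather than zeroing it), and the ensemble is the mean over members.
The %ΔSR guard masks cells with present SR below 0.5 — dividing by a
near-zero stacked suitability produces meaningless percentages.  Sign
agreement counts the majority sign among non-zero member changes (zeros
are uninformative about direction) with stippling at ≥ 90%.  Factor
variance shares are main-effect sums of squares of the member %ΔSR over
the algorithm × set × ESM factorial — the simplest decomposition that
reproduces a qualitative SDM > ESM > set ranking without a model fit.

MESS similarity follows the standard percentile branches; the minimum over
predictors is the cell score and the argmin its driver.  A degenerate
reference (max = min) scores 0 at the point value and a −10⁴ sentinel
elsewhere, logged.

## Turnover, associations, diagnostics

Binarisation applies thresholds to annual-mean suitability (presence at
HSI ≥ t, the ≥ convention frozen) over the family-specific ranges
0.25–0.40 (GLM/GAM/ANN) and 0.10–0.25 (RF) in 0.01 steps; the Jaccard
partition is computed per member × threshold and then averaged.  Empty
assemblages score 0 on all components by convention.

Association scores are the Dunning G² of the 2×2 co-occurrence table,
sign-flipped when observed co-occurrence falls below the independence
expectation.  The significance percentile (75th of the positive scores,
type-7 linear interpolation) is computed per scenario and period — the
per-period reading of an ambiguous pooling choice; pooled percentiles can
be obtained by concatenating score tables.  Pairs with a zero margin score
0 and are removed by the positivity rule.

Range-shift centroids are suitability-weighted cell-center means with
cos(latitude) area weights, computed on the hemisphere holding the larger
present suitability mass (preventing bipolar ranges from cancelling to the
equator), with circular longitude averaging across the date line.
Velocity divides the haversine distance (R = 6371 km) by 6.9 decades — the
midpoints 2021.5 and 2090.5 of the two twenty-year windows; the window
midpoint divisor is a package choice since only the windows themselves are
stated.  Both the all-species and the poleward-only velocity medians are
reported, and both the std and the IQR, because the "±" convention on such
summaries is ambiguous.

The severity regionalisation standardises the five change fields, keeps
the leading principal components (up to four, at least enough for 95%
variance), partitions cells with a hand-rolled PAM (greedy BUILD
initialisation, assignment/medoid-update sweeps; no installed package
provides k-medoids) on Euclidean PC distances, and selects k by the
Calinski–Harabasz profile (silhouettes are also returned; k can be fixed
by the caller).  Severity is |Σⱼ wⱼ·scoreⱼ| with wⱼ the PC variance
shares — invariant to PC sign flips and to cell ordering.  Only the
PCA + Euclidean + PAM path is implemented; it is the variant that the
exploratory comparisons in this literature settle on.

Trait structure uses HSI-weighted medians (cumulative weight 0.5; midpoint
convention on exact ties) and weighted variances per member and month,
annual medians over months, ensemble means over members.  Species with
fewer than 5 measurements inherit genus means; mean S/V > 10 marks
artifactual outliers and removes the species.

The MTE diagnostic regresses ln(SR) on inverse thermal energy 1/(kT)
(k = 8.617333×10⁻⁵ eV K⁻¹, T in kelvin) inside a temperature window and
reports the slope magnitude in eV together with a cubic polynomial over
the full range.  Expected magnitudes are ≈ 0.32 eV for autotrophs and
≈ 0.65 eV for heterotrophs.

Service overlap testing is Kruskal–Wallis at α = 0.01 per gridded service
covariate across severity regions, with two-sided rank-sum post hocs and
Bonferroni correction over the k(k−1)/2 pairs; a region exclusion list per
service mirrors cases where a region's reporting is unreliable.

## The synthetic worlds

`synth.generate_environment` builds monthly climatologies with a cos^1.5
latitudinal SST profile (≈ −1 °C poles to ≈ 28 °C equator), a
hemisphere-antiphased sinusoidal seasonal cycle (amplitude 4 °C at the
poles by default; 0 turns the annual SST range identically off), smooth
seeded spatial texture, nutrients declining sigmoidally with SST (PO₄
near NO₃/16 so N* varies around zero), chlorophyll tracking nutrients,
oxygen anti-correlated with SST, solar-geometry PAR, winter-deepening
mixed layers, mid-latitude wind maxima and small-scale eddy velocity
components.  Virtual species have product-of-Gaussians niches with centers
drawn inside the realized 5–95% environmental range; log size is coupled
to the thermal center through a Gaussian copula (default ρ = −0.6,
warm-small) so size-structure responses are recoverable.  Occurrences are
drawn from the exact joint distribution effort × suitability; a planted
contamination fraction violates exactly one QC rule per bad record.
Pseudo-ESM anomalies scale biogeochemical deltas with the local warming,
so zero warming propagates exact zeros through every change statistic.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: ocean dynamics and fronts, land masks and
coastlines, realistic OBIS/GBIF record densities, taxonomic noise beyond a
synonym map, detection differences among sampling gears, and niche shapes
other than smooth unimodal responses.  Recovery results on these worlds
demonstrate the correctness of the machinery, not the field accuracy of
any particular ecological inference.

## Problem sizes

The default verification world uses 10° cells (36 × 18 × 12 months), 50
species, two pseudo-ESMs and two evaluation splits for the end-to-end
smoke run — chosen so a complete pipeline pass stays within minutes on a
single core while exercising the full 4-algorithm × 4-set member
structure; the 10-split design arithmetic is verified separately at
2-species scale, and grid size, split count and record count are all
parameters, not code.

## Known limitations

* The GAM is an unpenalised regression spline (no smoothing-parameter
  selection); with basis dimension 5 this matches the intended low
  flexibility but will differ numerically from penalised-spline fits.
* The stepwise GLM explores single-block moves greedily; it does not
  guarantee the global AIC optimum.
* PAM uses Voronoi-style medoid updates after a greedy build, which can
  terminate in a local optimum different from exhaustive-swap PAM on
  adversarial data.
* MESS drivers report the argmin predictor only; ties resolve to the first
  predictor in set order.
* The synthetic bathymetry is deep everywhere; the bathymetry QC rule is
  exercised through planted per-record values rather than a coastal field.
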