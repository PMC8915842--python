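# Methods

This note documents the models, the simulator, the numerical choices, and
the limits of what the tests demonstrate.

## Screen design

Half-log dilution series are realized as the rounded {1, 3.33} × 10^k
ladder: starting at the top concentration, steps alternate ÷3 and ÷(10/3).
This is the convention that reproduces the published dose ledger exactly
(e.g. an 8-point series from 10 µM bottoms at 10/3000 → 0.00333 µM at the
3-significant-figure reporting precision); a geometric 10^0.5 step would
not. Log series are plain decade steps. A plate carries test and
negative-control chemicals at 8 half-log concentrations × 2 technical
replicates (16 wells each), a viability-control chemical at 6 log
concentrations with the point nearest 1 µM in triplicate (8 wells), and 24
vehicle (DMSO) wells. Treatments are assigned to coordinates by a seeded
uniform permutation; the stream is derived from (seed, CRC32(plate id)), so
replicate plates share concentration sets but not positions. An optional
`no_edge_vehicle` flag restricts vehicle wells to interior coordinates; the
default is full randomization, matching the stated screen design.

## Synthetic cell-level data

The simulator emulates the per-cell export of a high-content imaging
pipeline, not the images themselves. Defaults reflect the screen being
emulated; they are study conditions, not tuning knobs.

- **Feature taxonomy.** Features split evenly over five channels; within a
  channel, intensity:texture:shape:position ≈ 60:100:60:40 (exactly 1,300
  by largest-remainder apportionment at the default size).
- **Baselines.** Intensity/texture features are log-normal (median drawn in
  200–2000 a.u., log-scale 0.2–0.5); shape/position features are normal.
  Each feature's theoretical nMAD is computed (numerically for log-normals)
  so that every other magnitude in the generator is expressed in nMAD
  units. Cell-level latents share a per-channel factor (ρ = 0.3), which
  reproduces the blockwise channel structure of real feature correlation
  without claiming its exact covariance.
- **Treatment effects.** A chemical shifts a configured feature subset by
  `effect_size / (1 + (true_bmc/c)^h)` nMADs, h = 4 by default. The steep
  default ties the recorded potency to the concentration where well-level
  responses emerge; with shallow slopes a well-powered analysis detects
  sub-half-max shifts and "recovers" a BMC well below the Hill midpoint,
  which is a property of the truth definition, not an estimation error.
- **Variability.** Per-well feature intercepts (SD 0.25 nMAD) model culture
  heterogeneity; per-plate intercepts (SD 0.10 nMAD) model batch effects
  that the per-plate normalization must remove; measurement noise adds
  0.05 nMAD; well cell counts are Poisson with an 8 % lognormal
  between-well factor around 800 cells/well (or the configured mean).
- **Cytotoxicity.** Expected cell count is thinned by a Hill survival
  factor; PI-positive probability rises by a Hill function from 2 % to
  70 %. PI intensities straddle the positivity threshold lognormally.
- **Geometry.** Positions follow a parent–offspring (Thomas) cluster
  process (mean cluster 8 cells, 30 µm spread) in a five-field imaged area
  of 2.09 mm², because these cells grow in dense clusters — this makes the
  nearest-neighbor distance and contact-area endpoints informative.
- **Validity.** A cell is valid when Hoechst intensity and nucleus area
  fall inside configured gates (~2–3 % fail), emulating segmentation QC
  without reimplementing it.

What the simulator does not emulate: optics and segmentation error,
feature-redundancy structure beyond one factor per channel, spatial plate
effects (edge gradients), or dose-misdispense errors. Passing tests
therefore demonstrate the correctness and calibration of the analysis
under idealized but realistically sized data — not robustness to imaging
artifacts.

## Concentration–response engine

Ten model shapes (constant, hill, gain–loss, poly1/2, power, exp2–5) are
fit by maximum likelihood under Student-t errors with 4 degrees of freedom
and a fitted log scale `er`; heavy tails damp outlying wells relative to
least squares. AIC = 2k − 2ℓ with `er` counted in k; ties break toward
fewer parameters, then registry order.

Numerics: bounds are scale-derived (AC50s within [min conc/10, 10 × top];
powers in [0.3, 8]; |top| ≤ 1.2 × max |response|; the exponential dose
scale b ≥ top/100, below which exp2/3 are numerically step-like and
redundant with hill). Optimization is L-BFGS-B with analytic gradients from
5 deterministic starts per model, plus a bounded least-squares polish
(exact on noiseless data) and cascaded starts from nested parents
(constant → sloped; hill → gain–loss with the loss term switched off;
exp4 → exp5; exp2 → exp3), which makes log-likelihood nondecreasing along
exact nesting chains. Fits are invariant to permutation of the (conc,
response) pairs because inputs are canonically sorted.

BMC inversion finds the smallest positive concentration where |fitted
response| crosses |BMR| toward the fitted top: closed form for hill, exp4,
exp5, poly1, power; a 600-point log-grid scan plus Brent refinement for
poly2, exp2, exp3 and gain–loss. Censoring rules:

- constant model, or no crossing at or below the top tested
  concentration → ">top";
- a crossing below the lowest tested concentration is reported (flagged
  `below_range`) only if the fitted exceedance still holds at the lowest
  tested concentration — otherwise the exceedance lives entirely where
  there is no data (a gain–loss "needle") and the result is censored;
- an endpoint may declare a required direction: the global distance
  endpoint accepts only increases (a fitted *decrease* in
  distance-from-null means "more typical than vehicle", not a phenotype).

## Viability endpoints

Vehicle medians for count normalization are per plate; vehicle statistics
for the cytotoxicity baseline and BMR (3 × nMAD of vehicle %PI) pool all
plates. Exclusions are single-pass: the vehicle median is not recomputed
after dropping low-count vehicle wells. Wells, not well means, are the
fitting units. The count EC50 is reported as the count BMC only when the
selected hill describes a loss whose asymptote exceeds 3 × the vehicle
normalized-count nMAD; an upward or sub-noise hill that wins AIC on
sampling noise is not evidence of reduced viability and is censored. The
overall viability BMC is the lower of the two endpoint BMCs (censored only
if both are), the LOEC is the lowest tested concentration strictly above
it, and concentrations above the LOEC are excluded from profiling. When
the viability BMC falls below the lowest tested concentration, one
concentration remains and the phenotype BMC is "not calculable" — the
em-dash convention for fully cytotoxic chemicals.

## Two-stage normalization

Stage 1 (per plate): cell-level z = (x − median)/nMAD over vehicle cells;
features with zero vehicle nMAD on any plate are dropped study-wide and
logged. Stage 2 (per plate): well medians of z, centered on the vehicle
well median and scaled by the vehicle well nMAD. Vehicle wells are thus
exactly calibrated (median 0, nMAD 1 per plate per feature, to floating
point), and a well-level value reads as robust SDs from the vehicle
median.

## Global Mahalanobis profiling

Principal axes are computed by SVD from all viability-retained wells
(centered, not re-scaled — features already share nMAD units); the
component count is the smallest explaining ≥ 95 % of variance, capped at
one less than the vehicle-well count, and reduced further if the vehicle
covariance is ill-conditioned. The vehicle covariance in component space
uses Ledoit–Wolf shrinkage toward a scaled identity, which keeps the
estimate invertible when the component count approaches the vehicle-well
count.

The null requires care. Because stage-2 statistics are estimated from the
vehicle wells themselves, vehicle profiles are exactly self-calibrated
while treated wells carry the estimation noise of those statistics as
shared per-plate offsets; measured against a null built from pristine
vehicle profiles, even no-effect treated wells sit systematically above
the vehicle distance distribution (about +1 BMR under the default study
size), which overcalls hits. The null is therefore built from
*cross-calibrated* vehicle profiles: each plate's vehicle wells are split
in half and each half is re-scaled against the other half's statistics (an
exact affine map in scaled space). These pseudo-treated profiles enter the
principal-axis fit, define the vehicle mean and covariance, and provide
the vehicle distances (leave-one-out for each well's own distance). Since
half-plate statistics (12 wells) are noisier than the full-plate
statistics (24 wells) treated wells see, the null slightly *over*-covers
the treated noise: hit calls are conservative by design, which is the
right failure mode for a reference-chemical screen. Under the default
simulated conditions this leaves negative controls censored at both
endpoints in ≈ 97–100 % of replicate screens while chemicals with effects
≥ 2 nMAD are recovered within ≈ 0.25 log10 of truth.

The response is D − median(vehicle D), fit with the nine-model family at a
BMR of 1 × nMAD of vehicle D, with the upward-direction requirement above.

## Culture endpoints

Percent confluence is total cell-body area over imaged area (capped at
100 %); average distance is the well mean of nearest-neighbor nucleus
centroid distances (per-cell nearest neighbor, then averaged); percent
contact area is approximated by the overlap of equivalent-area discs at
nucleus centroids, as segmentation masks are not available to a tabular
pipeline — it is a proxy and is documented as such. Group comparisons
report Shapiro–Wilk and Levene checks, then Kruskal–Wallis with Dunn's
post-hoc test (pooled mid-ranks, tie-corrected, two-sided normal p-values,
Bonferroni-multiplied) against a reference group at adjusted p < 0.05.
Dunn's test is implemented in-package.

## Reference selection

The viability:profiling ratio is defined only when both BMCs are
estimated; any censored or not-calculable input propagates as "—". A
chemical is selected when its phenotype BMC is estimated and either the
ratio reaches `min_ratio` (default 5 — a configurable operationalization
of "large"; the published choices have calculable ratios ≥ 6.4 while a
ratio of 1.3 was rejected) or viability is censored within the tested
range. Display follows the published table: 3-significant-figure
scientific BMCs, 1-decimal ratios with thousands separators.

## Problem sizes

The simulated validation screen uses 3 replicate plates of a reduced
roster (5 test chemicals spanning the archetypes, 2 negatives, 1 cytotoxic
control), 200 features, ~200 cells/well, and 20 seeded replicates — large
enough for the calibration claims above while keeping the full suite and
the acceptance script to a few minutes each on one CPU.

## Known limitations

- The component-retention and null-construction choices are calibrated for
  tens of vehicle wells; with very few vehicle wells (< 4 per plate) the
  cross-calibration split is skipped and distances revert to the
  self-calibrated vehicle null.
- BMC confidence intervals are out of scope (point estimates only).
- The feature-level stage fits every feature independently; no
  multiplicity correction is applied, mirroring the BMR-crossing
  convention rather than a hypothesis-testing one.
- Published BMC magnitudes for real chemicals depend on the real raw data
  and are not reproduced here; the package reproduces the published dose
  ledger, the ratio arithmetic, and the censoring semantics, and validates
  potency estimation against simulation ground truth.
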