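# Methods

This note records the models, numerical choices and known limitations
of the package, in the order the pipeline runs.

## Synthetic study design

The generator (`wingclines.synthetic`) emulates a two-front poleward
range expansion sampled at `n_sites` 10 km grid cells (default 54,
with 10–20 males per site drawn uniformly when `n_per_site` is unset)
across latitudes 50.0–57.2°. Its defaults are the study conditions
every recovery test runs under:

- **Size cline** — true log centroid size rises by `size_slope` = 0.02
  per degree of latitude (≈2% per degree) from baselines of 2.60
  (forewing) and 2.39 (hindwing), falls by 0.001 per year colonised,
  and carries site-level (sd 0.01) and specimen-level (sd 0.03)
  log-scale noise.
- **Shape cline** — each wing has one fixed unit-norm tangent
  direction, built from the template and orthogonalised against
  translation, scale and rotation; specimens are displaced along it in
  proportion to their colonisation score. A single direction keeps the
  recovery analysis identifiable. The deformed shape is renormalised
  to unit centroid size so that deformation never leaks into size.
- **Nuisance transforms** — every configuration is randomly rotated
  and translated (no reflection; sides are generated as left wings)
  and perturbed by isotropic landmark noise (sd 0.01 in unit-CS
  template coordinates).
- **Temperature** — monthly means are an annual site mean plus a
  seasonal sinusoid (amplitude 5.5 °C, July peak) and small noise; the
  annual means correlate with latitude at `lat_temp_correlation`
  (default −0.74, the strongest covariate correlation the sampled
  gradient exhibits). The correlation is imposed by projecting the
  noise against standardised latitude, so the configured value is hit
  up to Monte-Carlo error.
- **Colonisation wave** — years colonised decline linearly northwards
  from 53 to 3 with sd-8 noise, clipped to [1, 53]; the noise keeps
  latitude and colonisation history identifiable in the mixed models
  (their correlation is ≈0.87 rather than ≈1).
- **Images** — a brown elliptical silhouette with cream elliptical
  spots on a uniform grey-230 background, two calibration patches
  (nominals 60 and 200), and an affine lighting distortion with gain
  in [0.92, 1.06] and offset in [−8, 6] grey units. The distortion
  range is chosen so no pixel clips at either end of the 8-bit scale,
  keeping calibration exactly invertible up to quantisation. Brown and
  cream greys follow latitudinal slopes of 1.49 and 3.38 grey units
  per degree, so true contrast rises at 1.89 units/degree.
- **Occurrence records** — the focal species is recorded every year
  from its true colonisation year, so first record equals truth;
  recorder effort (fraction of the 57 non-focal species recorded per
  grid-year, default 0.3) is scriptable per grid and year to construct
  low-confidence scenarios.

What the generator does **not** emulate: photorealistic wings or
venation, digitising error correlated across landmarks, spatial
autocorrelation in recorder effort or climate, measurement error in
occurrence dates, and any size-shape interaction beyond the single
deformation direction. Passing recovery tests therefore demonstrate
that the estimators are consistent and correctly calibrated under the
assumed generative structure — not that real wing photographs or BNM
records are free of the artefacts this structure omits.

## Morphometrics

GPA centres each configuration, scales to unit centroid size, and
iteratively rotates to the running consensus using the 2-D orthogonal
Procrustes solution restricted to det +1 (reflections excluded);
right-side wings are mirrored (x negated) beforehand so left and
right are comparable. The consensus is the renormalised mean,
iterated to an RMS change below 1e−10 (max 100 iterations;
non-convergence flags the result rather than raising). Aligned shapes
are orthogonally projected onto the tangent plane at the consensus.
All specimens of a wing type are pooled in one superimposition across
both expansion regions, matching the pooled covariation analysis
downstream.

Allometry is the least-squares multivariate regression of the
flattened tangent coordinates on log CS. The test statistic is the
percent of total shape variance explained; its permutation p shuffles
log CS and uses the (b+1)/(n_perm+1) estimator (default 10,000
permutations; the seed is a required argument). The regression score
projects centred shapes onto the unit-norm coefficient vector;
residual shapes are the size-adjusted shape variables. The
fore-vs-hindwing allometry comparison is an ANCOVA F-test on the
wing × log CS interaction at the regression-score scale.

## Two-block PLS

Axes are singular vectors of the p×q cross-covariance matrix between
column-centred blocks. The environmental block is z-scored by default:
its variables (degrees, years, °C) are incommensurable, and leaving
them unscaled would let the widest-ranged variable dominate the
loadings — this choice changes loadings and is deliberately prominent
in the API (`standardise_block2`). Each axis is oriented so its
largest-magnitude environmental loading is positive; ties in the
max-|loading| flag go to the first variable in input order. The
overall permutation test permutes environmental rows against fixed
shape rows and uses the RV statistic; per-axis tests use the absolute
correlation between paired axis scores of the permuted fit. The table
reports per-axis loadings, percent covariation σᵢ²/Σσⱼ², between-block
r and permutation p.

## Colour pipeline

Calibration fits nominal = gain·measured + offset by least squares
over all patches and applies it to every channel, clipping to
[0, 255]. Segmentation flood-fills the background from the four image
corners (tolerance 12 grey units, configurable), takes the largest
connected non-background component and fills holes; a wing below 1%
of the image area is a failure. The wing's longest axis is the
principal axis of its pixel coordinates; two cuts perpendicular to it
at 1/3 and 2/3 of the extent partition the mask exactly, and the
basal third is the band containing (or nearest to) the annotated
wing–body attachment point. Thirds are measured on the bounding
extent of the axis projection, not on arc positions; the choice is
noted for sensitivity analysis. Grey values use ITU-R 601 luminance
weights (0.299, 0.587, 0.114). Brown/cream separation is Otsu's
threshold on the within-wing grey histogram — chosen because it is
deterministic and parameter-free — with the darker class brown;
class means closer than 10 grey units mean no separable pattern.
Wings with scale-damage grade 4 are excluded from all colour metrics.
The attachment point is generator metadata; real images would need it
annotated.

## Demography and environment

Regional species richness pools distinct species across all years in
the 100 nearest neighbouring grids (great-circle distance between
centroids, ties broken by grid id; a per-year variant sits behind a
flag). A grid-year is well-recorded when its recorded species reach
10% of regional richness, boundary inclusive. Colonisation
confidence: first record before 1975 → core; otherwise ≥3
well-recorded years strictly before the first record → high;
otherwise low (first record within the onset of good recording);
no record → unoccupied.

Emergence curves smooth weekly counts with a cubic smoothing spline
whose penalty is chosen by generalised cross-validation; generations
are local maxima exceeding 20% of the curve maximum (the floor
suppresses noise peaks; count data give no sharper rule). Development
temperature averages the second-generation peak month and the two
preceding months of the collection year, taking months from the
previous calendar year when the window crosses January. T₁₀ averages
monthly means over the eleven calendar years from collection−11
through collection−1 — the window is implemented exactly as the
variable's defining worked example (2007–2017 for a 2018 collection)
even though that inclusive span exceeds a literal ten years; fidelity
to the definition-by-example wins.

## Mixed models

`fit_lmm` wraps REML estimation (statsmodels MixedLM). The full
random structure — crossed intercepts for day offset, site nested in
expansion, and expansion — is expressed as variance components over a
single trivial group; a single-factor structure uses the ordinary
grouped form, which is faster and numerically better conditioned.
Singular fits (components at zero) are reported with the component
zeroed and flagged, not raised. ICC = Στ₀₀/(Στ₀₀+σ²); marginal and
conditional R² follow the variance-partitioning convention (fixed
variance share; plus random components). Significance of fixed
effects uses the t-as-z rule, |t| ≥ 1.96 inclusive; no mixed-model
p-values are produced. The optimiser is an implementation detail; the
contract is that the REML objective is maximised to tolerance.

The recovery simulations (acceptance suite and script) fit the size
model with site as the single random intercept: the generator injects
no collection-date effect, and expansion has only two levels, so the
fuller structure adds boundary-valued components without changing the
latitude estimate. The full Table-style structure is exercised in its
own unit test. Simulation sizes — 200 replicates of 40 sites × 15
specimens for coverage, 500 replicates at n≈15–20 with 199
permutations for null calibration — are the package's chosen balance
of Monte-Carlo error against runtime; analysis-facing permutation
defaults remain 10,000.

The voltinism comparison is a Welch two-sample t-test on centroid
size; the percent difference (mean₂ − mean₃)/mean₂ × 100 is rounded
to one decimal, matching reporting precision. Colour-latitude
regressions are OLS per colour with an interaction F-test for slope
equality, and the brown–cream association independent of latitude is
the squared correlation of the two detrended residual series.

## Known limitations

- TPS support covers the LM/IMAGE/ID/SCALE dialect only (2-D, no
  curves or semilandmarks, no missing-landmark estimation).
- The thirds split and the Otsu-based pattern separation are one
  reasonable formalisation each of operations that imaging macros
  leave underspecified; both are deterministic but not the only
  defensible choice.
- Mixed-model degrees of freedom are not computed; inference is
  deliberately limited to the t-as-z rule.
- The per-axis PLS permutation statistic (axis-score correlation) is
  a common convention; other choices (per-axis singular value) would
  give different per-axis p-values while leaving axes unchanged.
- Emergence-peak detection assumes 1–3 clearly separated generations;
  overlapping broods merge into single peaks.
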