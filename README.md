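# wingclines

Geometric-morphometric and colour analysis of wing clines in a
range-expanding butterfly, built as a tested, reusable Python pipeline.

Populations expanding their range poleward experience two overlapping
selection regimes: spatial selection for dispersal at the leading edge,
and steep environmental gradients (latitude, temperature, season
length). Wing size, shape and melanism are the classic morphological
read-outs of both. This package reimplements the full analysis chain
used to quantify such clines in the Speckled Wood butterfly (*Pararge
aegeria*) in Britain, from raw landmark files and wing photographs to
mixed-model inference:

- **Morphometrics** — TPS landmark I/O (14 forewing / 11 hindwing
  landmarks), centroid size CS = √Σᵢ‖xᵢ − x̄‖², generalised Procrustes
  analysis (GPA) with tangent projection, multivariate allometry
  regression of shape on log CS with permutation inference, and
  wireframe shape predictions.
- **Covariation** — two-block partial least squares (2B-PLS) between
  size-adjusted shape and environmental variables via SVD of the
  cross-covariance matrix, Escoufier's RV coefficient
  RV = tr(S₁₂S₂₁)/√(tr(S₁₁²)·tr(S₂₂²)), and permutation tests of
  block independence.
- **Colour & pattern** — affine grey calibration against patches of
  known nominal grey, flood-fill wing segmentation, principal-axis
  orientation and splitting into thirds, luminance grey means (0 =
  black … 255 = white), Otsu separation of the brown ground colour
  from the cream spot pattern, areas, and contrast = cream − brown.
- **Demography & environment** — colonisation year from occurrence
  records with a recorder-effort confidence class (core / high / low),
  well-recorded grid-years (≥10% of regional species richness),
  emergence-curve smoothing with GCV-penalised splines to estimate
  voltinism and the second-generation peak, developmental temperature
  (peak month plus two preceding months) and the 10-year mean annual
  temperature T₁₀.
- **Inference** — REML linear mixed models with random intercepts for
  collection-date offset, site nested in expansion, and expansion;
  the t-as-z significance rule (|t| ≥ 1.96); the voltinism Welch
  t-test with percent size difference; and latitude regressions of
  brown/cream lightness with a slope ANCOVA.
- **Synthetic data** — a first-class generator producing landmark
  sets, wing images, occurrence histories, count series and monthly
  temperature tables with known clines, so every stage is testable
  end to end against ground truth.

## Worked example

```python
import numpy as np
from wingclines import (SyntheticConfig, gen_sites, gen_landmarks, gpa,
                        allometry_regression, two_block_pls,
                        percent_size_difference)

cfg = SyntheticConfig(seed=1, n_sites=20, n_per_site=10)
sites, temps, truth = gen_sites(cfg)
configs, spec_truth = gen_landmarks(sites, cfg)

fw = [c for c in configs if c.wing == "forewing"]
proc = gpa(fw)
print(f"forewing GPA: n={proc.n}, converged in {proc.iterations} iterations")
print(f"mean centroid size: {proc.centroid_sizes.mean():.3f}")

allo = allometry_regression(proc, n_perm=999, seed=2)
print(f"allometry: {allo.pct_variance_explained:.2f}% of shape variance, "
      f"permutation p = {allo.permutation_p:.3f}")

ids = spec_truth[spec_truth.wing == "forewing"].site_id
env = sites.set_index("site_id").loc[ids][
    ["lat", "years_colonised", "annual_mean_temp"]].to_numpy()
res = two_block_pls(allo.residual_shapes, env, n_perm=999, seed=3)
print(f"2B-PLS: RV = {res.rv:.3f}, overall p = {res.permutation_p_overall:.3f}, "
      f"PLS1 covariation = {res.pct_covariation[0]:.1f}%")

print(f"percent size reduction (2.60 vs 2.55): "
      f"{percent_size_difference(2.60, 2.55)}%")
```

prints

```
forewing GPA: n=200, converged in 4 iterations
mean centroid size: 2.721
allometry: 59.21% of shape variance, permutation p = 0.001
2B-PLS: RV = 0.150, overall p = 0.001, PLS1 covariation = 99.6%
percent size reduction (2.60 vs 2.55): 1.9%
```

The 200 generated forewings carry a latitudinal size cline (2% per
degree) and a colonisation-history shape cline, so shape covaries
strongly with log CS (59% of variance; the permutation p of 0.001 is
the smallest attainable at 999 permutations) and the size-adjusted
shape residuals covary with the environmental block (RV = 0.15, one
dominant PLS axis — the generator deforms shape along a single
direction). The final line recomputes the percent size difference
between bivoltine and trivoltine populations from their group mean
centroid sizes: wings average 1.9% smaller where a third generation
fits into the season.

A full orchestrated run — covariates, GPA, allometry, PLS, colour
metrics and mixed models, written as results-table CSVs — is

```python
from wingclines import pipeline_run
report = pipeline_run(SyntheticConfig(seed=1, n_sites=12, n_per_site=6), "out/")
```

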