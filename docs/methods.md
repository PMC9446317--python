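# Methods

## Overview

`lesionmorph` implements a four-stage analysis of ischemic stroke lesion
morphology: (1) ADC-threshold segmentation, (2) six shape descriptors of the
binary lesion mask in native space, (3) atlas-overlap localization, and
(4) association statistics against atrial-fibrillation (AF) status. All
volumes are assumed pre-co-registered; registration is an input contract, not
a computation. A synthetic-data module generates every input with known
ground truth, so the statistical and geometric machinery can be validated
end-to-end without patient data.

## Segmentation

Acute ischemia restricts water diffusion, so lesions appear hypointense on
the apparent diffusion coefficient (ADC) map. A voxel is lesion iff it lies
in the brain mask and 0 < ADC ≤ `threshold`.

* `threshold` = 620·10⁻⁶ mm²/s — the established cutoff for acutely ischemic
  tissue. The comparison is **inclusive**: "maximum threshold" is read as an
  attained upper bound, matching common ADC-threshold practice; boundary
  voxels are vanishingly rare in real (noisy) maps and the parameter is
  configurable.
* ADC ≤ 0 is treated as invalid background so masked-out or air voxels can
  never enter the lesion.
* `min_volume_mm3` = 10 mm³ — components **strictly** smaller are removed as
  implausible (noise/artifact); a component of exactly 10 mm³ survives. The
  filter uses physical volume (voxel count × voxel volume), not voxel count,
  and the same 26-connectivity as the shape stage for internal consistency.
* Manual rater corrections enter as a complete replacement mask that is
  validated (binary, same grid) and logged with the voxel delta.

## Shape descriptors

* **Component count** — maximal connected sets under 26-connectivity
  (corner-touching voxels are one component; the standard choice for lesion
  masks, configurable to 6 or 18). Labels are renumbered by the
  lexicographically smallest voxel index of each component, so labeling is
  deterministic regardless of the underlying flood order.
* **Volume** — voxel count × voxel volume, reported in mL (1 mL = 1000 mm³).
* **Surface area** — default is the area of a marching-cubes isosurface
  (iso-level 0.5, spacing-aware), computed **per component** after a Gaussian
  pre-smoothing of the binary field with σ = 0.5 voxels. The smoothing
  suppresses the staircase bias of a raw binary isosurface (+9% on a sphere of
  radius 20 voxels) while remaining mild enough that small blobs (radius ≥ 3
  voxels) are neither eroded below the iso-level nor driven to a shape factor
  below 1 by more than ~0.3%; a component smoothed entirely below the
  iso-level falls back to its raw binary surface. Computing per component
  prevents smoothing from bridging nearby components or deleting a small one
  next to a large one. An exposed-voxel-face estimator (`face_count`) is
  retained as an option; it is exact for axis-aligned boxes but overestimates
  curved surfaces by a known factor (3/2 for a sphere) and is therefore not
  the default, since the shape factor's sphere normalization requires a
  convergent area estimate.
* **Oriented minimum bounding box (OBB)** — one box over **all** components
  jointly, measuring spatial dispersion independently of the scanner axes.
  Voxels are treated as closed cuboids: the box must contain all 8 corner
  points of every lesion voxel, which guarantees a nonzero OBB for
  single-voxel lesions and a fill ratio ≤ 1. The search reduces the corner
  cloud to its convex hull, scores candidate orientations (identity, inertia
  axes of the hull vertices, and every hull-face normal combined with the 2D
  minimum-area rectangle of the projected hull — the rotating-calipers
  construction), refines the best candidate on a local Euler-angle grid (2°
  steps within ±10°) and polishes with Nelder–Mead on a rotation-vector
  perturbation. Because the identity is always a candidate and extents come
  from projections of all corner points, the result is sandwiched between the
  convex-hull volume and the axis-aligned box volume by construction. The
  search is approximate; an exhaustive rotation-grid search is provided in
  `lesionmorph.oracles` for validation and agrees within 1% on rasterized
  cuboids (the production search often lands slightly *below* a single-axis
  exhaustive sweep, because tilting around the remaining axes pays off on
  jagged rasterized shapes).
* **Fill ratio** — V / V_OBB ∈ (0, 1]; small values indicate dispersed,
  multifocal lesions.
* **Shape factor** — S = √A / ∛V / C with C = √(4π)/(4π/3)^⅓ = 2.199085233…,
  the value of √A/∛V for a sphere; S = 1 for a perfect sphere, larger for
  every other shape, and scale-invariant.

Degenerate inputs: every descriptor raises on an empty mask (subjects without
an acute lesion are excluded upstream with a reason code). Flat or collinear
corner clouds fall back to an axis-aligned box.

## Localization

Per-label lesion-voxel counts are aggregated into three class systems —
hemisphere (left/right), vascular territory (left ICA / right ICA / basilar)
and cortical vs deep — and a class is *affected* iff its aggregated count is
≥ `min_voxels` (default 100, applied uniformly to all three systems).
Hemisphere is "both" and territory "multiple" when two or more classes are
affected. Aggregation precedes thresholding because "any cortical region
affected" is a class-level statement. If no class of a category reaches the
threshold, the subject is assigned the maximal-overlap class and flagged
(`below_threshold`) rather than dropped, preserving cohort size; flagged rows
can be excluded downstream. The rule is applied in the atlas grid's voxels.
Real atlases (e.g. a labelled brain parcellation plus a vascular territory
map) are consumed as a NIfTI label volume plus a CSV label table; the bundled
toy atlas exists only for testing.

## Statistics

* **Preparation** — each shape descriptor is natural-log transformed (they
  are strongly right-skewed) and z-scored over analyzed rows; age and NIHSS
  are z-scored without the log (an odds ratio of ~2 per year of age is not
  plausible, per SD it is); binary indicators pass through. The log base is
  irrelevant after z-scoring but fixed to e for reproducible intermediates.
  Zero-variance and non-positive inputs raise.
* **Group comparisons** — two-sided Mann–Whitney (scipy, tie-corrected) with
  medians + IQR for continuous variables; Pearson chi-squared (no continuity
  correction) with a Monte-Carlo p-value for frequencies. Null tables are
  sampled conditional on both margins (sequential multivariate
  hypergeometric draws) and p = (1 + #{simulated χ² ≥ observed})/(1 + B)
  with B = 10 000 replicates by default and a mandatory seed, so p is never
  zero and is reproducible. An exact enumeration oracle for 2×2 tables lives
  in `lesionmorph.oracles`.
* **Logistic models** — maximum-likelihood fits (statsmodels `Logit`) with
  Wald 95% CIs and p-values (the standard default when no method is stated;
  OR = exp(coef) by construction). Perfect separation and rank-deficient
  designs raise, naming the variable / collinear columns. The default
  multivariate shape model is {components, volume, sphericity, OBB volume,
  fill ratio} — surface area is excluded because it is collinear with
  volume. The extended model adds age, sex, NIHSS, cortical involvement and
  multiple territories.
* **Stepwise elimination** — backward: refit, remove the variable with the
  largest p while it exceeds α = 0.05, ties broken by input order for
  determinism; the removal trace is recorded, and a model that loses every
  variable is returned as intercept-only with a flag. Missing values are
  handled by listwise deletion per model with n reported per fit.

## Synthetic data: what it does and does not emulate

* **Lesion masks** — rasterized spheres scattered around the grid centre
  with isotropic Gaussian dispersion (`dispersion_mm`). Disjointness is
  enforced against a 1-voxel dilation guard, so the ground-truth component
  count is unambiguous under any connectivity; placement uses bounded
  rejection sampling (1000 retries) and fails loudly rather than silently
  under-generating. The dispersion knob is this package's construct for
  driving OBB volume; it is not an anatomical model.
* **ADC maps** — two-level volumes (lesion 400·10⁻⁶, background 800·10⁻⁶
  mm²/s, symmetric around the 620·10⁻⁶ threshold the way acute lesion and
  normal parenchyma values are) plus white Gaussian noise (50·10⁻⁶ default).
* **Toy atlas** — hemispheres split at the x midplane, an inferior-third
  basilar territory, ICA territories above it, and a 2-voxel cortical shell
  at the grid boundary. It tiles the grid exactly.
* **Cohorts** — independent log-normal shape features with medians and IQRs
  matched to published stroke-cohort marginals (lesion volume 0.39
  [0.13–1.13] mL, OBB volume 13 [3.4–95.8] mL, sphericity 1.26 [1.21–1.32],
  …; σ recovered from q3/q1 = exp(1.349 σ)), normal age (66 ± 14 y),
  Bernoulli sex and location flags at observed frequencies. AF follows
  Bernoulli(logistic(β₀ + β·z)) on *theoretically* standardized latents, so
  β is exactly per-SD; defaults put nonzero effects only on age (OR 2.13),
  female sex (2.45) and OBB volume (1.72) around a 12.3% prevalence.
  Distribution kinds beyond log-normal (normal, Bernoulli) exist because
  clinical covariates are not plausibly log-normal.

Not emulated: brain anatomy and tissue contrast, registration error,
correlated shape features (real descriptors are strongly inter-correlated;
independence makes collinearity diagnostics trivially clean here),
non-spherical lesion shapes, scanner heterogeneity. Passing tests therefore
demonstrate the correctness of the measurement and inference machinery, not
clinical performance on real MRI.

The end-to-end driver `simulate_study` draws AF from age, sex and the
per-subject dispersion latent (the generative proxy for OBB volume, available
before measurement) and raises prevalence to 30% so that even a 20-subject
smoke cohort almost surely contains both outcome groups; the cohort-level
generator keeps the realistic 12.3%.

## Problem sizes and tolerances

Validation uses: a radius-10 mm sphere at 0.5 mm spacing (shape-factor
identity within ±0.05); 50 rotated cuboids on ≤ 32³ grids against a 1°
exhaustive rotation sweep (never worse than the sweep by > 1%, always within
the hull/AABB sandwich); 50 random 12³ masks against a flood-fill oracle at
6- and 26-connectivity; 20 noisy segmentation round trips (Dice ≥ 0.95);
simulated cohorts of n = 2000 over 100 seeds for stepwise model recovery and
200 seeds for null CI coverage (95% ± 4%); 20 000-replicate Monte-Carlo
chi-squared p-values against exact enumeration on tables with n ≤ 30; and a
20-subject end-to-end run checked for byte-identical reproduction under a
fixed seed.

## Known limitations

* The OBB search is a heuristic global search with local refinement; exact
  3D minimum-volume boxes are not computed (the exhaustive rotation-grid
  search is provided only as a validation oracle).
* The mesh area estimator's smoothing trades a small systematic bias
  (+4.5% on a radius-20-voxel sphere) for robustness on small components;
  shape-factor values are comparable within a fixed estimator but not across
  estimators (face counting yields systematically larger S).
* Whether the original analysis z-scored NIHSS, used inclusive thresholds,
  or applied the 100-voxel rule in native or atlas voxels is unstated in the
  source material; the choices here are documented above and configurable.
* Stepwise selection on correlated predictors is known to favour nuisance
  variables; the package reproduces the procedure, it does not endorse it.
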