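# lesionmorph

Quantitative 3D morphometry of ischemic stroke lesions, and its association
with subsequently detected atrial fibrillation (AF).

Cardioembolic strokes — typically caused by AF — tend to produce *scattered*
infarct patterns: multiple lesion components, cortical involvement, several
vascular territories. `lesionmorph` turns a binary 3D lesion mask (segmented
from diffusion MRI) into a small set of shape and location markers of that
dispersion and runs the statistical analysis linking them to AF status. It is
aimed at stroke-imaging researchers who have co-registered NIfTI volumes (ADC
maps, lesion masks, atlas label volumes) and a clinical covariate table, and
at methodologists who want a fully synthetic, ground-truthed test bed for
lesion-shape statistics.

## What it computes

**Segmentation** (`segment_adc`, `remove_small_components`): lesion = brain
voxels with apparent diffusion coefficient 0 < ADC ≤ 620·10⁻⁶ mm²/s, then
removal of components smaller than 10 mm³; manually corrected masks are
accepted via `apply_manual_edits`.

**Shape descriptors** (`shape_descriptors`), for a mask with volume *V* and
surface area *A*:

1. number of connected components (26-connectivity by default);
2. lesion volume *V* (mL);
3. surface area *A* (mm²), from a spacing-aware marching-cubes mesh;
4. volume of the oriented minimum bounding box (OBB, mL) enclosing **all**
   components jointly at free orientation — a measure of spatial dispersion;
5. fill ratio *V* / *V*<sub>OBB</sub>;
6. sphere-normalized shape factor

   S = √A / ∛V / C,  C = √(4π) / (4π/3)^⅓ = 2.199085233…

   so a perfect sphere scores S = 1 and every other shape scores more.

**Location** (`overlap_counts`, `classify_location`): hemisphere
(left/right/both), vascular territory (left/right ICA, basilar, multiple) and
cortical involvement, by atlas-label overlap with a ≥ 100 lesion-voxel rule.

**Statistics** (`prepare_features`, `fit_univariate`, `fit_multivariate`,
`stepwise_eliminate`, `compare_groups`): shape features are log-transformed
and z-scored (odds ratios are per SD), groups compared with Mann–Whitney and
Monte-Carlo chi-squared tests, and AF modelled by logistic regression with
backward stepwise elimination at α = 0.05.

**Synthetic data** (`make_lesion_mask`, `make_adc_volume`, `make_toy_atlas`,
`simulate_cohort`): every stage is testable against known ground truth with
no patient data.

## Worked example

```python
import lesionmorph as lm
from lesionmorph.volumes import brain_mask_like

# a 3-component synthetic lesion and its noisy ADC map
mask, truth = lm.make_lesion_mask(lm.LesionSimConfig(
    n_components=3, radius_range_mm=(4.0, 6.0), dispersion_mm=15.0, seed=11))
adc = lm.make_adc_volume(mask, noise_sd=50e-6, seed=11)

seg = lm.remove_small_components(lm.segment_adc(adc, brain_mask_like(adc)), 10.0)
print(lm.shape_descriptors(seg).as_dict())
```

prints (seed 11):

```
n_components       3
volume_ml          1.286
surface_area_mm2   829
sphericity         1.204
obb_volume_ml      13.8
lesion_obb_ratio   0.09321
```

Three 4–6 mm blobs scattered with 15 mm dispersion occupy only ~1.3 mL of
tissue but need a 13.8 mL bounding box — the fill ratio of 0.09 and the OBB
volume are exactly the dispersion signature the analysis targets. On a
simulated 2000-subject cohort whose AF risk truly depends on age, female sex
and OBB volume:

```python
df = lm.simulate_cohort(lm.default_cohort_config(n_subjects=2000, seed=1))
fit = lm.stepwise_eliminate(lm.prepare_features(df), lm.FULL_MODEL_VARS)
print(fit.to_frame().round(3))
```

```
     variable  coef  odds_ratio  ci_low  ci_high    p    n
          age 0.838       2.312   2.019    2.647 0.00 2000
          sex 0.813       2.256   1.759    2.893 0.00 2000
 n_components 0.135       1.145   1.013    1.293 0.03 2000
obb_volume_ml 0.586       1.797   1.580    2.043 0.00 2000
```

Stepwise elimination drops the five null covariates (lesion volume, NIHSS,
multiple territories, cortical involvement, sphericity) and keeps the three
generating variables — plus, in this seed, a borderline component-count term —
with odds ratios per SD close to the generating values (2.13, 2.45, 1.72).

A command-line interface mirrors the library:
`lesionmorph simulate|segment|shape|locate|analyze|run --help`.

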