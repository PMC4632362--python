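# gtvkit

Quantitative comparison of radiotherapy **gross tumour volume (GTV)
delineations** across imaging modalities (CT, MR, fused CT-MR, FDG-PET)
and across observers.

In head-and-neck radiotherapy planning, the GTV drawn for the same tumour
differs systematically with the imaging modality it was contoured on and
with who contoured it. Quantifying those differences needs three things
working together: geometrically careful 3-D contour comparison, a
reproducible PET auto-segmentation in place of subjective manual PET
contouring, and statistics that separate modality effects from patient and
observer variability in small, incomplete cohorts. `gtvkit` packages all
three for physicists and analysts running delineation studies, plus a
synthetic multi-observer study generator so every stage is testable
without patient data.

## What it computes

**Contour concordance** — for an ordered pair of binary masks (A, B) on a
common voxel grid, with I = |A∩B|:

- conformity index `CI = I / |A∪B|` (Jaccard) and `DICE = 2I / (|A|+|B|)`
- sensitivity index `I/|A|` and inclusion index `I/|B|` (directional
  containment)
- centre-of-gravity distance `CGD = ‖c(A) − c(B)‖` (mm)
- mean distance to conformity `MDC`: mean distance from each voxel of the
  symmetric difference to the nearest voxel of the other structure (mm)

with two-stage aggregation (mean per patient, then mean ± SD across
patients) into inter-observer and inter-modality summary tables.

**Adaptive-threshold PET segmentation** — inside a tumour ROI, the GTV is
`SUV ≥ T` with the contrast-oriented rule

```
T = a · SUV_mean(70 % isocontour) + b · SUV_mean(background)
```

where (a, b) are scanner-specific slopes fitted by least squares from
sphere-phantom measurements (`calibrate_coefficients` /
`calibrate_from_phantoms`); largest-connected-component post-processing
suppresses physiologic-uptake satellites.

**Volume statistics** — linear mixed-effects models on cube-root
transformed volumes (`V^{1/3}`), with modality and observer role as fixed
effects and patient and observer as crossed random intercepts (observer
terms dropped when the single auto-segmented PET contour is included);
pairwise modality contrasts flagged at α = 0.02. Inter-observer
variability as the per-patient SD of observer volumes per modality,
compared across modalities by one-way ANOVA + Tukey HSD at 95 %
confidence.

See `docs/methods.md` for definitions, model assumptions, the synthetic
generator's design and known limitations.

## Worked example

```python
from gtvkit import StudyConfig, generate_study, run_pipeline

study = generate_study(StudyConfig(seed=1))          # 11 patients, 5 observers
bundle = run_pipeline(study.masks, provenance={"seed": 1})

print(bundle.volume_summary.round(1).to_string(index=False))
print("Inter-observer SD (cm^3), column means:",
      bundle.sd_table.column_means.round(2).to_dict())
print("Tukey significant pairs:", bundle.sd_anova.significant_pairs)
c = bundle.human_model.contrast("CTMR", "CT")
print(f"CT-MR vs CT contrast (cube-root scale): {c['estimate']:.3f}, p = {c['p_value']:.4f}")
```

prints

```
modality  mean_cm3  median_cm3  mean_sd_cm3  max_cm3  min_cm3
      CT      15.3        13.5          5.2     34.8      1.9
    CTMR      16.1        15.2          3.3     34.5      4.7
      MR      14.8        15.2          2.4     26.2      5.2
     PET      11.8        11.5          NaN     18.3      5.4
Inter-observer SD (cm^3), column means: {'CT': 5.22, 'CTMR': 3.27, 'MR': 2.42}
Tukey significant pairs: [('CT', 'CTMR'), ('CT', 'MR')]
CT-MR vs CT contrast (cube-root scale): 0.119, p = 0.0019
```

Reading this: the generated cohort shows the configured structure — fused
CT-MR volumes are systematically larger than CT (the mixed-model contrast
is positive on the cube-root scale and significant at α = 0.02), the
auto-segmented PET volumes are the smallest, and CT contours carry the
largest observer-to-observer volume spread (5.22 cm³ mean per-patient SD
against 2.42 cm³ for MR), which the ANOVA + Tukey stage flags. PET has no
SD entry because it contributes one algorithmic contour per patient.

A command-line interface wraps the same pipeline:

```bash
gtvkit generate --seed 1 --out study/          # synthetic study to disk
gtvkit run --manifest study/manifest.csv --out report/
gtvkit segment-pet --suv suv.nii.gz --roi roi.nii.gz \
       --coeff-a 0.2579 --coeff-b 2.0884 --out gtv_pet.nii.gz
```

Masks and SUV volumes are NIfTI (axis-aligned affines) or a plain JSON
voxel-list format; manifests and all result tables are CSV, with a
full-precision `results.json` per run. Identical inputs and seed produce
byte-identical output bundles.

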