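# Methods

`gtvkit` quantifies how radiotherapy gross-tumour-volume (GTV) contours
differ across imaging modalities (CT, MR, fused CT-MR, FDG-PET) and across
observers. This note describes the models and procedures the package
implements, the choices made where the design was open, and what the
synthetic study generator does and does not emulate.

## Geometry

All structures are binary masks on axis-aligned regular voxel grids
(dims, spacing in mm, origin at the centre of voxel (0,0,0)). Physical
position of index *i* along an axis is `origin + i * spacing`. Oblique
orientation matrices are rejected at I/O with a clear error; nothing in
the analysis requires them. Two grids are "compatible" when dims, spacing
and origin agree within 1e-6 mm; all pairwise metrics require compatible
grids, and masks delineated in another frame are first resampled onto the
common CT/PET frame through a supplied rigid transform (nearest-neighbour
semantics: a target voxel is set iff its centre maps back into a true
source voxel, which preserves binariness exactly). Estimating the
registration itself is out of scope; transforms are inputs.

## Contour concordance metrics

For an ordered pair (A, B) of non-empty masks on a common grid, with
I = |A∩B|:

| metric | definition | range |
|---|---|---|
| CI (conformity index) | I / |A∪B| (Jaccard) | [0, 1] |
| DICE | 2I / (|A| + |B|) | [0, 1] |
| Se. Idx | I / |A| — fraction of A inside B | [0, 1] |
| Incl. Idx | I / |B| — fraction of B inside A | [0, 1] |
| CGD | Euclidean distance between the centroids (mm) | ≥ 0 |
| MDC | mean, over all voxels of the symmetric difference, of the distance to the nearest voxel of the *other* mask (mm) | ≥ 0 |

The conformity index here is the Jaccard overlap — a definition strictly
below DICE whenever the masks differ, linked by `DICE = 2·CI/(1+CI)`.
MDC is defined volumetrically: distances are between voxel centres,
computed with an anisotropic Euclidean distance transform, pooling both
directions of the symmetric difference into a single mean (hence symmetric
in its arguments). A surface-based variant would weight deep non-overlap
differently; the volumetric form is used throughout and the test suite's
brute-force oracle checks exactly this definition. Distance transforms run
on the union's bounding box, which leaves every value unchanged but makes
cost proportional to structure size rather than grid size.

Aggregation is two-stage everywhere: metric values are averaged over
contour pairs within a patient first, then means and SDs are taken across
patients, so each patient contributes equally regardless of how many
contour pairs it supplies. Inter-observer summaries use all unordered
observer pairs within a modality and report CI, DICE, CGD and MDC (the
directional indices are meaningless for unordered pairs). Inter-modality
summaries compare, per patient, each clinician's contour in the first
modality with the same clinician's contour in the second — or with the
single auto-segmented PET contour — keeping Se. Idx as "first within
second" and Incl. Idx as "second within first". A clinician missing either
contour of a pair is skipped, not imputed.

## Adaptive-threshold PET segmentation

The PET GTV is segmented with a contrast-oriented adaptive threshold.
Inside a user-supplied tumour ROI, SUV_max is located and `mean70` is the
mean SUV over voxels at or above 70 % of SUV_max. With BG the mean SUV of
a disjoint background region, the threshold is the single-pass linear rule

    T = a · mean70 + b · BG

with scanner-specific slopes (a, b). The comparison is inclusive (≥ T,
fixing tie-breaks), the segmentation is restricted to the ROI, and by
default only the largest 26-connected component is kept, suppressing
physiologic-uptake satellites inside the ROI. A threshold outside
(0, SUV_max) is refused as degenerate. Every segmentation returns an audit
record (SUV_max, mean70, BG, T, coefficients).

The slopes are obtained by least squares from phantom measurements
(`calibrate_coefficients`): for spheres of known volume, the "true"
threshold is the SUV level at which the segmented volume equals the true
volume, regressed on (mean70, BG). The built-in calibration
(`calibrate_from_phantoms`) renders noiseless spheres of radius 5–15 mm at
background SUV 1–3 under the configured point-spread blur. For the default
render settings this gives a = 0.2579, b = 2.0884, frozen as package
defaults. Because the whole synthetic SUV field scales linearly with the
background level, BG scales out of the fit and b behaves as a
background-proportional offset; the values characterise this synthetic
scanner and are not comparable to published coefficients for physical
scanners. The background region builder is a shell starting a configurable
distance outside the ROI, two voxels thick — one reasonable choice among
many, supplied as a convenience and overridable per case.

## Volume statistics

Volumes are analysed on the cube-root scale: the cube root of a volume
behaves like a length, and brings right-skewed tumour-volume distributions
close to normal. A quantile-correlation check (`normality_check`, the
numeric stand-in for Q-Q plot inspection, default cut-off 0.975) verifies
this on each dataset.

Two linear mixed-effects models are fitted by REML:

* **human-contour model** — fixed effects: modality (CT, CT-MR, MR) and
  observer role (radiologist / oncologist); random intercepts: patient and
  observer, crossed (implemented as variance components on a single
  enclosing group).
* **PET-inclusive model** — fixed effect: modality (all four); random
  intercept: patient only. The single algorithmic PET contour per patient
  makes observer terms unidentifiable, so they are dropped.

Pairwise modality contrasts are Wald z-tests on fixed-effect differences.
Significance for model contrasts is flagged at α = 0.02, compensating for
the multiple models compared; raw p-values are always reported alongside
flags so other thresholds can be applied. The role contrast is reported
per modality and pooled. Unbalanced data (incomplete contour sets) are
fitted as-is; mixed models tolerate missingness and nothing is imputed.
Singular fits (a variance component at zero) are reported in the result's
notes, never silently dropped.

Inter-observer volume variability: per patient and modality, the sample SD
(n−1 denominator — the statistical default for five observers) of observer
volumes, PET excluded; cells with fewer than two observers are reported
missing and excluded from the column means. Modalities are compared with a
one-way ANOVA on the per-patient SDs followed by Tukey's HSD at 95 %
family confidence. Treating per-patient SDs as independent across
modalities ignores their within-patient correlation; this makes the
unpaired comparison conservative and is a documented limitation of the
procedure (not of the implementation). The same ANOVA+Tukey stage is
applied to per-patient mean concordance metrics for the positional
inter-observer comparison. Observer role does not enter the SD ANOVA.

## Synthetic study generator

No patient data ships with the package; `synthetic_study` generates
complete studies with the statistical skeleton the analysis expects.
Defaults emulate an 11-patient, 5-observer (2 radiologists, 3
oncologists), 3-human-modality + auto-PET design on a 64³ grid at 2 mm
isotropic spacing.

* **Base tumour**: the top-volume level set of a Gaussian-smoothed union
  of 2–4 overlapping random ellipsoids; volume drawn log-normal with
  median 12 cm³ and log-SD 0.55 (spanning roughly 4–35 cm³, the range a
  small oropharyngeal cohort shows).
* **Modality truths**: level-set shifts of the base tumour's signed
  distance calibrated by count so the volume ratio matches the configured
  multiplier — defaults CT 1.00, MR 1.07, CT-MR 1.19, PET 0.80, the
  ordering PET < CT < MR < CT-MR with magnitudes in the ratio a
  multimodality delineation study reports.
* **Sub-voxel level sets**: a plain voxel EDT is quantised into whole
  boundary shells, so thresholding it cannot represent sub-voxel offsets.
  `refined_signed_distance_mm` instead inverts the Gaussian-blurred
  indicator through the normal quantile function (for a flat boundary the
  blurred value at signed distance d is Φ(−d/σ)), giving a continuous
  distance estimate accurate to fractions of a voxel near the surface with
  the sign snapped to the mask — the zero level set reproduces the input
  exactly, and volumes respond smoothly and near-linearly to mm offsets.
* **Observer contours**: the modality truth's boundary is displaced by
  `role_bias + global_draw + local_field`, where the global draw is a
  whole-contour inflation (SD per modality: CT 1.45, CT-MR 1.10, MR 0.25 mm),
  the local field is unit-variance band-limited noise (10 mm correlation
  length) scaled per modality (CT 0.95, CT-MR 0.80, MR 0.25 mm), and the
  role bias is −0.9 mm for radiologists, +0.55 mm for oncologists.
  Amplitudes were calibrated by simulation so the SD-table column means
  land near the 4.47 / 3.71 / 2.49 cm³ targets with CT > CT-MR > MR, and
  the role bias makes oncologist volumes systematically larger. Radial
  displacement of a level set keeps contours connected and smooth, as real
  delineations are; voxel-flip noise would not.
* **PET phantom**: uniform background SUV 2.0, tumour at 8:1 contrast,
  convolved with a 7 mm FWHM Gaussian point-spread function plus white
  noise (SD 0.10 SUV), with a tumour ROI 8 mm outside the PET truth and a
  background shell 12 mm beyond that.
* **Missingness**: per-contour Bernoulli drops at per-modality rates
  (CT 0, MR 0.073, CT-MR 0.236 — the completion fractions such studies
  report), with the guard that no patient×modality cell is left with fewer
  than two observers (restored contours are noted). PET is never dropped.

Determinism: every random stream is keyed on (seed, stage tag, patient,
observer id, modality), so identical (config, seed) regenerates a
bit-identical study and observers are independent but reproducible.

What the generator does **not** emulate: head-and-neck anatomy, dental
artefact, attenuation/scatter physics, inter-patient correlation of
observer behaviour, or systematic disagreement about tumour *location*
(observers perturb a shared truth, so concordance metrics sit higher than
clinical inter-observer values — the structure, orderings and effect signs
are emulated, not the absolute DICE level). Passing tests therefore show
the pipeline recovers known structure from data obeying its assumptions;
they do not certify performance on clinical images.

## Statistical verification and problem sizes

The suite verifies, at sizes chosen to keep a full run in a couple of
minutes on one CPU:

* metric equivalence with an independent set-arithmetic / nearest-point
  oracle on 200 random pairs up to 16³ voxels (1e-9), plus algebraic
  identities on every pair;
* type-I error of the α = 0.02 modality contrast within the 99 % binomial
  interval over 200 simulated cohort-sized studies (volume records drawn
  directly from the generative model);
* sign recovery of a +20 % modality effect and a 1.5× role effect in
  ≥ 80 % of 200 replicates (the modality effect also at p < 0.02 — power
  ~97 %; the role contrast is informed by only five observer draws, so
  significance power is ~65 % by design and only the sign is asserted);
* SD-ordering detection on nine fixed full synthetic studies: column-mean
  ordering in the majority of seeds and Tukey CT-vs-MR rejection in the
  majority. These conditions are borderline-powered on purpose: the
  reference 11-patient SD table itself yields ANOVA p = 0.048 under the
  same procedure;
* PET sphere recovery within one voxel shell for radii 5–15 mm with
  live-calibrated coefficients, and exact (1e-9) coefficient recovery on
  noiseless calibration data;
* byte-identical report bundles for repeated runs (no timestamps are
  written; provenance carries the config hash, seed and package version).

## Known limitations

* Wald p-values from the mixed models are asymptotic; with 11 patients
  they are approximate (the null simulation shows slight conservatism).
* The Tukey step inherits the independence approximation discussed above.
* Nearest-neighbour resampling can move a contour by up to half a voxel;
  metrics between masks resampled from other frames carry that
  quantisation.
* The probit-based sub-voxel distance saturates ~6.7σ (≈13 mm at the
  default σ = 2 mm) from the boundary; configured offsets beyond that are
  not representable (defaults stay far below).
* `polygons_to_mask` is a minimal planar-contour voxeliser (voxel counted
  iff its centre is inside or on the polygon boundary); it is a
  convenience importer, not a treatment-planning-dialect parser.
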