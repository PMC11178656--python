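# Methods

This note documents the models, conventions and numerical choices behind
`gliorad`, in the order the pipeline runs.

## Data model and time coordinates

All images of one subject live on a single co-registered grid (same shape
and spacing); the package validates congruence and deliberately does not
register or resample across native grids — co-registration is an
acquisition-side concern. Raw PET values are arbitrary
activity-concentration units: body-weight SUV scaling cancels in TBR and
does not affect TTP or slope signs, so it is not modelled.

The time coordinate of every kinetic computation is the **frame midpoint in
minutes**. The midpoint is the unbiased representative of a
uniform-within-frame sample; with the standard 16-frame 0–40 min schedule
the frames with midpoint > 3 min have midpoints {4, 7.5, 12.5, 17.5, 25,
35} min — exactly one per TTP reporting category (<5, 5–10, 10–15, 15–20,
20–30, 30–40 min).

## Kinetic maps

* **TTP**: argmax of the TAC over frames with midpoint > 3 min (this
  excludes the ten early 10 s / 30 s blood-pool frames and nothing else).
  Ties break toward the earliest frame. A curve still rising at the end of
  the acquisition has no interior maximum; it receives the final midpoint
  (35 min) rather than a missing value, so monotonically increasing
  kinetics land in the 30–40 min category by construction.
* **Late slope**: unweighted OLS over the last three frames (15–40 min),
  reported **per hour**. Only the sign is interpreted clinically; the unit
  is a package convention recorded in the output metadata.
* **TBR**: division by the mean over the healthy-background mask (≥ 50
  voxels required; the mask is an input with recorded provenance). Dynamic
  TBR normalizes each frame by its own background mean, flattening the
  background TAC. TBR is invariant to positive rescaling of the input by
  construction.

## Synthetic phantom cohort

The generator emulates the statistical structure the analysis assumes — not
anatomy. Each subject is an ellipsoidal tumor (necrotic core, active rim,
edema shell) at a random interior position of a 64³ grid at 2.036 mm
isotropic spacing, with a confining mask ⊇ whole-tumor (T2) mask and a
disjoint healthy-background region. Voxel TACs are
`baseline + amplitude·f_label(t) + N(0, σ)`:

* wild-type `f`: linear uptake to a peak at 10 min, then linear washout
  (30% by 40 min) — TTP at the 12.5 min midpoint, negative late slope;
* mutant `f`: saturating exponential rise with a 25 min time constant —
  TTP at 35 min, positive late slope.

These functional forms are generator configuration: the real class
signatures are only qualitative (early peak + washout vs. monotone rise),
and any pair of curves with those shapes is equally valid. Amplitudes
(rim 1.5 wild-type / 0.9 mutant; core 0.4×, edema 0.15× of rim) are chosen
so the late static TBR of both classes clears the 1.6 iso-contour while
wild-type uptake is visibly higher. Static contrasts give wild-type tumors
higher TSPO TBR; T1CE rim contrast exceeds core contrast exactly when the
subject draws ring enhancement.

Cohort structure defaults: 87 subjects at prevalence 59:28
wild-type:mutant; ages from class-conditional truncated normals (wild-type
mean 62 y, mutant mean 43 y, SD 12, truncated to 21–84) so age alone is
informative; ring-enhancement probability 28/59 for wild-type and 1/28 for
mutant (back-computed from the subgroup accounting of a typical cohort);
sex independent of label with P(f) = 37/87. The exact means are invented
and configurable; they reproduce the qualitative relationships (age
predictive, sex not, ring enhancement predominantly wild-type).

What the phantom does **not** model: anatomy and brain templates, partial
volume and scanner PSF, arterial input functions, registration error,
intensity non-uniformity, and realistic feature-level effect sizes. A high
AUC on phantoms therefore demonstrates correctness of the machinery
(features capture the injected contrast; CV is unbiased), not clinical
performance.

Determinism: subject `i` is generated from `default_rng([seed, i])`
(metadata) and `default_rng([seed, i, 1])` (images), so any subject is
reproducible in isolation and cohorts are bitwise reproducible.

## Segmentation

`mask = (TBR ≥ threshold) ∧ confining`, threshold 1.6 by default (1.3/1.8
as sensitivity settings for TSPO). An empty mask is legal and means "tumor
not visible in this modality"; subjects below the visibility floor
(default 10 voxels — the floor is explicit configuration, as "not visible"
has no canonical quantitative definition) are excluded from that
modality's feature rows, with the exclusion logged. An optional
26-connectivity component filter (off by default) removes stray
suprathreshold noise voxels that would otherwise contaminate texture
matrices. Under the T2 volume-definition mode the whole-tumor mask (active
+ necrotic + edematous) is routed to every modality; for phantoms it is
generator ground truth, and any externally produced mask with the same
provenance is accepted interchangeably.

The FET-derived images (static averages and kinetic maps) all share the
iso-contour of the late static TBR_FET20-40 image — the clinically
established definition of the metabolically active volume.

## Radiomics

* **Resampling**: trilinear for intensities, nearest-neighbor for masks,
  voxel-center convention; identity when the input is already at the
  target spacing (2.036 mm isotropic by default).
* **Discretization**: fixed bin width per modality, frozen before any
  modeling. Intensity images use the prevalence-weighted rule
  `0.6·mean(IQR_wt)/4 + 0.4·mean(IQR_mut)/4` with subject-wise ROI IQRs
  (voxel pooling across subjects would weight large tumors more; the
  subject-wise average is the natural reading and the default). TTP maps
  take at most six discrete values, so an IQR-derived width degenerates;
  their width is fixed a priori at 5.1 min, which keeps all six
  acquisition categories in distinct bins. Bins are anchored at the ROI
  minimum for intensity images and at zero (bin edges on integer multiples
  of the width) for TTP maps — TTP values live on an absolute time axis
  and must not change bins with the ROI minimum. Because the width rule
  needs both classes' IQRs, the widths are cohort-level preprocessing, not
  re-fit per CV fold; this leaks one scalar per modality and is accepted
  and documented.
* **Feature families**: 18 first-order, 24 GLCM + 16 GLRLM + 16 GLSZM +
  5 NGTDM + 14 GLDM texture, 14 shape. Conventions: GLCM symmetric,
  13 unique 3-D directions, per-direction features averaged (not
  matrix-merged); GLRLM likewise; GLSZM zones by 26-connectivity, single
  matrix; NGTDM 26-neighborhood distance 1 with out-of-mask neighbors
  ignored; GLDM 26-neighborhood, level tolerance α = 0, dependence size
  counts the center voxel (minimum 1). Moment statistics use the
  population convention and kurtosis is uncorrected (normal ≈ 3).
  Logarithms use base 2 with a machine-epsilon guard. A single-voxel ROI
  yields NaN for all texture features; a constant ROI yields NaN skewness
  and kurtosis, Correlation 1, Imc1 0 and MCC 1 by the usual degenerate
  conventions. NaNs are flagged-missing: columns missing in > 20% of rows
  are dropped before CV, the rest are imputed with the training-fold
  median inside the pipeline.
* **Shape**: surface quantities come from a marching-cubes mesh of the
  zero-padded mask indicator smoothed with a Gaussian of σ = 0.5 voxel.
  Meshing the raw binary mask overestimates smooth surface area by ≈ 7%
  (staircase effect), biasing sphericity of a digital ball to ≈ 0.93; the
  half-voxel smoothing restores ≥ 0.96 at radius 8–12 voxels while
  changing mesh volume by < 2%. Axis lengths are 4·√λ of the principal
  components of the physical voxel centers; masks with < 8 voxels get NaN
  mesh features. Maximum 2-D diameters are computed on the mesh-vertex
  projections onto the three coordinate planes.

All first-order and texture features are verified against independent
naive-loop implementations (per-pair matrix accumulation, explicit flood
fill, voxel-walked runs) to 1e-8 relative tolerance on 100 random ROIs in
the test suite — the reference for correctness is that dual route, not an
external tool.

## Classification

Balanced L1 logistic regression (liblinear, unpenalized intercept,
`random_state` fixed) inside stratified 5-fold 50-repeat nested CV:
repeat `r` derives its outer split from seed `base_seed + r`, each outer
split runs an inner stratified 5-fold grid search maximizing mean inner
AUC over C ∈ {0.1, 0.3, 0.5, 0.8, 1.0} (and n ∈ {3, 5, 10} when top-n
selection is active), then the whole pipeline is refit on the outer
training fold and scored once on the untouched outer test fold — 250 test
AUCs in total, reported as mean ± SD. Ties in the inner search break
toward smaller C, then smaller n: prefer stronger regularization and
sparser models. Only the hyperparameters applicable to the active mode
are tuned (C alone for unimodal runs; C and n for multimodal top-n runs).
The positive class is IDH wild-type. Scaling, imputation, filtering and
selection statistics are computed on training folds only — asserted by an
adversarial test feature that separates classes within test folds but
cancels across training folds and provably cannot lift the AUC. Subgroup
analyses (non-ring-enhancing, female-only, male-only) re-run the identical
machinery on filtered rows and require ≥ 5 subjects per class. The
age-alone and sex-alone baselines are ordinary runs with a single
covariate column.

When the inner grid has a single candidate the inner loop is skipped; when
the L1 path zeroes every feature, the model degenerates to intercept-only
and scores 0.5 AUC (all-tie decision scores).

## Problem sizes and runtimes

Defaults are desk-scale by design: 64³ grids at 2.036 mm, 100-subject
recovery experiments, texture matrices on cropped ROI bounding boxes. A
full 100-subject feature extraction takes ~15 s and one 50-repeat nested
CV on ~90 features ~1 min on a single core. The permutation null is
estimated as the mean over 8 independent label permutations: with 100
subjects and effectively categorical TTP features a single permutation
retains chance association of up to ±0.06 AUC, which averaging removes.

## Known limitations

* Phantom effect sizes are far larger than clinical ones; recovery AUCs
  near 1.0 validate the machinery, not the clinical claim.
* The bin-width rule leaks one cohort-level scalar per modality into the
  CV (see above).
* Shape features depend mildly on the mesh-smoothing σ; σ = 0.5 voxel is
  fixed and documented rather than exposed as a tuning knob.
* No wavelet/LoG filtered-image features, 2-D extraction, DICOM ingestion,
  registration, harmonization, or compartmental kinetic modeling.
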