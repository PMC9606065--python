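# Methods

This note documents the models, surrogates, numerical choices and
limitations behind `petsynth`. It is the package's own account of what the
code computes; every number quoted here is produced by the test suite or
`scripts/acceptance.py`, not asserted from elsewhere.

## Problem setting

Whole-body FDG-PET at the maximum table speed of a modern digital PET/CT
scanner (50 mm/s vs 1.5 mm/s for a standard acquisition, a ~33.3-fold
reduction in acquisition time) produces images dominated by count noise.
The package implements an image-to-image translation approach to this
problem: a conditional GAN is trained on paired (ultra-short, full-time)
acquisitions to synthesize a full-acquisition-time image from the
ultra-short scan, optionally conditioned on the co-registered CT. The
evaluation methodology — body-masked image metrics, per-lesion SUV
recovery, PERCIST-stratified matched-pair lesion detection — is implemented
in full.

Because no paired clinical data ship with the package, a phantom simulator
provides data with the statistical structure the method needs. The
simulator is first-class, tested code; its role is to make every stage of
the pipeline executable and verifiable at desk scale.

## Phantom simulator (`petsynth.phantom`)

**Anatomy.** A body is an elliptic-cylinder torso containing five tissue
compartments: lungs (two ellipsoids), liver (ellipsoid), a mediastinal
lymph-node compartment, a posterior spine cylinder (bones), and remaining
soft tissue (other). Each compartment carries a constant background SUV
(defaults: soft tissue 1.0, liver 2.5, lung 0.4, bone 1.4, nodes 1.0) and a
CT attenuation value (air −1000 HU, lung −700, soft tissue 40, liver 60,
bone 700); the CT is smoothed with a 1-voxel Gaussian to soften boundaries.
Focal lesions are spheres of configurable volume and uptake that overwrite
the background. Spheres are rasterized as the *n* nearest voxel centers
with *n* = round(volume / voxel volume), so the rasterized volume is within
half a voxel of the request regardless of sub-voxel center placement.

**Cohort defaults.** Random patients draw 1–4 lesions with volumes
log-uniform in 0.5–30 ml and SUVs log-uniform in 2–27 — the ranges spanned
by clinical lesion tables in this setting — placed inside a randomly chosen
organ with bone and nodal lesions most frequent. 30% of patients are
lesion-free controls (the clinical reader study this package's evaluation
mirrors had 17/50 lesion-free cases). The default grid is 220×220 in-plane
at 3.3 × 3.3 × 3.0 mm voxels; tests and desk runs use 64×64 in-plane at the
same spacing to keep runtimes in minutes.

**Acquisition surrogate.** Continuous-bed-motion acquisition and iterative
TOF reconstruction are replaced by voxelwise Poisson thinning: expected
counts per voxel are `SUV × C × t`, where `C` (`counts_per_suv_fulltime`,
default 100) calibrates full-time counts per unit SUV and `t` is the
acquisition-time ratio (1 for the full scan, 1.5/50 = 0.03 for the
ultra-short scan). A Poisson draw is rescaled to SUV and convolved with a
4-mm-FWHM Gaussian standing in for the reconstruction point-spread
function. This surrogate preserves exactly the property the network must
learn from — voxel noise variance scaling as 1/t (the measured
coefficient-of-variation ratio over a uniform compartment is ≈ √(1/0.03) =
5.77) — and deliberately omits attenuation, scatter, randoms, axial
sensitivity profiles and the variable-speed abdominal emphasis of real
protocols. `C = 100` makes the full-time scan low-noise (CoV ≈ 10% per
voxel in soft tissue) and the ultra-short scan count-starved (~3 expected
counts per soft-tissue voxel), which is the regime of interest. `C` has no
measurable counterpart in the published setting and is exposed as a
configuration knob.

**Determinism.** Every phantom is a pure function of its spec; the paired
scans use sub-seeds `seed` (full-time) and `seed + 1` (ultra-short), so
pairs are bit-reproducible and the two noise realizations independent.

## Preprocessing (`petsynth.preprocess`)

PET volumes are converted to body-weight SUV, clipped at a fixed ceiling of
SUV 50 and scaled to (0, 1); uptake above 50 saturates by design. CT is
resampled to the PET grid (trilinear, −1000 HU fill) and windowed from
(−1000, 3000) HU to (0, 1). For each valid axial slice (the first and last
slices are never predicted, only used to complete their neighbours'
stacks, so an N-slice volume yields N−2 samples) a 3-channel 2.5D stack
(previous, center, next) is built per modality; PET and CT stacks
concatenate to 6 channels. Samples are padded symmetrically with the
background value (0 in normalized space, i.e. −1 after the final
`x → 2x − 1` rescale) to the network resolution — 224 for the full-scale
profile, matching a 220-pixel reconstruction matrix with a 2-pixel border.
Every step has an exact inverse on its non-saturated range;
`postprocess_prediction` applies the inverse chain, clamps negatives, and
fills the two unpredicted edge slices by replicating the nearest predicted
slice (recorded here as the package's convention; any choice for those two
noise-dominated slices is defensible).

## Network and training (`petsynth.nn`, `petsynth.gan`)

**Architecture.** The generator is coarse-to-fine: a global network runs on
a 2×-downsampled copy of the input (7×7 opening convolution, then
downsampling stages implemented as stride-1 3×3 convolutions followed by
2×2 average pooling, residual blocks, nearest-neighbour upsampling), and a
local enhancer runs at full resolution, adding the global network's final
feature map to its own encoded features before its residual blocks and
output head (7×7 convolution, tanh). Instance normalization follows every
convolution except the output head. With the PET/CT input, the opening
convolution of both encoders can be a 2-group convolution, so PET
(channels 0–2) and CT (channels 3–5) are processed by disjoint filter
groups with structurally zero cross-connections — verified exactly in the
tests by perturbing CT channels and asserting bit-identical PET-group
activations. The three variants are M1 (PET-only), M2 (PET/CT), M3 (PET/CT
with the group convolution).

The discriminator is a patch classifier applied at three scales (input
pairs average-pooled 0, 1, 2 times), each scale receiving the
(condition, image) channel concatenation and exposing per-block activations.

**Objective.** Least-squares GAN loss plus a feature-matching loss: the L1
distance between discriminator activations for (condition, real) and
(condition, fake) pairs, averaged over layers (excluding the final score
map) and discriminators, weighted by λ = 10. There is no direct pixel loss;
at this scale the feature-matching term does most of the reconstruction
work while the GAN term keeps outputs on the image manifold.

**Optimization.** Adam (β₁ = 0.5, β₂ = 0.999), batch size 4, learning rate
0.002 held for the first half of training and then decayed linearly to zero
(the full-scale protocol is 100 epochs with decay from epoch 50; desk
profiles use 6–10 epochs with decay from the midpoint). Cross-validation
folds are assigned per patient — never per slice — and the final prediction
averages the fold generators' outputs in (−1, 1) space before inversion to
SUV.

**Implementation.** The networks are written directly in numpy with
explicit backpropagation (im2col-free convolution via per-offset
matmuls, instance-norm and pooling backward passes, Adam), sized for a
single CPU. All layer gradients are validated against central-difference
numerical differentiation; training is bit-reproducible given the config
seed. The full-scale profile (`NetConfig.full_scale()`: 224-pixel inputs,
base width 64, 9 residual blocks, 3-layer discriminators) is expressible
but not intended to be trained on CPU; the desk profile (64-pixel inputs,
base width 16, 2+1 residual blocks) trains in minutes. A learning rate of
0.002 is used deliberately — it is the rate this training protocol states,
ten times the historical pix2pixHD default of 0.0002 — and works at desk
scale.

## Image metrics (`petsynth.metrics`)

MAE (in SUV), PSNR and SSIM are computed over a patient-specific body mask;
volumes are zeroed outside the mask first. PSNR uses a fixed data range of
50 SUV (the normalization ceiling) so scores are comparable across
patients. SSIM uses a uniform 7×7×7 window with K₁ = 0.01, K₂ = 0.03 and
sample-covariance normalization, computed in 3D and averaged over voxels
whose window center lies inside the mask (a per-slice 2D mode is available
behind a flag). The masked implementation agrees with
`skimage.metrics.structural_similarity` to 1e−6 on fixtures where the
masking semantics coincide. The body mask is derived from CT by
thresholding above −500 HU, morphological closing with a 3-voxel ball
(against an edge-replicating border, since the torso spans the axial field
of view), keeping the largest component and filling holes per slice; on
phantoms it reproduces the ground-truth mask up to a 1-voxel boundary band.

## Lesion evaluation (`petsynth.lesions`)

Per-lesion metrics on a given image: volume (voxel count × voxel volume),
SUV_mean and SUV_max over the mask, and SUV_peak — the image mean over a
1-cm³ sphere (radius 6.2035 mm, voxel-center discretization) centered on
the lesion's hottest voxel, with argmax ties resolved to the lowest
(z, y, x) index and clipping at the image boundary flagged. A lesion is
PERCIST-measurable when SUV_peak strictly exceeds
1.5 × mean(SUV_liver) + 2 × SD(SUV_liver); the liver reference is measured
in a 3-cm spherical VOI placed at the deepest liver voxel (falling back to
the whole organ when it cannot host the VOI, recorded in the output).

Matched-pair detection compares reference lesion masks (from reading the
full-time image) against candidate masks (from reading the synthetic
image): components are 26-connected, IoU is computed on 3D voxel sets, each
reference lesion takes its highest-IoU candidate (ties to the smaller
label), and *any* overlap (IoU > 0) counts as detection at the correct
position — the masks come from different images, so exact voxel agreement
is not demanded. Rates are aggregated at lesion, organ (any lesion in a
(patient, organ) cell) and patient level, each split into
PERCIST-measurable and non-measurable strata; patient-based sensitivity is
detected-positives over positives and specificity is one minus the
false-positive rate over lesion-free patients. Detected-vs-missed group
comparisons use the two-sided Mann–Whitney U test (exact distribution for
tie-free groups of ≤ 8, tie-corrected normal approximation otherwise, via
scipy).

**Surrogate reader.** No human reader exists for phantom images, so a
reproducible surrogate stands in: within each organ compartment, voxels
exceeding the organ's median uptake plus k (default 3) robust standard
deviations (MAD-based, floored at 0.15 SUV) are lesion candidates;
components smaller than 2 voxels are discarded. This is a deliberately
simple stand-in, not a model of a human reader, and none of the
paper-defined metrics depend on it — it only supplies the masks that a
reader would supply. At the default thresholds it reads occasional noise
clusters in lesion-free full-time phantom images, so patient-level
specificity of a phantom study can be degenerate; the published cohort
counts embedded in `petsynth.reference_cohort` are the clinically comparable
source for patient-level sensitivity/specificity.

## Reference cohort counts (`petsynth.reference_cohort`)

The per-organ, per-stratum detected/missed lesion counts of the published
50-patient reader study (229 PERCIST-measurable and 69 non-measurable
lesions across 33 lesion-positive patients; 26 of 33 positives detected, no
false positives among 17 lesion-free patients) are embedded as data. The
acceptance suite expands them to per-lesion records and verifies that
`detection_report` reproduces every published rate (e.g. 0.78 for
PERCIST-measurable lesions, 0.22 for non-measurable, 65% overall, 79%
sensitivity, 100% specificity). The true per-patient lesion composition is
not published, so patient- and organ-level aggregates of the expanded table
are nominal; only lesion-level rates and the patient-level outcome are
exact.

## What desk-scale results do and do not show

The end-to-end acceptance run (12 phantoms at 64×64×16, two folds, 10
epochs, PET-only variant) verifies the *mechanism*: the trained ensemble
beats the raw ultra-short input on body-masked MAE and SSIM against the
full-time reference, detection rates are higher for PERCIST-measurable
than non-measurable lesions, and missed lesions have lower uptake and
volume than detected ones. These are the qualitative signatures of the
full-scale clinical result. Desk-scale numbers are *not* comparable to
clinical ones: the phantom lacks anatomical texture, physiological uptake
variation, motion and reconstruction artifacts; the network is ~100×
smaller than the full-scale profile; and the surrogate reader is cruder
than a physician. Which input variant (M1/M2/M3) wins is a patient-data
question — on piecewise-constant phantoms the CT adds little information —
so the package computes the variant comparison table but asserts nothing
about its ordering.

## Numerical conventions

- Arrays are (z, y, x) with axis 0 axial; spacing/origin follow the same
  order in mm. NIfTI I/O transposes to the on-disk (x, y, z) order.
- Float volumes are written as float32; label volumes as int32. Network
  math is float32; gradient tests cast to float64.
- Connected components use 26-connectivity; labels are ordered by
  descending size. CT interpolation is trilinear; labels nearest-neighbour.
- Degenerate inputs fail loudly: empty masks, empty folds, invalid time
  ratios, mismatched grids and channel counts all raise with a message
  naming the offender. Zero-MSE PSNR returns +inf rather than raising.
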