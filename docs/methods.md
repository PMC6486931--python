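# Methods

This note documents the models, parameter choices and numerical decisions
behind `mplesion`, and what the phantom-based validation does and does not
establish.

## Pipeline overview

A study enters the pipeline as a set of co-registered volumes on one
reference grid (axis order `(frame, z, y, x)`, 0-based voxel indices,
NIfTI affines respected on I/O): a DCE-MRI series with per-frame
acquisition times, three high-resolution volumes (pre-, peak-,
post-contrast), DWI b0/b850 with the ADC map, an FDG-PET volume, a breast
mask and a voxel-wise lesion annotation. Registration itself is out of
scope; `resample_to_reference` only moves volumes between grids given
their affines (nearest or linear interpolation).

Segmentation is voxel-wise binary classification inside the breast mask;
classification operates on per-lesion feature vectors; both use random
forests (100 trees, Gini splitting, unlimited depth, seeded — the
conventional defaults, fixed here for reproducibility).

## Intensity preprocessing

The breast mask is grown from the pre-contrast volume: an Otsu threshold
separates tissue from air, the seed is the brightest voxel of the largest
above-threshold 6-connected component, and the mask is that voxel's
component of the above-threshold set (equivalent to intensity-based
region growing with a global stopping threshold; deterministic and
parameter-light).

MRI intensities are standardised to zero mean and unit SD estimated from
the breast area. For the DCE series the statistics come from the
pre-contrast frames only and one shared affine map is applied to every
frame, preserving inter-frame enhancement contrast. The three
high-resolution volumes share the affine map derived from the
pre-contrast volume so that peak and post keep their enhancement offset
(per-volume statistics would erase it). When a noiseless baseline has
zero variance (ideal phantoms), the scale falls back to the enhanced
frames; the map remains affine. DWI, ADC and PET are consumed on their
native scales — their absolute values (s/mm², uptake) are themselves
informative.

## Voxel features

The per-voxel table has 62 named columns in seven groups: 26 DCE frame
intensities from the first enhancing frame `j`, 25 two-frame forward
differences `(I(x, i+2) − I(x, i)) / (t_{i+2} − t_i)`, the enhancement sum
normalised by its in-mask maximum, pre/peak/post intensities and their
three pairwise differences, b0/b850/ADC, and PET. The difference index
runs over `i = j..j+24`, which matches the 25-count with the smallest
frame demand; when the series ends exactly at `j+25` the difference window
start is truncated by one frame. Contrast arrival is detected as the
first frame whose mean in-mask signal exceeds the running baseline mean by
two baseline SDs, confirmed by the following frame (enhancement persists,
noise spikes do not); at least three baseline frames are required.

## Segmentation

Training pools up to 1000 randomly drawn voxels per class per patient
(without replacement, seeded). The probability threshold is selected on a
grid of 101 values in [0, 1] to maximise the mean training-set DSC, ties
broken toward the smaller threshold (favouring sensitivity). Predicted
masks are labelled with 6-connectivity; in evaluation mode, components
with no overlap with the annotation are discarded — this mimics a reader
dismissing obvious false positives (vessels, enhancing parenchyma) before
diagnosis, and allows classification accuracy to be measured independent
of segmentation errors. DSC of two empty masks is defined as 0. LOOCV
reports per-lesion rows (DSC attributed to the blobs touching that
lesion), per-patient aggregate rows, voxel-level sensitivity, and a
detection flag (≥ 1 overlapping blob).

## Lesion features

**CKC.** In-lesion signal-time curves (25 frames from contrast arrival)
are clustered by fuzzy c-means (c = 5, fuzziness m = 2 — conventional FCM
settings, c matching the ADC/PET choice) and the cluster-centre curve with
the highest enhancement rate is kept. The rate criterion is
`(max(curve) − curve[0]) / (t_max − t_0)`, a literal "enhancement rate";
it is isolated in one function and swappable. Lesions smaller than the
cluster count fall back to the mean curve with a warning flag. Curve
dynamics are summarised by 21 four-frame forward differences
`(c[i+4] − c[i]) / (t_{i+4} − t_i)`.

**Kinetic fit.** Bounded trust-region least squares with three seeded
restarts fits `(G, α, τ, t½, β, k)`; `α, τ > 0` are enforced by the
bounds. The time origin is shifted one frame after contrast arrival so
`t^k` stays defined for `k < 1`. Curve summaries over the 7-minute
window use a 2001-point grid: AuC by trapezoidal quadrature, Cmax/Tmax by
grid argmax plus bounded local refinement, T1/2 as the earliest root of
`C(t) = Cmax/2` (bracketed bisection), MDER as the maximum of the
hand-derived analytic derivative. Non-convergent fits are flagged, never
silently zeroed.

**Texture.** Spatial GLCMs accumulate all 26 unit-offset neighbour pairs
with both voxels in the lesion; intensities are quantised to 128
equal-width bins over the in-mask range, which makes the statistics
invariant to any affine intensity rescaling (so the choice of raw versus
standardised input volumes is immaterial except for binning edge cases;
standardised volumes are used). Spatio-temporal GLCMs pair each voxel's
value in two volumes of the enhancement sequence — (pre, peak),
(pre, post), (peak, post) — with bins shared over the pooled range of
both volumes so the two axes are commensurate. Matrices are symmetrised
and normalised to sum 1 and summarised by Haralick's 13 second-order
statistics; correlation-type statistics are defined as 0 for degenerate
marginals.

**ADC/PET cluster extremes.** In-mask intensities are split into five
fuzzy clusters; the lowest centre (ADC: restricted diffusion) and highest
centre (PET: focal uptake) are the features. Fewer than five distinct
voxels fall back to the in-mask extreme with a warning.

**Shape.** Volume, surface area (marching-cubes mesh of the lightly
Gaussian-smoothed binary mask — smoothing removes the voxel staircase
that inflates the raw mesh area by ~10%), compactness `36πV²/S³`,
sphericity, surface-to-centroid radius mean/SD, elongation (square root
of the extremal principal-component variance ratio) and convexity
(volume over convex-hull volume), all voxel-spacing aware. The exact
descriptor set in the source literature is not restated there; this is a
standard morphology set and is labelled approximate.

## Classification and ranking

The lesion forest's threshold maximises training F1 on a 101-point grid
(ties toward the smaller threshold). Evaluation is leave-one-lesion-out;
when a ranking method is requested, the ranking is recomputed inside each
training fold, so the held-out lesion cannot influence feature selection
(verified by a label-flip invariance test). Experiments are repeated
(default 20) varying only the forest seed; AUC is reported as mean ± SD
over repeats, sensitivity/specificity as means at the fold thresholds.
The AUC is the rank-based Mann–Whitney statistic with midrank ties.

mRMR uses the MID (difference) form — relevance minus mean redundancy —
with equal-frequency 3-bin discretisation for mutual-information
estimation, the original default for continuous features; MIQ is
available as an option. Gini importance is the forest's mean impurity
decrease (normalised to sum 1). The characteristic redundancy contrast —
duplicated informative features co-ranked by GI but demoted by mRMR — is
asserted on seeded simulations.

The classification-from-segmentation path computes lesion features on the
union of predicted blobs overlapping each annotated lesion; undetected
lesions fall back to the manual annotation and are flagged, so
classification can be evaluated on all lesions regardless of segmentation
misses.

## The phantom

The phantom emulates the study's input data with known ground truth. Each
patient is an ellipsoidal "breast" of uniform tissue (baseline signal 100
arbitrary units) on a 32³ grid of 1.5-mm isotropic voxels, with one
spherical lesion of 5–9 mm radius per patient, a 32-frame DCE series at
13.2 s per frame with contrast arriving at frame 6 (so the 26-frame
feature window exists), optional straight-tube enhancing vessels
(blood-pool kinetics, background ADC/PET, excluded from the annotation),
and additive Gaussian noise (SD 2 on the signal scale, proportionally
scaled for ADC and PET).

Lesion kinetics are drawn from class-specific uniform priors chosen for
separability — published per-class parameter values are not available, so
the priors encode the qualitative patterns: malignant `G` 120–180, `τ`
8–18 s, `t½` 35–70 s, `β` −8·10⁻⁴…−3·10⁻⁴ (washout); benign `G` 60–110,
`τ` 35–60 s, `t½` 150–230 s, `β` = 0 (persistent). Malignant lesions get
ADC 0.9·10⁻³ mm²/s and PET uptake 4.0 versus benign 1.4·10⁻³ / 1.2 and
background 1.8·10⁻³ / 0.5. DWI follows the mono-exponential forward model
`S(b) = S0·exp(−b·ADC)`; the high-resolution peak/post volumes are the
kinetic model evaluated at each lesion's enhancement maximum and at the
end of acquisition, preserving the pre/peak/post semantics without
modelling a second pulse sequence. Cohorts are pure functions of
`(config, seed)`.

What the phantom does **not** emulate: registration misalignment, breast
compression or coil inhomogeneity, parenchymal background enhancement
texture, PET partial-volume effects, irregular or spiculated lesion
margins, and multifocality beyond disjoint spheres. Because lesions are
homogeneous spheres with strong multiparametric contrast, phantom
segmentation DSC saturates near 1 and classification AUC near 1; passing
these tests demonstrates that the pipeline's machinery is correct and
unbiased, not that clinical-level accuracy is attained — clinical DSC/AUC
depend on patient data that are not part of this package.

## Validation problem sizes

The test suite and the acceptance script run: 100 noise-free kinetic
recovery fits (median relative error on `G, τ, t½` under 5%);
brute-force GLCM/Haralick/AUC/Dice oracles on volumes up to 5×5×5;
LOOCV segmentation on an 8-patient cohort; LOOCV classification on a
30-lesion balanced cohort (20 seed repeats) plus a label-permutation null
averaged over 5 permutations — a single permutation is one high-variance
draw from the null, and leave-one-out evaluation biases null AUC slightly
below 0.5 (holding out a positive depletes positives in training), which
the averaging makes visible as a stable ≈0.4 rather than an outlier.

## Known limitations

* The CKC enhancement-rate criterion and the FCM cluster count for curve
  clustering follow cited-but-unrestated conventions; both are documented
  design choices, isolated and configurable.
* Shape descriptors approximate a supplementary-material set that is not
  publicly specified.
* The LOOCV unit is the lesion; multifocal patients would contribute
  multiple, non-independent rows. Patient-level grouping is available by
  filtering the feature table on `patient_id`.
* The phantom's vessels are straight tubes; curved or branching vessels
  would stress the post-processing step harder.
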