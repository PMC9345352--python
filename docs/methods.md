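# Methods

## The problem

Given a skull-stripped, atlas-aligned T1-weighted head volume, the pipeline
(1) segments 14 regions of interest — three bilateral inferior-frontal-gyrus
subdivisions plus the hippocampus, amygdala, caudate nucleus and thalamus
pairs — and (2) predicts a continuous per-subject score (a residualized fluid
intelligence measure in the motivating application) from the segmented
structures alone.  The two stages are trained separately: segmentation first,
then regression on the segmented output.

## Stage 1: symmetry-aware segmentation

**Label scheme.** Because the hemispheres are near mirror images, the default
scheme merges each bilateral family into one class: background plus five
foreground classes (`symmetric_5`).  The alternative `per_roi_14` scheme
keeps one class per structure (15 softmax outputs) and is retained to measure
what the anatomical prior buys.  Class indices are assigned by each family's
smallest atlas code, so the mapping is deterministic and documented:
frontal gyrus 1, hippocampus 2, amygdala 3, caudate nucleus 4, thalamus 5.
Background is class 0 and participates in the softmax.

**Network.** A four-level 3D U-Net variant (the fourth level is the
bottleneck).  A 1x1x1 stem lifts the input to 16 channels; each level applies
a *recombination block*: 1x1x1 expansion from C to `expansion`*C (default 4C),
3x3x3 convolution with batch normalization, ReLU, a SegS-E attention block,
and a 1x1x1 reduction to the level's width, summed with a 1x1x1 shortcut
projection of the block input.  Levels are connected by 2x2x2 max pooling and
stride-2 transposed convolutions.  Skip connections are additive after a
1x1x1 projection at every resolution; in addition, the 64-channel tensor
entering the third encoder level (1/4 resolution under the default schedule
16 / 32-64-96-128) is projected to 96 channels and added to the matching
decoder tensor (the "bottleneck skip").  A 1x1x1 head with voxelwise softmax
yields class probabilities.

The SegS-E block computes a weight map with the input's full shape: a
depthwise 3x3x3 convolution with dilation rate 2 (one kernel per channel)
followed by a 1x1x1 channel-mixing convolution, applied to the input by
element-wise (Hadamard) product.  The gate is linear by default; a sigmoid
squashing is available (`se_gate="sigmoid"`).  Two numerical consequences are
worth knowing:

* at initialization a zero-mean weight map would suppress the residual path
  and its gradient, so the pointwise bias starts at 1 (the gate opens as the
  identity);
* the linear gate makes each block quadratic in its activations, so an
  uncalibrated network can overflow float32 in eval mode.  Batch-norm running
  statistics therefore adopt the first training batch outright before the
  usual exponential update (momentum 0.1), which keeps eval-mode inference
  sane even after very short trainings.

**Training.** Patches of 112^3 voxels (desk-scale runs use 32^3) are sampled
uniformly from the training volumes — optionally constrained to contain
foreground — with batch size 10 and 200 iterations per epoch at full scale.
Intensities are z-scored per volume over the positive-intensity (brain) mask.
The objective is soft Dice averaged over foreground classes,
`1 - mean_c (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps)` with `eps = 1e-5`.  Plain
Dice loss barely moves from a cold start when the foreground classes are
small (the gradient is dominated by the denominator and nearly uniform), so
the first half of all steps minimizes voxelwise cross-entropy before
switching to the Dice objective; the warm-up fraction (and an optional
learning-rate scale for the Dice phase) are configurable.  The optimizer is
Adam (default 1e-3; the small desk-scale networks use 1e-2).

**Inference.** Whole volumes are tiled with windows of the training patch
size at 50% overlap and mean-averaged class probabilities; argmax gives the
label map.

## Stage 2: minimum bounding cubes and score regression

For each of the five family classes the tightest axis-aligned box around the
class's voxels (both hemispheres together, so one cube per family) is
cropped, resized to `L_max`^3 where `L_max` is the box's longest edge, and
then resized to the regression input size (64^3 published; desk-scale runs
use 32^3).  The two-step resize is the minimum-bounding-cube (MBC)
normalization; `resize_direct` performs the single-interpolation baseline
for comparison.  Real-valued content is interpolated trilinearly with a
Gaussian anti-aliasing prefilter when downscaling (the one deliberate
deviation from naive interpolation); binary content uses nearest-neighbour.
Cube content defaults to the intensity crop masked to the structure
(background zeroed); unmasked intensity and binary masks are options.

The regressor stacks the five cubes as input channels: three rounds of
[3x3x3 convolution + batch norm + ReLU] with 10, 20 and 1 channels, a
flatten (262,144 features at 64^3), and fully connected layers
262,144 -> 4096 -> 64 -> 1 with dropout 0.5 between the FC layers.  Training
minimizes MSE with Adam on z-scored targets (the inverse transform is stored
with the model); training cubes are randomly mirror-flipped each epoch —
legitimate augmentation because the content is bilateral — and prediction
averages the eight flip variants (test-time augmentation).  Early stopping
on a validation split restores the best weights when a validation fraction
is configured.

## The phantom generator

Real cohort data for this task is access-restricted, so the package ships a
generator whose subjects exercise every pipeline stage: a spherical "brain"
envelope (intensity 0.35) containing 14 ellipsoidal structures placed as
exact mirror pairs about the mid-sagittal plane, carrying the same atlas
codes as the real label maps.  Families differ in mean intensity (0.55-0.95,
mimicking tissue contrast differences between deep-grey structures); voxel
noise is Gaussian (sd 0.05).  Per subject, each family's radii are scaled by
a shared uniform factor of 1 +/- 0.15 (so volumes vary by roughly +/- 45%)
and each instance's centre is shifted independently by up to 2% of the grid
edge, which breaks exact mirror symmetry the way anatomy does.  Subjects
whose jittered structures collide or leave the envelope are redrawn.

The score is morphology plus noise: weight 10 per family on the family's
rendered volume relative to its analytic nominal volume (centred at 1), plus
Gaussian noise with sd 6.  With these defaults the morphological signal
carries roughly half the score variance — a deliberately generous coupling
chosen so recoverability is testable at desk scale, while real
brain-morphometry couplings are far weaker.  Ellipsoids keep true volumes
analytic; the generator makes no attempt at anatomical realism, scanner
artifacts or bias fields, so passing tests demonstrate that the
implementation recovers what its own generative model planted, not
performance on real MRI.

A caveat the phantom makes visible: MBC normalization is scale-free, so
absolute structure volume survives only through relative geometry (the ratio
of blob extent to the fixed inter-hemispheric separation inside each family
box).  Translation jitter corrupts exactly that ratio, which bounds how much
of the volume-driven score any cube-based regressor can recover — see the
limitations below.

## Evaluation

* Dice: exact set overlap `2|A∩B|/(|A|+|B|)`; undefined (error) when both
  masks are empty.
* Average surface distance: surface voxels are foreground voxels with at
  least one six-connected background neighbour (border voxels count);
  directed ASD is the mean minimum Euclidean distance in mm from surface(A)
  to surface(B); a symmetric variant averages both directions.  The reported
  variant is flagged in the report.
* MSE per the usual formula.
* `resampled_eval` repeats a train/test cycle over seeded resamples
  (default 5) and reports mean, SD, and a 95% normal-approximation
  confidence interval (`mean ± 1.96·sd/√n`); Mann-Whitney U is available for
  comparing two runners' per-resample metrics.

## Desk-scale problem sizes

The reference experiments (shared by the test suite and
`scripts/acceptance.py`) use sizes chosen for single-core CPU runs:

* Segmentation: 12 subjects on a 64^3 grid, patch 32^3, stem 4 with channel
  schedule (8, 16, 24, 32) and expansion 2, batch 2, 5 epochs x 100
  iterations, lr 1e-2 (about six minutes).  Held-out mean Dice typically
  reaches ~0.9-0.98 with directed ASD around a voxel; the residual errors are
  confusions between the spatially adjacent caudate and thalamus.
* Merge-mode comparison: 8 subjects at 48^3, patch 24^3, a slim schedule
  (stem 2, channels 4-8-12-16), 2 x 60 iterations, five training seeds for
  each label scheme with foreground-constrained patches (about three
  minutes).  Both schemes share the backbone; only the softmax head differs
  (6 vs 15 classes), so the contrast isolates what the symmetry prior buys
  at matched capacity and budget.
* Regression: 60 subjects at 48^3 with ground-truth label maps, cube edge
  20^3 with the published conv channels (10, 20, 1) and FC
  8000 -> 128 -> 16 -> 1, 80 epochs with mirror-flip augmentation and
  flip-averaged prediction (about four minutes).

## Known limitations

* The NumPy engine is single-threaded and CPU-bound; full-scale (112^3
  patch, 240^3 volume) training is out of reach here and the published
  protocol sizes are exercised only as configuration defaults and shape
  checks.
* Score regression at desk scale operates at its information limit: the MBC
  pathway is scale-free, so the phantom's volume-driven score survives only
  through weak relative-geometry cues.  A linear oracle on near-ideal
  handcrafted cube features barely beats the cohort variance, and the
  flatten-plus-FC CNN — which must find those cues in raw voxels from ~45
  training subjects — typically does not; its held-out MSE sits near the
  mean predictor's.  The regression experiment reports these numbers as
  measured.  With the restricted real cohort (thousands of subjects) the
  sample-efficiency constraint would be far milder.
* The per-ROI (15-class) scheme gives patch-based training an inherently
  ambiguous task on a mirror-symmetric phantom when a patch sees neither
  midline nor envelope context; this is precisely the ambiguity the
  symmetric merge removes, and the comparison experiment quantifies it.
* Sliding-window inference recomputes overlapping windows naively; at 50%
  overlap that is an 8x redundancy traded for simplicity.
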