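# Methods

This note documents the models, numerical choices and limitations of the
`neolesion` pipeline in enough detail to reproduce or modify it.

## Problem setting and assumptions

The pipeline segments *new* MS lesions: hyperintense regions present in a
follow-up FLAIR scan but absent at baseline. It assumes its inputs are
already rigidly co-registered onto a common grid, skull-stripped (background
exactly 0) and bias-field corrected; those steps are standard upstream
preprocessing and are deliberately out of scope. Baseline and follow-up must
share shape and voxel spacing; this is verified at load time and violations
raise a registration error rather than being resampled silently.

All volumes are reoriented to the closest canonical (RAS) axis order on
load, making plane names deterministic: axis 0 is the sagittal slicing axis,
axis 1 coronal, axis 2 axial. Any fixed convention would do; without one,
"axial slice i" is not reproducible across datasets. Canonicalization is
idempotent and is tested as such.

## Intensity normalization

Per scan, independently:

1. **Percentile clip (p = 99)** — foreground (strictly positive) intensities
   above their 99th percentile are set to that percentile. This removes hot
   voxels that would otherwise dominate the later density estimate.
   Percentiles use numpy's linear interpolation between order statistics.
2. **KDE mode rescale** — a Gaussian-kernel density estimate (Scott's rule)
   of the foreground intensities is evaluated on a 1,000-point grid spanning
   their range; the scan is divided by the argmax location, so the dominant
   tissue mode maps to 1.0. Ties break toward the higher intensity (on
   FLAIR the intended anchor is the brighter dominant peak). A constant
   foreground has no density estimate; the scan is then divided by that
   constant (documented fallback).

Clip-then-rescale is one of two defensible orderings of these two steps;
clipping first stabilizes the bandwidth and the mode against the extreme
tail. The transform preserves the rank order of foreground intensities
everywhere except the clipped top, and is scale-equivariant up to the
discretization of the KDE grid (both tested). Background voxels are never
touched.

## Slicing geometry

Slices are zero-padded onto a square canvas by centering; odd remainders put
the smaller margin on the low-index side. This tie-break makes padding a
bijection: each record stores `(orig_shape, pad_offsets)` and unpadding is
exact, which the round-trip property tests exploit (slice → pad → unpad →
restack is the identity on arbitrary volumes). The canvas is 512 px by
default — large enough for any in-plane dimension the target data can
produce — and configurable (desk-scale tests use 32–64). Canvas-centering of
the full field of view is used rather than brain-bounding-box recentering,
which would break exact inversion.

Training pools keep only slices whose new-lesion label contains at least one
pixel, then concatenate the axial, sagittal and coronal lists into one pool
(each record keeps its plane tag). Selection is a pure, idempotent filter.

## Networks

All variants share the encoder–bridge–decoder topology: `levels − 1` encoder
blocks with 2×2 max-pool downsampling between them, a bridge block, and
`levels − 1` decoder stages of biased 2×2 stride-2 transpose convolution →
(optional attention gate on the skip) → channel concatenation → block,
closed by a biased 1×1 convolution and sigmoid. Default filter widths are
(32, 64, 128, 256, 512) on a 2-channel input.

* **Plain block**: [biased 3×3 conv → batch norm → ReLU] × 2.
* **Residual unit** (full pre-activation): `h(x) + F(x)` with
  `F = [BN → ReLU → biased 3×3 conv] × 2`; `h` is the identity when input
  and output widths match, otherwise a biased 1×1 projection. With the
  residual branch zeroed the unit is exactly its shortcut — the
  degradation-resistance motivation is tested as literal passthrough.
* **Attention gate**: both the skip feature `x` and the gating signal `g`
  (the decoder feature before upsampling, i.e. one level coarser) pass
  through BN + ReLU and a biased 1×1 convolution to `inter` channels
  (default: half the skip width, minimum 1). The `x` branch is
  average-pooled onto `g`'s grid, the branches are added, then ReLU → 1×1
  convolution to one channel → sigmoid gives coefficients α ∈ (0,1), which
  are nearest-upsampled back to `x`'s grid and multiply `x` elementwise.
  Averaging-pooling the x branch onto the coarse grid (rather than a strided
  convolution) keeps the gate parameter-light; the α resampling direction is
  fixed by the requirement that the gate's output match `x`'s shape.

The final 1×1 convolution's bias is initialized to `log(0.01/0.99)` so
initial predictions sit near the foreground prior instead of 0.5 — the
standard initialization for heavily imbalanced dense prediction, without
which early dice gradients are dominated by the all-background solution.
Other convolutions use He-normal weights and zero biases.

**Parameter accounting.** `count_parameters` computes the total analytically
from the configuration; batch-norm layers contribute four values per channel
(learned scale and shift plus moving mean and variance), matching the
convention under which deep-learning frameworks report model totals. The
analytic count equals the instantiated model's count for every block /
attention combination in a randomized sweep, and the default plain
configuration totals exactly 7,771,585 parameters. Counts are independent of
input size (the networks are fully convolutional).

## The numpy autodiff engine

`neolesion.nn` is a minimal reverse-mode automatic-differentiation engine:
tensors wrap numpy arrays, each op records a vector-Jacobian product, and
gradients flow by topological sweep. It implements exactly what the networks
need — stride-1 "same" convolution (im2col), 2×2 stride-2 transpose
convolution, batch normalization (training and inference modes), 2×2
max/average pooling, nearest upsampling, channel concatenation, and the
elementwise/reduction ops of the loss. Every backward pass is checked
against central differences; an end-to-end gradient check through the full
residual attention U-Net and the hybrid loss agrees with numeric gradients
to better than 1e-6 relative error. Optimization is standard bias-corrected
Adam.

## Loss

`L = L_dice + w_f · L_focal` with `w_f = 1`:

* `L_dice = 1 − (2·Σ gt·pr + s)/(Σ gt + Σ pr + s)`, smoothing `s = 1`;
  computed per sample and averaged over the batch. The smoothing term makes
  empty-mask slices well-defined (loss 0 for an empty prediction on an empty
  label).
* `L_focal = mean[−gt·α(1−pr)^γ log pr − (1−gt)·α·pr^γ log(1−pr)]` with
  α = 0.25, γ = 2, probabilities clamped to [1e-7, 1−1e-7] for log
  stability. As configured, α multiplies **both** classes; the common
  variant with `1−α` on the negative class is available via
  `alpha_complement=True`. The mean reduction keeps the term's scale
  independent of canvas size.

## Training schedule

Adam, initial learning rate 1e-4; reduce-on-plateau ×0.1 with patience 10
epochs; early stopping with patience 50; batch size 8; up to 200 epochs.
The plateau and early-stop callbacks monitor **validation loss** (the
framework-default monitored quantity); best-weights selection monitors
**validation dice**, computed per slice at threshold 0.5 with the same
smoothing as the loss and averaged. Monitoring dice for the schedule
callbacks is brittle early in training, when the dice signal is flat while
the loss is still falling — the learning rate collapses before segmentation
quality moves.

Augmentation applies one random geometric transform per sample, identically
to both channels and the label: horizontal/vertical flips (p = 0.5 each),
rotation uniform in ±10°, and shifts uniform in ±10% of the canvas —
conventional mild ranges, exposed in `TrainConfig`. Images are resampled
bilinearly, labels nearest-neighbour so they stay binary. All randomness
(splits, augmentation, initialization, batching) flows from seeded
generators, so two runs with the same seeds produce identical first-epoch
losses.

Patient-level splitting assigns whole cases to train or validation, never
slices of one patient to both.

## Reconstruction and fusion

Per plane, predicted probability slices are unpadded via their stored
offsets, binarized at 0.5 (ties map to foreground — a fixed convention is
needed at the boundary), and stacked along the plane axis; missing slice
indices are a hard completeness error. The three per-view binary masks are
fused by voxelwise majority vote (≥ 2 of 3). Voting operates on binary
masks, not averaged probabilities, and is symmetric, idempotent on identical
inputs and monotone — all property-tested against the 8-pattern truth table.

## Evaluation metrics

Connected components use 26-connectivity (configurable); a ground-truth
lesion counts as detected when it shares ≥ 1 voxel with the prediction, and
symmetrically for predicted lesions. Surface voxels are mask voxels with at
least one background 6-neighbour, with outside-the-grid treated as
background; surface distances are Euclidean in millimetres using the voxel
spacing, averaged symmetrically over both surfaces.

Undefined metrics are reported as explicit flags, never coerced to numbers:
DSC when both masks are empty; lesion-wise S/P/F1 when the ground truth has
no lesions (such cases belong to the no-lesion track, scored by predicted
lesion count and volume, optimum zero); surface distance when either mask is
empty; specificity when no true negative is possible. Cohort aggregates
average each metric over the cases where it is defined. An empty prediction
against a non-empty ground truth scores S = P = F1 = 0 by convention.

## Synthetic phantoms

`PhantomConfig` defaults describe the intended test conditions: a 64³ grid
at 1 mm isotropic spacing; an ellipsoidal brain (semi-axes 0.42 × grid) on
zero background; voxelwise two-mode intensity mixture, (mean 100, sd 5) with
weight 0.4 and (mean 200, sd 8) with weight 0.6, giving the bimodal
foreground histogram the KDE normalizer expects; 3 stable and 2 new
spherical lesions of radius 2–5 voxels with peak intensity 1.6 × the
brighter mode and smooth radial falloff to 0.7 × peak at the rim; additive
Gaussian noise (sd 5) drawn independently per time point. Lesion centers are
rejection-sampled inside the brain without overlap (bounded retries, then a
placement error). The ground truth marks exactly the new-lesion spheres.

By construction, mean lesion intensity exceeds the brighter tissue mode and
the two time points are voxel-identical outside new lesions up to the noise
draws — both tested. Cohorts derive per-case seeds from one generator and
can include a configurable fraction of cases with no new lesions, emulating
cohorts in which many patients show no activity.

What the phantoms do **not** emulate: MR physics (bias fields, partial
volume, scanner texture), anatomy, registration error, or ambiguous/subtle
lesions. Passing phantom tests therefore demonstrates the correctness of
the pipeline's machinery — geometry, losses, optimization, metrics — not
clinical-grade segmentation accuracy on real data.

## Problem sizes used in tests

The test suite runs the pipeline at desk scale by choice: 32–64 voxel
phantoms, 32–64 px canvases, filter stacks like (4, 8) or (8, 16, 32), and a
20-slice memorization pool for the learning check, which runs the full
Adam/plateau/early-stop schedule (≈ 600 gradient steps) and verifies the
pool dice exceeds 0.8. Metric oracles run 1,000 randomized ≤ 8³ mask pairs
against exhaustive brute-force implementations. The 512-canvas default
network is built and counted exactly, but trained only at reduced scale.

## Known limitations

* Training at the full 512×512 canvas is computationally expensive on the
  numpy engine; it is intended for correctness and desk-scale experiments,
  not production GPU training.
* The attention-gate internals (intermediate width, pooling choice) follow
  common practice; other gate designs exist and would change the parameter
  counts of the attention variants.
* The challenge-grade lesion-matching rules used by evaluation platforms are
  more elaborate than the ≥ 1-voxel overlap criterion implemented here; no
  minimum-lesion-size filter is applied before counting components.
* Masks with values outside {0, 1} are rejected, not thresholded; silent
  coercion hides labelling errors.
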