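# Methods

This note documents the models, numerical choices and limitations behind
`qaerr`: a simulator and detector for multileaf-collimator (MLC) positional
delivery errors in patient-specific IMRT QA with a low-resolution 2D
ion-chamber array (27 × 27 chambers at 10 mm pitch).

## Problem setting

Pre-treatment QA compares a plan's *predicted* dose plane against a
*measured* one. Conventional gamma-pass-rate analysis flags disagreement but
not its cause. `qaerr` instead frames the question as five-way image
classification: given a stack of dose-comparison maps for one beam, decide
whether the delivery was error-free or carried a systematic **shift**,
**opening**, **closing**, or **random** MLC leaf-position error.

## Error model

Errors are injected into every control point of a beam, in isocenter-plane
millimetres (leaf width 10 mm at isocenter, bank A ≤ bank B):

| family   | operation                                    | magnitudes |
|----------|----------------------------------------------|------------|
| shift    | both banks displaced by ±m (same direction)  | 2, 3 mm    |
| opening  | each bank moved m away from the beam axis    | 1, 2 mm    |
| closing  | each bank moved m toward the axis            | 1, 2 mm    |
| random   | i.i.d. N(0, σ²) per leaf, bank, control point| σ = 1, 2 mm|

Shift keeps every aperture width fixed; opening/closing change the X field
size by exactly ±2m. Closing (and random) displacements that would cross a
leaf pair are clamped to the pair's midpoint: this preserves the pair's
centroid and avoids unphysical negative gaps. The shift direction is a
parameter (default +1, toward bank B). Random-family draws are redrawn
independently at every control point; the per-beam seeds are derived with a
CRC32 of the plan/beam identity so a manifest is reproducible across
processes. Each beam yields 9 dataset rows (error-free + 2 magnitudes × 4
families); both magnitudes of a family share one class label.

Jaws, collimator/gantry rotation, MU errors and dynamic-leaf interpolation
between control points are out of scope.

## Synthetic dose engine

Clinical TPS doses and phantom measurements are not reproducible on a desk,
so a transparent fluence-convolution engine stands in for both arms; every
downstream stage is agnostic to dose provenance, so TPS exports can be
substituted.

1. Each control point's aperture is rasterized on a ±135 mm, 1 mm grid with
   exact partial-pixel coverage; fluence is 1 in the opening and equal to
   the leaf transmission (default 0.02) elsewhere. The nonzero floor keeps
   the 10% low-dose gamma threshold meaningful.
2. Control points are accumulated with the meterset fraction delivered
   since the previous point (dose is linear in total meterset).
3. The sum is blurred with a Gaussian penumbra kernel (σ = 3 mm, a
   realistic flattened 6 MV penumbra scale) and box-averaged over each
   10 × 10 mm detector cell — ion chambers average over volume, so box
   averaging, not point sampling.
4. The measured arm multiplies the error-free dose by elementwise
   (1 + N(0, δ²)) noise, δ = 0.01 by default. The real detector's noise is
   not characterized here; δ is a declared knob, not a claim about the
   device.

Synthetic plans are smooth per-leaf gap random walks across control points
with central leaf pairs biased open (Gaussian envelope), gaps clipped to
[0, 200] mm, and monotone meterset weights ending at 1 — an emulation of
modulated step-and-shoot segments. The generator does not reproduce
site-specific aperture statistics, organ-avoidance shapes, tongue-and-groove
or interleaf effects; passing tests demonstrate method correctness and
recoverability under this idealized model, not clinical sensitivity.

## QA maps

For each dataset row the *reference* is the predicted dose (with the row's
error injected) and the *evaluated* distribution is the error-free measured
dose. Three 27 × 27 maps are computed and bilinearly resized
(corner-aligned) to the network input size:

* **Dose difference**: (evaluated − reference) as % of the global reference
  maximum, clipped to ±10% and scaled to [−1, 1]. The ±10% clip mirrors the
  gamma recipe below and is configurable.
* **Signed gamma** under 3%/2 mm and 2%/1 mm (global normalization, 10%
  threshold): per reference point, the Low gamma index minimized over the
  evaluated distribution bilinearly upsampled 10× (1 mm steps) within a
  search radius of 3 × DTA; the magnitude then carries the sign of the
  local dose difference (hot = +, cold = −, exact ties kept +).
  Sub-threshold points are encoded 0 (neutral between hot and cold; a
  separate validity mask is available but not fed to the network). Values
  are clipped at |γ| = 1.5 and scaled to [−1, 1].

Upsampling factor and search radius trade cost against search accuracy;
correctness of the search is pinned by an exhaustive brute-force oracle in
the test suite (agreement to 1e-9 on random grids). Maps are computed at
detector resolution and then interpolated, not the reverse. Note the sign
convention's consequence: because errors live in the *reference* arm, an
opening error makes the expanded-field ring *cold* (measured below the
widened prediction) and closing makes it *hot*.

## Classifier

A hybrid CNN → windowed-attention network:

* **Stem**: 7×7 Convolution–BatchNorm–ReLU (CBR) cluster.
* **RCA stages**: residual bottleneck blocks — 1×1 CBR expansion, strided
  3×3 CBR, squeeze-and-excitation channel gate (global average pool → 2-layer
  bottleneck → sigmoid), 1×1 projection, residual add (1×1 strided
  projection on the identity when shape changes).
* **Attention stages**: linear patch embedding, then pairs of window /
  shifted-window multi-head self-attention blocks (pre-norm, MLP with GELU,
  stochastic depth); shifted blocks roll the token map by half a window and
  mask cross-seam attention; patch merging (2×2 concat + linear) halves
  resolution and doubles width between stages.
* **Head**: layer norm, global average pooling, linear 5-class layer,
  softmax.

The published description fixes the stem (7×7, 32 channels at full
resolution) and the block *types* but not widths, depths, window size or
head counts; those live in `NetConfig` as declared defaults. Two profiles
ship: `full_config` (224×224×3 input; RCA 64/128/256 stride 2 → 28×28;
attention dims 256/512, depths 2+2, 8 heads, window 7, ≈12M parameters) and
`desk_config` (96×96 input; stem stride 2, RCA 16/32, attention dims 32/64,
4 heads, window 6, ≈110k parameters) for CPU-scale runs. Initialization:
Kaiming for convolutions, truncated normal (σ = 0.02) for linear/attention
weights; all draws flow from the config seed.

The network runs on a compact reverse-mode autodiff engine built on NumPy
(`qaerr.nn`): tensors record exact vector–Jacobian products per operation
(im2col/col2im convolution, batched matmul, reductions, roll/reshape for
window partitioning), with batch/layer norm composed from differentiable
primitives. Tensors are float32 by default; the dtype is switchable to
float64, which the test suite uses to verify gradients against central
finite differences to ~1e-3 relative at ε = 1e-5.

## Training and evaluation protocol

* Plan-level 80:20 train/test split (all beams and all 9 variants of a plan
  stay on one side), then plan-disjoint 5-fold cross-validation inside the
  training set; each plan validates exactly once. Because every beam
  contributes one row per class, plan-disjoint folds are automatically
  class-proportional.
* Per fold: cross-entropy loss, AdamW, cosine-annealed learning rate, early
  stopping on validation loss, best-validation checkpoint kept. The
  reference protocol is lr 1e-5, weight decay 1e-4, batch 32, ≤150 epochs,
  patience 50; the desk profile uses lr 1e-3, batch 16, ≤20 epochs,
  patience 5 — a from-scratch 110k-parameter model on a small synthetic
  cohort needs a proportionally larger step and a shorter schedule.
* Online augmentation (all label-preserving, applied identically to all
  channels, outputs clipped to [−1, 1]): horizontal/vertical flips,
  rotation ≤15°, affine (scale 0.9–1.1, translate ≤5%), random erasure of
  one rectangle (5–20% per side), and intensity jitter restricted to one
  global a·x + b contrast/brightness map per sample, which preserves
  pixel-rank order within each channel.
* Test-time inference averages the five folds' probability vectors.
* Metrics are one-vs-rest per class: precision, sensitivity, specificity,
  F1 (zero denominators reported as 0 and logged), overall multiclass
  accuracy reported identically per class, ROC/AUC per class, and a
  row-normalized confusion matrix. Classes absent from the truth are
  flagged undefined rather than zeroed. t-SNE of penultimate features
  supports visual inspection.

## Desk-scale study conditions

The end-to-end recovery experiment uses 20 synthetic plans × 3 beams
(60 beams → 540 map stacks), engine noise 0.01, the desk network profile
and desk schedule, seed-pinned throughout. Under these conditions the
ensemble separates all five classes essentially perfectly — the synthetic
cohort with σ = 2 mm random errors against 1% detector noise is an easier
discrimination problem than clinical data, where random-vs-error-free
confusion dominates because time-integrated measurement lets opposite
per-control-point errors cancel. The recovery test therefore asserts a
conservative floor (macro accuracy ≥ 0.60; F1 ≥ 0.80 for the three
systematic families) and deliberately does not require the random /
error-free confusion pattern.

## Numerical details and edge cases

* All-zero reference dose → normalization error (raised, not silenced).
* Apertures entirely outside the fluence grid render as pure transmission
  with a warning.
* Gamma ties and exact dose equality take the positive sign.
* Bilinear resize is corner-aligned: constants and corners are preserved
  and outputs never leave the input range.
* DICOM RT PLAN rewrite touches only `LeafJawPositions` (serialized to
  0.01 mm); all other elements are preserved. Control points without an MLC
  position sequence inherit the previous positions.
* Checkpoints embed the full `NetConfig` so a model file is self-describing.

## Known limitations

* The dose engine is a fluence model: no scatter kernels, heterogeneity,
  output factors or absolute calibration; leaf ends and tongue-and-groove
  are ignored.
* Single-channel ablations are supported as an experiment harness, but at
  desk scale all channel choices saturate, so the multi-channel advantage
  reported on clinical data is not observable here.
* ResNet-18 / pure Swin-Transformer baselines are not reimplemented.
* Clinical dose impact on target/organ-at-risk structures is out of scope.
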