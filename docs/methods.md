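# Methods

## Scope and design

This package implements a 2-D multi-class tumor-segmentation stack: the
G-Net encoder–decoder, its four characteristic blocks (squeeze-excitation,
sigmoid self-attention, spatial pyramid pooling, fusion), the evaluation
metrics and the Tversky/boundary losses, a BraTS-like synthetic phantom
generator, PNG/NIfTI I/O, and a training loop with the reference
optimization protocol (Adam, learning rate 0.001, categorical cross-entropy,
early stopping on validation loss with patience 5 and best-weight
restoration).

The numerical core is a small reverse-mode automatic-differentiation engine
over numpy arrays (`gnet.nn`): NHWC float32 tensors, im2col-free shifted-
matmul convolutions, ceil-mode max pooling, nearest-neighbor upsampling, and
Adam. Writing the engine in-house keeps every operation small enough to be
cross-checked against naive loop oracles in the test suite, which is the
package's primary correctness argument. The user-facing surface is a
scikit-learn-style estimator (`GNetSegmenter`) so the model composes with
sklearn's `clone`/`get_params` machinery; the blocks, model, losses and I/O
remain importable as ordinary modules, and a click CLI wraps the estimator
for shell use.

## Architecture decisions

Several wiring choices are under-determined by the block definitions alone;
the ones made here are:

* **Mirrored decoder.** One upsample(×2) + fusion stage per encoder
  pooling step, fusing with the *post-SE* feature map of the matching
  resolution (SE is applied immediately after each conv block, so those are
  the features available at each scale). The fusion convolution width equals
  that stage's encoder width.
* **Self-attention once, at the bottleneck**, after SPP — the gate is meant
  to capture long-range context, which lives at the coarsest resolution.
* **Two pooling steps for the default three-stage encoder** (none after the
  last stage), keeping the bottleneck at 1/4 resolution so SPP windows up
  to 8 px remain valid on 128-px inputs.
* **Nearest-neighbor upsampling** rather than transposed convolution,
  avoiding deconvolution checkerboard overlap; the upsample index map
  `out[i,j] = in[i//p, j//p]` is the exact inverse of the pooling grid.
* **SE bottleneck width** `max(C // r, 1)` with reduction `r = 16` by
  default (standard SE practice), biases included and initialized to zero;
  both configurable.
* **SPP** defaults to pool sizes (2, 4, 8) — three octaves — with 256
  filters per level and the original input included in the concatenation.
  When a pool size does not divide the spatial extent, pooling is ceil-mode
  (−inf padding) and the level is resized back to exactly the input
  resolution.
* **Convolutions** are stride-1 with "same" zero padding; 3×3 in conv and
  fusion blocks, 1×1 for attention/reduction/head. He-normal initialization
  (ReLU networks), seeded, so two builds from the same seed are bitwise
  identical.
* **Input size** defaults to 128×128 single-channel and must be divisible
  by `2^(stages−1)`; the constraint is validated with the required factor
  named in the error.

## Losses and metrics

* Reported metrics (accuracy, precision, sensitivity, specificity, Dice)
  are computed from *hard* argmax masks via per-class confusion counts —
  the set-cardinality definitions. Argmax ties resolve to the lowest class
  index, and the test oracles mirror that rule.
* Losses are computed from *soft* probabilities so they stay
  differentiable. Tversky uses flattened soft counts over all pixels and
  channels (a per-class-averaged variant is available via `per_class=True`);
  defaults α = 0.7, β = 0.3, smooth = 1.0 — the canonical FN-weighted
  setting for imbalanced segmentation. At α = β = 0.5 and vanishing smooth
  it equals 1 − soft Dice (tested).
* The boundary loss compares Sobel gradient magnitudes of the true and
  predicted per-class maps. Borders are handled by **edge replication**, so
  a constant image has an exactly zero edge map and the response is
  invariant to constant offsets; the differentiable version reproduces this
  with a replicate-pad / convolve / crop sequence and an ε = 1e-8 inside
  the square root to keep the gradient finite on flat regions.
* Empty-denominator convention: when the relevant ground-truth set is
  empty, a metric is 1.0 if the prediction agrees it is empty and 0.0
  otherwise; occurrences are logged at DEBUG level.
* The optimized objective is categorical cross-entropy by default, with
  Tversky and boundary losses tracked per epoch as monitored metrics. A
  composite mode `CE + λ₁·Tversky + λ₂·boundary` is available
  (`loss_mode="composite"`), since segmentation pipelines differ on whether
  these auxiliary losses are optimized or only monitored.

## Early stopping

"Improvement" is a strict decrease of the monitored validation loss by more
than `min_delta` (default 0); ties count toward patience. Training stops
when `patience` (default 5) consecutive epochs fail to improve, and the
best epoch's weights are restored (also when the epoch budget runs out
without triggering the stop). The semantics are property-tested against a
brute-force oracle on arbitrary loss series. Maximum epochs defaults to 50
and early stopping can be disabled to reproduce a fixed-length run.

## Synthetic phantoms

`PhantomSpec` generates single-channel slices with 4-class masks. With
probability `tumor_probability` (default 0.8 — tumor-rich, as slice
datasets curated for segmentation typically are) the mask contains a nested
lesion: three concentric boundaries (whole tumor / core / necrosis) drawn
as one rotated, anisotropic ellipse deformed by a shared radial Fourier
perturbation (harmonics 3–5, amplitude ≤ 0.12/√h, bounded below at 0.5), so
nesting holds by construction — the enhancing rim is the core annulus
outside the necrosis boundary. Radii are sampled hierarchically as
fractions (whole: 0.18–0.32 of the image; core: 0.40–0.65 of whole;
necrosis: 0.35–0.60 of core), which guarantees strict nesting for any valid
spec.

Intensities emulate a FLAIR-like contrast — background 0.35, necrosis 0.15,
edema 0.70, enhancing 0.80 — each drawn per pixel from a Gaussian with
σ = 0.02, multiplied by a smooth quadratic bias field (amplitude 0.08,
mimicking coil inhomogeneity), plus additive Gaussian noise (σ = 0.02), and
clipped to [0, 1]. A 4-channel mode provides FLAIR/T1/T1ce/T2-like
contrasts of the same anatomy. Generation is keyed on `(seed, index)`, so
any phantom is reproducible in isolation.

What the phantoms do **not** model: brain anatomy (no skull, ventricles or
tissue texture), 3-D continuity between slices, modality physics,
infiltrative or multifocal lesion geometry, and class-intensity overlap as
severe as real MRI. Tests passing on phantoms therefore demonstrate that
the architecture, losses, optimization and I/O are implemented correctly
and that the network can learn a nested-intensity segmentation task — not
that it reaches any particular accuracy on real BraTS data.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately small problem sizes chosen as
the smallest that still exercise every code path: 32–64 px inputs, encoder
widths (4, 8, 16) or (8, 16, 32), 8–96 phantoms, ≤ 300 optimization steps.
Oracle comparisons use 1e-5–1e-6 absolute tolerances (float32 arithmetic
against float64 oracles); softmax conservation is checked at 1e-5; counting
metrics are exact. Max-pool gradient routes to the first maximum on ties.
Min–max normalization maps constant slices to zero. The wiring-coverage
test uses `se_reduction=1` so a silent parameter can only indicate a wiring
defect, not a stochastically dead unit in a one-unit ReLU bottleneck.

## Known limitations

* 2-D slices only; no volumetric (3-D) blocks.
* Single-threaded numpy training: practical for the phantom-scale problems
  here, not for full-resolution BraTS training.
* No pretrained weights, Hausdorff distance, calibration or uncertainty
  outputs.
* The NIfTI reader respects the stored affine but always slices along the
  last axis; reoriented volumes should be canonicalized upstream.
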