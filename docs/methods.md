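# Methods

## Problem and model

`leafsam` segments disease lesions on plant leaves and classifies the
disease jointly, following the adapter-tuning paradigm: a Segment Anything
(SAM)-style ViT image encoder is kept frozen and adapted with small
trainable modules, so that only a few percent of the parameters train.

The architecture has four pieces:

1. **Multi-Scale Adaptive Adapter (MAA)** — a bottleneck adapter
   (`Down → ReLU → MSPM → Up`) inserted twice per ViT block.  The middle
   stage, the Multi-Scale Pyramid Feature Module (MSPM), reshapes the
   bottleneck tokens to a C×H×W grid, splits the channels into four groups,
   adaptively average-pools each group to a pyramid scale (default
   {1, 2, 3, 6}), multiplies by a content-dependent sigmoid gate
   W_D,j ∈ (0,1) produced by a per-branch 1×1 convolution, refines with a
   1×1 convolution plus 3×3 depthwise-separable convolution (GELU), and
   restores resolution with bilinear interpolation.  A trunk path applies a
   3×3 depthwise-separable convolution to the ungrouped input; branches and
   trunk are concatenated (2C channels) and fused by a 1×1 convolution back
   to C.  The up-projection is initialised to zero, the standard safeguard
   that makes the adapter a no-op at step 0.
2. **Local Feature Extraction Module (LFEM)** — a trainable convolutional
   pyramid: 3×3 conv (BN+ReLU) + max-pool; a parallel standard + dilated
   (rate 2) 3×3 conv pair summed, max-pooled, and compressed by a 1×1
   convolution to give `F_L` at 1/4 input resolution; further
   max-pool/conv stages reach the token grid, the last stage using 3×3
   convolutions with LayerNorm+GELU at `embed_dim` channels (`F_LN`).
3. **Feature Fusion Module (FFM)** — inside every ViT block, Cross-Branch
   Attention takes queries from the (layer-normalised) global tokens and
   keys/values from `F_L`, then a Squeeze-and-Excitation gate
   `S = σ(W₂ δ(W₁ z) · α_epoch)` rescales channels, with
   `α_epoch = 1 − exp(−β·epoch)` ramping the local branch's influence from
   0 toward 1 over training (β = 0.2 by default).
4. **Mask–class hybrid decoder** — SAM's two-way-transformer mask decoder
   (learned IoU and mask output tokens, 4× transposed-convolution
   upsampling, hypernetwork dot-product mask head, sigmoid quality head)
   plus a lightweight classification head: global average pooling of the
   image embedding followed by two fully connected layers.

The encoder output is `neck(F_G,N + F_LN)` where the neck is the SAM pair
of convolutions with channel layer-normalisation.

Training minimises

    L_mask  = α·L_Dice + β·L_BCE          (α = β = 0.5)
    L_joint = 0.6·L_mask + 0.2·L_IoU + 0.2·L_cls

with soft (probability-valued) Dice and IoU losses (ε = 1e-6 smoothing),
pixel-mean BCE (probabilities clipped to [1e-7, 1−1e-7]), and label
cross-entropy.  Severity is graded by the percentage of infection
POI = lesion pixels / leaf pixels, banded light (0, 0.2], moderate
(0.2, 0.5], severe (0.5, 1] with band boundaries belonging to the lower
band.  The published formula multiplies by 100; we treat POI as a fraction
in (0, 1] and regard the ×100 as presentational, since the band thresholds
are themselves ≤ 1.

## Design choices where the design was open

- **Block composition.**  The block is implemented as
  `F' = A + MAA₁(A) + F_prev` with `A = Attention(FFM(LN(F_prev)))`, and
  `out = MLP(LN(F')) + MAA₂(LN(F')) + F'`.  The adapters contribute
  *additively alongside* the frozen sublayers (their forward returns only
  the bottleneck delta).  This is the only composition consistent with
  zero-initialised up-projections preserving the pre-trained function,
  which the package treats as a hard invariant.
- **FFM residual.**  The gated attention output is added residually to the
  global tokens (`F_G + S·CBA`); the literal non-residual form is available
  via `ffm_residual=False`.  Without the residual, the α = 0 gate at epoch
  0 would halve the signal entering attention and zero-start equivalence
  would be unattainable.
- **Pyramid scales.**  The four pooling branches use adaptive average
  pooling to {1, 2, 3, 6} — the classic pyramid-pooling ladder — applied to
  four channel groups of width C/4.  A pure global pool cannot produce a
  W×H map, so the adaptive reading is forced.  Configurable.
- **Adapter reduction** r = 4 (standard bottleneck ratio); **SE reduction**
  16; **CBA heads** inherit the host ViT's head count; CBA has no output
  projection (only W_q, W_k, W_v are defined).
- **FFM keys.**  The LFEM's 1/4-resolution map is projected to `embed_dim`
  by a 1×1 convolution and adaptively average-pooled to a key grid of twice
  the token grid per side, bounding the cross-attention cost at every
  preset.
- **LFEM trunk depth** adapts to the patch size (log2(patch) pooling
  stages), so `F_LN` always lands exactly on the token grid; channel
  schedule 3→32→64→128→embed_dim at paper scale, 3→16→32→embed_dim at tiny
  scale.
- **Decoder prompts.**  Training and evaluation run unprompted: an empty
  sparse prompt set and a learned "no-mask" dense embedding, because batch
  evaluation must be automatic.  A single mask output is produced (one
  binary lesion mask per image); the IoU quality token is kept but not
  supervised (the joint loss has no quality-regression term).
- **Optimiser.**  AdamW (β = 0.9/0.999), weight decay 0.01 on matrices and
  convolution kernels only; learning rate `lr(t) = lr0·exp(−k·t)` with
  lr0 = 5e-4 and, since only the functional form is prescribed, default
  `k = ln(10)/total_steps` — one decade of decay over the run.
  α_epoch uses the 0-based epoch index and is constant within an epoch.
- **Thresholds.**  Masks are binarised at 0.5 on sigmoid probabilities for
  evaluation; losses always use soft probabilities.  Empty–empty mask
  pairs score Dice = IoU = 1 in metrics and 0 in losses (perfect agreement
  on absence).  Dice/IoU losses are computed per image and averaged over
  the batch, matching the per-image evaluation convention.
- **Evaluation aggregation** is image-averaged (then stratified by the
  severity band of the ground-truth POI), matching the per-severity
  reporting structure of the study.

## Numerical backend

No autodiff framework is available in the supported environment, so the
package ships a small reverse-mode automatic-differentiation engine over
numpy (`leafsam.tensor`): broadcast arithmetic, batched matmul, stride-1
grouped/dilated convolution (im2col), non-overlapping patch and transposed
convolutions, 2×2 max pooling, adaptive average pooling, exact bilinear
interpolation (separable row/column weight matrices), fused normalisation,
softmax/log-softmax and exact erf-based GELU.  Everything is float64:
slower than float32 but bit-stable and accurate enough that closed-form
identities hold to 1e-9–1e-12 in tests.  Every primitive's gradient is
verified against central finite differences in the test suite.  Model
construction draws from one process-wide seeded generator, numpy
single-threaded kernels are deterministic, and checkpoints (`.npz` with a
JSON metadata block recording config, seed and per-parameter frozen flags)
hash identically across same-seed runs on one machine.

A converted SAM ViT-b checkpoint (`.npz`, reference key names) can be
loaded into the frozen backbone via `leafsam.load_sam_backbone`; everything
runs and is tested with randomly initialised frozen weights, so no
download is required.

## Synthetic data: what it emulates and what it does not

The study dataset (26 classes × 200 plain-background leaf images with
lesion masks) is not publicly released, so `leafsam.data` generates a
controlled stand-in: superellipse leaf silhouettes with sinusoidal edge
perturbation on a flat noisy background; lesions as unions of Gaussian
blobs in three spatial patterns (fragmented ≈ 8–15 small blobs,
concentrated = one large blob, mixed = one large + several small); POI
driven into the requested severity band by a monotone bisection on a
global blob-scale factor (the generator raises a `GenerationError` naming
the constraint when a band is unreachable).  Each class has a fixed lesion
hue (evenly spaced on the hue circle) and speckle frequency from a seeded
table, with small per-sample jitter, so classes are statistically
separable and the classification head has signal to learn.

The generator reproduces the *structural* properties the pipeline needs —
controlled POI, the three lesion patterns, class-separable appearance,
binary masks with lesion ⊆ leaf — but not photographic realism: no
lighting variation, occlusion, venation, specular highlights or complex
backgrounds.  Passing tests therefore demonstrate that the architecture,
losses, schedules and bookkeeping behave as specified and that the model
can fit controlled data; they do not certify field performance on real
leaf photographs.

## Problem sizes used by the tests and acceptance script

The `tiny` preset (64 px images, patch 8, embed 64, depth 4, heads 2,
window 4, neck 32) is the CPU-scale twin of the paper preset used for all
behavioural checks.  The learnability check trains on 8 synthetic images
(2 classes) for 200 full-batch optimiser steps; the stratified-evaluation
check generates 4 classes × 50 images at 256 px; the reproducibility check
runs two 8-step trainings.  The `paper` preset (ViT-b dims) is constructed
and run forward once to pin its output shapes.

## Known limitations

- CPU-only and float64: paper-scale training is out of reach; the package
  demonstrates the method, not the published scores, which would require
  the unreleased dataset, the SAM checkpoint and GPU training.
- Windowed attention follows the SAM pad/window/unpad convention without
  relative position embeddings.
- The IoU quality estimate is produced but uncalibrated (unsupervised).
- The learnable-parameter count of the original description is internally
  inconsistent (133.9M vs 233.9M); no attempt is made to match either.
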