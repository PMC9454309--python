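# Methods

## Problem and model

Cone-beam CT (CBCT) acquired on the treatment machine is geometrically
faithful but radiometrically poor: scatter cupping, photon-starvation
streaks, beam-hardening bands, noise and a global HU offset make it
unsuitable for dose calculation or contour propagation in adaptive
radiotherapy. The package learns a slice-wise mapping from CBCT to a
synthetic CT (sCT) with planning-CT-like Hounsfield fidelity.

The translator is a U-shaped hierarchical encoder–decoder built from
shifted-window multi-head self-attention blocks:

- **Input/output projections.** A 3×3 convolution with LeakyReLU (slope
  0.01) lifts the single-channel slice to `C0` feature channels; a 3×3
  convolution projects back to one channel.
- **Stages.** Four encoder stages of two transformer blocks, each followed
  by a 4×4 stride-2 convolution that halves resolution and doubles
  channels; a two-block bottleneck at 16·`C0`; four decoder stages of a
  2×2 stride-2 transposed convolution, a concatenation skip from the
  matching encoder stage fused by a 1×1 channel-reducing convolution, and
  two more blocks.
- **Blocks.** Pre-norm residual form: `x + W-MSA(LN(x))` then
  `x + LeFF(LN(x))`. The first block of a stage uses plain window
  partitioning; the second shifts the partition by ⌊M/2⌋ via cyclic roll
  plus an additive mask so that content wrapped across the image border
  never attends across the seam.
- **Attention.** Within each M×M window,
  `Attention(Q,K,V) = softmax(QKᵀ/√d + B [+ mask]) V`, with per-head
  dimension `d = C/k` and a learned relative position bias `B` taken from
  a `(2M−1)² × k` table indexed by the 2D offset between tokens (shared
  across windows). The `1/√d` scaling is the standard choice for this
  attention family; a `1/d` variant is available via
  `AttentionConfig.scale_by_sqrt_d=False` since either is only a
  re-scaling of learnable logits.
- **LeFF.** Tokens are linearly expanded (ratio `leff_expansion`),
  re-gridded, passed through a 3×3 depth-wise convolution, flattened and
  linearly shrunk, with GELU after every linear/convolutional layer.

Inputs whose sides are not multiples of `window_size · 2⁴` are
reflect-padded and the output cropped back; training images are sized so
padding never enters the loss. There is no global input→output residual by
default (`global_residual` enables one).

Defaults where the architecture leaves room: window `M = 8` (tests and the
desk-scale study use `M = 4`), base channels `C0 = 32` (study: 8), channel
multipliers (1, 2, 4, 8) with 16 at the bottleneck, heads
(1, 2, 4, 8, 16), LeFF expansion 4 (study: 2), LayerNorm over channels per
token.

## Objective

`0.9 · Charbonnier + 0.1 · (1 − MS-SSIM)`, where

- Charbonnier = mean over pixels of `√((ŷ−y)² + ε²)`, ε = 10⁻³. The
  per-pixel mean (rather than a per-image norm, which remains available
  via `charbonnier_form="norm"`) makes the ε floor scale-free and the
  ε→0 limit equal to MAE.
- MS-SSIM multiplies the mean contrast and structure comparisons over a
  dyadic pyramid (2× average-pool between scales) and the mean luminance
  comparison at the coarsest scale, each raised to the per-scale exponent.
  Constants C1 = C2 = C3 = 1 (as specified for this objective — large for
  [−1, 1]-normalized images, but honored and configurable); local
  statistics over an 11×11 Gaussian window (σ = 1.5); 3 scales for 128-px
  slices with the standard five-scale exponent vector
  (0.0448, 0.2856, 0.3001, 0.2363, 0.1333) truncated and renormalized.
  The similarity enters the objective as `1 − MS-SSIM` so that the mixed
  loss is minimized, and component means are clamped to ≥10⁻⁶ before
  exponentiation so fractional powers stay defined on adversarial inputs.

Loss arithmetic runs in float64 even when network activations are float32,
so the closed-form identities (loss floor `0.9ε`, MS-SSIM of identical
images = 1, constant-image luminance = 0.5) hold to ~1e−12.

## Optimization

Adam (β = (0.9, 0.999), ε = 1e−8) wrapped in Lookahead with the original
defaults k = 5, α = 0.5, learning rate 0.001. The fast weights take an
Adam step every iteration; every k-th step the slow weights move a
fraction α toward them and the fast weights restart from the slow ones.
Checkpoints store the slow weights. Batch size 4 (study: 2); no data
augmentation. All randomness — initialization, data order, phantom
geometry, artifacts — flows from explicit integer seeds, and every stage
is byte-reproducible.

The network and its gradients are implemented on a compact NumPy
reverse-mode autodiff engine written for this package (`cbct2ct.autodiff`);
convolutions run as im2col/GEMM, the depth-wise 3×3 as nine shifted
multiply-adds. Training runs comfortably on one CPU core at the study
sizes below.

## Preprocessing and inference

HU values are clipped to (−1000, 1000) and mapped affinely to [−1, 1];
pixels outside the body are forced to 0 HU before mapping, mirroring the
zero-background pairing convention, and the synthetic CT is re-zeroed
outside the body after inverse mapping. The clip range covers pelvis soft
tissue; dense cortical bone above 1000 HU saturates, which is acceptable
for the phantom and configurable for other anatomy. When no body mask is
supplied one is estimated as the largest connected component above
−300 HU with holes filled.

## Digital pelvis phantom

Real paired data cannot be redistributed, so a seeded analytic phantom
provides the study conditions: an elliptical body (background exactly 0),
two circular femoral heads (700 HU), an elliptical bladder (10 HU), a
rectum disk with gas pocket (−800 HU) in soft tissue (40 HU), plus a
smooth Gaussian-filtered texture (≈8 HU). The CBCT degradation adds,
inside the body only: a cupping *depression* `−c·(1−(r/R)²)` (scatter
lowers central HU; amplitude 40), straight streaks through random
bone-interior points with Gaussian cross-profile σ = 1.5 px (6 streaks,
±60 HU), a dark band on the chord between the femoral heads (50 HU,
σ = 3 px), Gaussian noise (σ = 15 HU) and a +25 HU global shift. With
these defaults raw-CBCT MAE over the body is in the tens of HU. Dose
grids for gamma analysis are analytic 3D Gaussian bells peaking at the
prescription, with the evaluated grid a uniform scaling of the reference.

What the phantom does *not* emulate: projection-domain physics, real
scatter spectra, 3D cone-beam reconstruction artifacts, deformable anatomy
mismatch between the paired images, or DICOM metadata. Passing tests
therefore demonstrate the correctness of the algorithms and the
learnability of this artifact family, not clinical performance.

## Evaluation stack

- **HU accuracy** over the body mask: MAE, RMSE, and
  PSNR = 10·log₁₀(Max_p²/MSE) with Max_p defaulting to the width of the
  normalization range (2000); a perfect match reports +∞.
- **Contour agreement**: Dice coefficient (both-empty defined as 1) and
  mean distance to agreement as the symmetric mean surface distance in mm
  (boundaries = mask minus its erosion; spacing-aware distance
  transforms). Report aggregation uses sample sd (n−1); `roi_stats` uses
  population sd — both documented at the call sites.
- **Global 3D gamma**: for every reference voxel at ≥10% of prescription,
  γ = min over a sub-voxel candidate grid of
  `√((Δd/D_c)² + (r/dta)²)`, with the dose difference normalized to the
  prescription-scaled criterion (global normalization), trilinear
  interpolation of the evaluated dose, search radius 3·dta, and candidate
  spacing 0.1 of the smallest voxel dimension. Keeping the candidate step
  independent of dta makes candidate sets nested as criteria loosen, so
  pass rates respond monotonically to both criteria. γ = 1 counts as a
  pass (with a 1e−9 guard against rounding at the boundary). The
  vectorized search visits candidates in order of increasing distance and
  stops when the distance term alone exceeds every running minimum; it is
  exactly equal to exhaustive search, as tested against a per-voxel
  loop implementation.

## Desk-scale study conditions

The end-to-end study (`cbct2ct.study`, also run by
`scripts/acceptance.py`) uses 200 phantom pairs at 128 px (160/20/20
train/val/test), the `C0=8, M=4` network, and 2,000 Lookahead/Adam steps
at batch 2 on random 64-px crops — patch-based training standard for
image restoration, with full-slice inference. These sizes were chosen as
the smallest cohort on which the CBCT→CT improvement is unambiguous on a
single CPU core. The expected direction of results: synthetic CT beats
raw CBCT in MAE and PSNR on the held-out split; magnitudes depend on the
phantom's artifact amplitudes, not on clinical data.

## Known limitations

- 2D slice model; no volumetric attention or inter-slice consistency.
- The phantom's artifacts are low-dimensional and partially deterministic
  given the anatomy, so learned correction is easier than on clinical
  CBCT; results quantify correctness, not clinical accuracy.
- Gamma analysis assumes the two dose grids share a grid; resampling
  between mismatched grids is out of scope.
- Charbonnier/MS-SSIM mixing assumes both terms on comparable scales;
  with very different HU ranges the 9:1 mix may need retuning.
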