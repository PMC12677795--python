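# Methods

## PCA fusion

Images of one modality are vectorised into the columns of X ∈ ℝ^(D×N),
D = W·H. Each pixel row is standardised to mean 0 and unit variance;
rows with zero variance (constant background, ubiquitous in brain slices)
are mean-centred only, with their standard deviation recorded as 1 so
de-standardisation is exact. The covariance is the population form
S = (1/N) X̃X̃ᵀ. Because D ≫ N in practice, the eigenpairs are computed
from a thin SVD of X̃ (singular values s give eigenvalues s²/N), which is
mathematically identical to the dense eigendecomposition of S but never
materialises the D×D matrix; the equivalence is verified in the test suite
against a brute-force dense oracle on small stacks. Eigenvector signs are
fixed deterministically (first nonzero component positive) so results are
reproducible across runs and LAPACK builds.

Reconstruction projects onto the leading K eigenvectors, X̂ = BBᵀX̃, then
restores each row's scale and mean. K defaults to min(D, N) — the complete
basis, which reconstructs losslessly — because the fusion stage is used
here for restoration rather than compression; smaller K is a caller option.
The stack that PCA is fitted on is caller-controlled: a pair can be fused
alone or together with additional co-registered pairs supplying context
columns.

Three pixel-wise combination rules are exposed:

- `paper_reconstruct` (default): mean of the two per-modality PCA
  reconstructions. With a single pair and full K this degenerates to plain
  averaging; it becomes distinct when K < N or context images are supplied.
- `eigen_weighted`: the classic two-image PCA fusion — weights are the
  dominant eigenvector of the 2×2 covariance between the two images,
  normalised to sum to 1. In the degenerate perfectly anti-correlated case
  (weight sum 0) the rule falls back to equal weights.
- `average`: (MRI + PET)/2, the baseline.

Outputs are clamped to [0, 1].

## Network architecture

The segmenter is a five-level encoder-decoder. Each half-block is
conv3×3 → ReLU → conv3×3 → BatchNorm → ReLU (all convolutions biased,
'same' padding); downsampling is 2×2 max pooling with stride 2, and the
middle block holds 2048 filters at 1/64 of the input resolution (8×8 for
256×256 inputs). Encoder widths double from 64 to 1024. The decoder
upsamples with 2×2 stride-2 transposed convolutions and concatenates the
matching encoder activation (taken after the block's final ReLU, before the
next pooling); its channel plan is deliberately asymmetric — per block
(transpose out, conv1 out, conv2 out) = (1024, 1024, 1024), (512, 512, 256),
(256, 256, 128), (128, 128, 64), (64, 64, 64) — i.e. the second convolution
of blocks 2–4 halves the width. A 1×1 convolution with sigmoid produces the
probability map. Total trainable parameters at full width: 122,480,513;
adding the 2 running statistics per batch-norm channel (5,568 channels)
gives 122,491,649 stored values.

Batch norm accounts for 4 values per channel (scale, shift, running mean,
running variance), 2 of them trainable. Parameter counting is done twice —
analytically over the declarative layer plan, and by introspecting the
instantiated arrays — and the two paths must agree.

A `width_multiplier` scales every filter count; all scaled counts must stay
positive integers (validated with exact rational arithmetic), which admits
1/2, 1/4, 1/8, 1/16, 1/64 and similar. Input height/width must be divisible
by 64 (five poolings plus the middle pooling).

## The numpy layer engine

The network runs on a purpose-built numpy engine (`fuseg.nn`): convolution
as nine shifted GEMMs (efficient at small channel counts and trivially
correct to backpropagate through), non-overlapping 2×2 transposed
convolution via tensor reshapes, max pooling with argmax routing (ties to
the first index), and batch normalisation with population variance,
momentum-0.1 running statistics and ε = 1e-5. Binary cross-entropy is
computed on logits in the numerically stable softplus form; a soft Dice
loss (smoothing constant 1) and their sum are alternatives. Optimisation is
Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Training arrays are float32;
gradient-check tests run the same code in float64 and compare every layer,
and the whole assembled network, against central differences. Because ReLU
and max pooling are piecewise linear, finite differences are only trusted
at step sizes small enough that no routing decision flips inside the
interval; the end-to-end check uses directional derivatives at ε = 1e-8 and
an absolute floor for parameters whose true gradient is exactly zero (conv
biases feeding a batch norm).

## Preprocessing

Raw images carry an explicit bit depth (8, 12 or 16). Normalisation has two
modes: `paper_literal` divides by 2^depth (256 for 8-bit), `max_value` by
2^depth − 1 so the brightest representable intensity maps exactly to 1;
`paper_literal` is the default. Resizing is bilinear for images and
nearest-neighbour for masks (preserving binarity), clamped to the bit-depth
range. Augmentation draws one transform per new sample, uniformly from six
families — rotation ±15°, horizontal/vertical flip, zoom 0.9–1.1,
brightness scale 0.9–1.1, shift ±10 px — and applies it identically to MRI,
PET and mask (mask re-binarised at 0.5 after interpolation); every
augmented pair records its transform so co-registration can be re-verified
by replay. The train/test split is a seeded shuffle (the reference protocol
is 110 pairs split 88/22).

## Training protocol

Defaults: 100 epochs, 5-fold cross-validation, batch size 8, Adam at
lr 1e-3, BCE loss, threshold 0.5 for binarisation. The loss, optimiser
settings and batch size are free choices documented as such (the protocol
they accompany fixes only epochs and folds). Fold assignment uses seeded
shuffled K-fold; all folds are disjoint and cover the dataset. Determinism:
dataset generation, fold splits, weight initialisation and shuffle order
all derive from explicit seeds, so repeated runs agree bit-for-bit in data
and to float roundoff in losses.

## Synthetic phantoms

Each phantom is one axial slice at a configurable size (default 64,
network-compatible). The MRI-like channel has an elliptical brain (semi-axes
≈ 0.40·size with ±5 % jitter), a bright skull rim, low-amplitude smooth
texture, a hypointense tumour interior and a sharp hyperintense rim one
pixel wide — sharp edges being the defining MRI-like feature. The PET-like
channel is a smooth background plus a Gaussian uptake blob centred on the
tumour (σ = 0.8 × the larger semi-axis), smoothed with σ = 2 px — smooth,
high-intensity uptake being the defining PET-like feature. Tumours are
random ellipses with semi-axes 4–10 px placed fully inside the brain; the
mask is the exact ellipse interior, so co-registration is exact by
construction and the PET maximum falls inside the mask. Per-modality
Gaussian noise (σ 0.02 MRI, 0.01 PET) is added and intensities clipped to
[0, 1]. Generation is deterministic in (seed, index).

What the phantoms do not emulate: real tissue-class intensity
distributions, partial-volume effects, registration error between
modalities, scanner artefacts, and multi-focal or infiltrative tumour
geometry. Passing the phantom benchmark therefore demonstrates that the
pipeline is implemented correctly and can learn the fused-image → mask
mapping, not that the reported clinical-scale accuracy transfers to
patient data.

## Desk-scale benchmark

The standing benchmark trains the width-1/8 network on 48 of 64 seeded
64×64 phantoms for 25 epochs and evaluates Dice/IoU/accuracy on the 16
held-out phantoms, requiring mean Dice ≥ 0.80; it runs in about a minute
on one CPU core. These problem sizes were chosen so the whole pipeline —
generation, fusion, training, evaluation — stays a desk-scale experiment
while leaving a wide margin above an all-background predictor (Dice 0).
The published clinical-scale figures were obtained on BraTS data with GPU
training and are not reproduced here; the architecture itself, however, is
reproduced exactly and verified parameter-for-parameter.

## Numerical conventions and edge cases

- PSNR of identical images returns `inf` (zero MSE sentinel).
- SSIM uses stabilisers Z₁ = (0.01 L)², Z₂ = (0.03 L)², a 7×7 uniform
  window, population local moments, and averages only windows fully inside
  the image; it is cross-checked against scikit-image's implementation.
  The standard symmetric form of the index is implemented.
- Dice and IoU of two empty masks return 1.0 with an explicit warning
  (vacuous agreement), avoiding NaNs when averaging folds that contain
  tumour-free slices.
- Binarisation uses ≥ threshold → 1, threshold strictly inside (0, 1).
- Zero-variance rows in PCA standardisation use std 1 (centring only).
- Equal eigenvalues are ordered stably by the SVD and disambiguated by the
  sign convention; reconstructions are invariant to the choice.

## Known limitations

- The engine is CPU-only and single-threaded apart from BLAS; full-width
  training at 256×256 is possible in memory but not practical in time —
  the width multiplier exists for exactly this reason.
- Max-pool gradient routing sends ties to the first index rather than
  splitting, a standard but arbitrary convention.
- `paper_reconstruct` fusion of a lone pair at full K reduces to averaging
  by construction; meaningful PCA behaviour requires K < N or context
  images.
- The phantom generator produces single-connected elliptical tumours only
  (configurable count, but each component is an ellipse).
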