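# fuseg

Two-stage brain-tumour segmentation on co-registered MRI/PET slice pairs:

1. **PCA image fusion.** Each modality's images are vectorised into the
   columns of a matrix X ∈ ℝ^(D×N) (D = W·H pixels), every pixel row is
   standardised, the population covariance S = (1/N) X̃X̃ᵀ is
   eigendecomposed S = UΣUᵀ, and the images are projected onto the leading
   K eigenvectors B = [u₁ … u_K] and reconstructed as X̂ = BBᵀX̃ before
   de-standardisation. The reconstructed MRI and PET are combined pixel-wise
   into a single fused image that carries both anatomical edges (MRI) and
   metabolic uptake (PET). An eigenvector-weighted mode and a plain
   averaging baseline are also provided.
2. **Permutate U-Net segmentation.** A five-level encoder-decoder network
   (filters 64 → 1024 doubling per level, 2048-filter middle block, 2×2
   stride-2 transposed-convolution upsampling with skip concatenation, and a
   1×1 sigmoid head) segments the tumour from the fused image. At full width
   the network has 122,480,513 trainable parameters; a width multiplier
   scales every filter count so the same architecture trains on a laptop CPU.

Segmentation is scored with the Dice coefficient DC = 2|A∩B|/(|A|+|B|),
the Jaccard index IoU = |A∩B|/|A∪B| and pixel accuracy; fusion quality
with PSNR = 10·log₁₀(peak²/MSE) and the windowed SSIM index.

The network and its training loop run on a small, numerically verified
numpy engine (`fuseg.nn`) — no deep-learning framework is required. A
synthetic phantom generator produces co-registered MRI-like / PET-like
pairs with exact ground-truth tumour masks, so the entire pipeline is
testable without any patient data.

The package is aimed at researchers in multimodal medical image analysis
who want a transparent, fully inspectable reference implementation of
PCA fusion plus encoder-decoder segmentation at desk scale.

## Worked example

```python
from fuseg import (PhantomConfig, make_dataset, fuse_pair, score_fusion,
                   split_dataset, TrainConfig, train_model, evaluate_model)

pairs = make_dataset(PhantomConfig(size=64, seed=7), 64)

fused = fuse_pair(pairs[0], mode="eigen_weighted")
print(fused.weights)              # (0.734, 0.266) — MRI dominates this pair
print(score_fusion(fused, pairs[0]))
# {'psnr_mri': 22.13, 'ssim_mri': 0.930, 'psnr_pet': 13.33, 'ssim_pet': 0.316}

split = split_dataset([p.id for p in pairs], train_n=48, seed=7)
by_id = {p.id: p for p in pairs}
cfg = TrainConfig(epochs=25, width_multiplier=1/8, image_size=64,
                  batch_size=8, seed=1)
model, hist = train_model([by_id[i] for i in split.train_ids], cfg)
print(hist["train_loss"][0], hist["train_loss"][-1])   # 0.6812 -> 0.2585
print(evaluate_model(model, [by_id[i] for i in split.test_ids], cfg))
# {'dice': 0.947, 'iou': 0.900, 'accuracy': 0.996}
```

The fusion scores say the eigen-weighted image tracks the structural MRI
channel closely (SSIM 0.93) while still blending in PET uptake; the
held-out segmentation metrics show the width-1/8 model delineating the
phantom tumours almost perfectly after 25 epochs (~30 s on one CPU core).

The same operations are available from the shell:

```bash
fuseg synth --n 64 --size 64 --seed 7 --out data/
fuseg summary --format json | head        # per-layer architecture report
fuseg fuse --mri data/mri/phantom_7_0000.png --pet data/pet/phantom_7_0000.png \
           --mode eigen_weighted --out fused.png --report scores.json
fuseg train --data data/ --out run/
fuseg predict --model run/model.npz --mri data/mri/phantom_7_0000.png \
              --pet data/pet/phantom_7_0000.png --out mask.png
```

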