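"""Synthetic co-registered MRI/PET tumour phantoms with exact ground truth.

Each phantom models one axial slice: the MRI-like channel has an elliptical
brain with a bright skull rim, grainy internal texture and a sharply ringed
tumour; the PET-like channel is smooth, with a high-intensity Gaussian uptake
blob centred on the tumour. The binary mask is the exact tumour ellipse, so
all three channels are co-registered by construction.

Phantoms are deterministic in (seed, index), which makes datasets reproducible
and individually addressable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .io_prep import ImagePair

__all__ = ["PhantomConfig", "make_phantom_pair", "make_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom family."""

    size: int = 64
    tumour_count: tuple[int, int] = (1, 1)  # inclusive range
    tumour_radius: tuple[float, float] = (4.0, 10.0)  # pixel semi-axes
    mri_edge_contrast: float = 0.35
    pet_blob_sigma_scale: float = 0.8  # uptake sigma relative to tumour radius
    pet_smoothness: float = 2.0
    mri_noise_std: float = 0.02
    pet_noise_std: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if self.tumour_radius[1] >= self.size / 2:
            raise ValueError("tumour radii must be < size/2")
        if self.tumour_radius[0] <= 0 or self.tumour_radius[0] > self.tumour_radius[1]:
            raise ValueError("invalid tumour radius range")
        if self.tumour_count[0] < 1 or self.tumour_count[0] > self.tumour_count[1]:
            raise ValueError("invalid tumour count range")
        if self.mri_noise_std < 0 or self.pet_noise_std < 0:
            raise ValueError("noise std must be >= 0")


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_phantom_pair(config: PhantomConfig, index: int) -> ImagePair:
    """Generate the ``index``-th phantom of the family defined by ``config``."""
    rng = np.random.default_rng([config.seed, index])
    s = config.size
    cy0, cx0 = (s - 1) / 2.0, (s - 1) / 2.0
    brain_ry = s * 0.42 * rng.uniform(0.95, 1.05)
    brain_rx = s * 0.38 * rng.uniform(0.95, 1.05)
    brain = _ellipse_mask(s, cy0, cx0, brain_ry, brain_rx, 0.0)
    skull = _ellipse_mask(s, cy0, cx0, brain_ry + 1.8, brain_rx + 1.8, 0.0) & ~brain

    n_tum = int(rng.integers(config.tumour_count[0], config.tumour_count[1] + 1))
    mask = np.zeros((s, s), dtype=bool)
    centres: list[tuple[float, float, float]] = []
    for _ in range(n_tum):
        rx = rng.uniform(*config.tumour_radius)
        ry = rng.uniform(*config.tumour_radius)
        theta = rng.uniform(0.0, np.pi)
        rmax = max(rx, ry)
        # keep the tumour fully inside the brain ellipse interior
        for _attempt in range(50):
            cy = cy0 + rng.uniform(-1, 1) * (brain_ry - rmax - 3.0)
            cx = cx0 + rng.uniform(-1, 1) * (brain_rx - rmax - 3.0)
            cand = _ellipse_mask(s, cy, cx, ry, rx, theta)
            if cand.sum() > 0 and (cand & ~brain).sum() == 0:
                break
        mask |= cand
        centres.append((cy, cx, rmax))

    # MRI-like channel: textured tissue, bright skull, sharply ringed tumour
    texture = gaussian_filter(rng.normal(0.0, 1.0, (s, s)), 1.0)
    texture = 0.08 * texture / max(np.abs(texture).max(), 1e-9)
    mri = np.zeros((s, s))
    mri[brain] = 0.45 + texture[brain]
    mri[skull] = 0.95
    # rim = dilated mask minus mask: sharp hyperintense boundary ring
    rim = binary_dilation(mask, iterations=1) & ~mask
    mri[mask] = 0.45 - config.mri_edge_contrast + texture[mask]
    mri[rim & brain] = 0.45 + config.mri_edge_contrast
    mri += rng.normal(0.0, config.mri_noise_std, (s, s))

    # PET-like channel: smooth background plus Gaussian uptake on the tumour
    pet = np.zeros((s, s))
    pet[brain] = 0.25
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    for cy, cx, rmax in centres:
        sigma = config.pet_blob_sigma_scale * rmax
        pet += 0.65 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2)))
    pet = gaussian_filter(pet, config.pet_smoothness)
    pet += rng.normal(0.0, config.pet_noise_std, (s, s))

    return ImagePair(
        mri=np.clip(mri, 0.0, 1.0),
        pet=np.clip(pet, 0.0, 1.0),
        mask=mask.astype(np.uint8),
        id=f"phantom_{config.seed}_{index:04d}",
    )


def make_dataset(config: PhantomConfig, n: int) -> list[ImagePair]:
    """Generate ``n`` distinct phantoms (deterministic in config.seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [make_phantom_pair(config, i) for i in range(n)]
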