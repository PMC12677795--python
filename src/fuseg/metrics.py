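"""Image-quality and segmentation-overlap metrics.

Fusion quality is scored with PSNR and SSIM against each source modality;
segmentation quality with the Dice coefficient, the Jaccard index (IoU) and
pixel accuracy between the predicted and ground-truth binary masks.

SSIM here is the standard windowed form with stabilizers Z1 = (0.01 L)^2 and
Z2 = (0.03 L)^2 and a uniform odd window (default 7x7); local statistics are
population moments, and the mean is taken over windows fully inside the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "SSIMParams",
    "psnr",
    "ssim",
    "dice",
    "iou",
    "pixel_accuracy",
    "binarize",
]


@dataclass(frozen=True)
class SSIMParams:
    """Window size, dynamic range L and derived stabilizers."""

    window: int = 7
    dynamic_range: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("SSIM window must be odd and >= 3")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic range must be positive")

    @property
    def z1(self) -> float:
        return (0.01 * self.dynamic_range) ** 2

    @property
    def z2(self) -> float:
        return (0.03 * self.dynamic_range) ** 2


def _check_dims(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def psnr(ref: np.ndarray, test: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(max_i^2 / MSE), in decibels.

    Identical images have zero MSE; this returns ``inf`` as the documented
    sentinel rather than raising.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    _check_dims(ref, test)
    if max_i <= 0:
        raise ValueError("max_i must be positive")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_i ** 2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, params: SSIMParams | None = None) -> float:
    """Mean local structural similarity, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _check_dims(a, b)
    p = params or SSIMParams()
    if min(a.shape) < p.window:
        raise ValueError(f"image {a.shape} smaller than SSIM window {p.window}")
    win = p.window
    mu_a = uniform_filter(a, win)
    mu_b = uniform_filter(b, win)
    var_a = uniform_filter(a * a, win) - mu_a ** 2
    var_b = uniform_filter(b * b, win) - mu_b ** 2
    cov = uniform_filter(a * b, win) - mu_a * mu_b
    z1, z2 = p.z1, p.z2
    num = (2 * mu_a * mu_b + z1) * (2 * cov + z2)
    den = (mu_a ** 2 + mu_b ** 2 + z1) * (var_a + var_b + z2)
    smap = num / den
    pad = win // 2  # keep only windows fully inside the image
    return float(smap[pad:smap.shape[0] - pad, pad:smap.shape[1] - pad].mean())


def _as_binary(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if not ((m == 0) | (m == 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")
    return m.astype(bool)


def dice(i1: np.ndarray, i2: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 (with a warning) if both empty."""
    a = _as_binary(i1, "i1")
    b = _as_binary(i2, "i2")
    _check_dims(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        warnings.warn("Dice of two empty masks: returning 1.0 (vacuous agreement)",
                      stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou(i1: np.ndarray, i2: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 (with a warning) if both empty."""
    a = _as_binary(i1, "i1")
    b = _as_binary(i2, "i2")
    _check_dims(a, b)
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("IoU of two empty masks: returning 1.0 (vacuous agreement)",
                      stacklevel=2)
        return 1.0
    return int((a & b).sum()) / union


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels on which the two binary masks agree."""
    a = _as_binary(pred, "pred")
    b = _as_binary(truth, "truth")
    _check_dims(a, b)
    return float((a == b).mean())


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map in [0,1] into a {0,1} mask (>= threshold -> 1)."""
    p = np.asarray(prob_map, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return (p >= threshold).astype(np.uint8)
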