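"""Training and evaluation of the segmenter on fused MRI/PET images.

The pipeline fuses each pair (PCA reconstruction by default), replicates the
grayscale fused image to the network's input channels, and optimises the
sigmoid-head U-Net with Adam. The protocol mirrors the study design: a fixed
epoch budget, k-fold cross-validation with Dice / IoU / pixel-accuracy
reporting, and full determinism under a fixed seed (weight init, shuffle
order and fold assignment all derive from it).

The loss is selectable: binary cross-entropy (default, matching the
single-channel sigmoid head), soft Dice, or their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import KFold

from . import fusion, metrics, nn
from .io_prep import ImagePair
from .network import NetworkSpec, PermutateUNet, build_network

__all__ = [
    "TrainConfig",
    "FoldResult",
    "SegmentationResult",
    "fuse_to_inputs",
    "train_model",
    "evaluate_model",
    "cross_validate",
    "predict_mask",
]

_LOSSES = ("bce", "dice", "bce_plus_dice")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    folds: int = 5
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss: str = "bce"
    seed: int = 0
    width_multiplier: float = 1.0
    threshold: float = 0.5
    image_size: int = 256
    fusion_mode: str = "paper_reconstruct"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(input_h=self.image_size, input_w=self.image_size,
                           width_multiplier=self.width_multiplier)


@dataclass(frozen=True)
class FoldResult:
    fold: int
    train_loss: list[float]
    val_loss: list[float]
    dice: float
    iou: float
    accuracy: float


@dataclass(frozen=True)
class SegmentationResult:
    probability: np.ndarray
    mask: np.ndarray
    dice: float | None = None
    iou: float | None = None
    accuracy: float | None = None


def _loss_fn(name: str):
    if name == "bce":
        return nn.bce_with_logits
    if name == "dice":
        return nn.dice_loss_with_logits

    def combined(logits, target):
        l1, d1 = nn.bce_with_logits(logits, target)
        l2, d2 = nn.dice_loss_with_logits(logits, target)
        return l1 + l2, d1 + d2

    return combined


def fuse_to_inputs(pairs: list[ImagePair], config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fuse each pair and build (X, Y) network tensors.

    X is (N, H, W, C) with the fused grayscale image replicated across the
    input channels; Y is (N, H, W, 1) of binary masks.
    """
    spec = config.network_spec()
    xs, ys = [], []
    for p in pairs:
        if p.mask is None:
            raise ValueError(f"pair {p.id} has no ground-truth mask")
        if not np.isin(p.mask, (0, 1)).all():
            raise ValueError(f"pair {p.id} has a non-binary mask")
        fused = fusion.fuse_pair(p, mode=config.fusion_mode).pixels
        xs.append(np.repeat(fused[:, :, None], spec.input_channels, axis=2))
        ys.append(p.mask[:, :, None].astype(np.float32))
    return np.stack(xs).astype(np.float32), np.stack(ys)


def train_model(pairs: list[ImagePair], config: TrainConfig,
                val_pairs: list[ImagePair] | None = None
                ) -> tuple[PermutateUNet, dict[str, list[float]]]:
    """Train a fresh model on fused pairs; returns (model, loss history).

    Deterministic given ``config.seed``: weight initialisation and per-epoch
    shuffle order are drawn from it.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    x, y = fuse_to_inputs(pairs, config)
    xv = yv = None
    if val_pairs:
        xv, yv = fuse_to_inputs(val_pairs, config)
    model = build_network(config.network_spec(), seed=config.seed)
    opt = nn.Adam(model.layers(), lr=config.learning_rate)
    loss_fn = _loss_fn(config.loss)
    rng = np.random.default_rng(config.seed + 1)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    n = x.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, dlogits = loss_fn(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)
        if xv is not None:
            vloss = 0.0
            for start in range(0, xv.shape[0], config.batch_size):
                logits = model.forward(xv[start:start + config.batch_size],
                                       training=False)
                l, _ = loss_fn(logits, yv[start:start + config.batch_size])
                vloss += l * min(config.batch_size, xv.shape[0] - start)
            history["val_loss"].append(vloss / xv.shape[0])
    return model, history


def evaluate_model(model: PermutateUNet, pairs: list[ImagePair],
                   config: TrainConfig) -> dict[str, float]:
    """Mean Dice / IoU / pixel accuracy of the model over pairs with masks."""
    x, y = fuse_to_inputs(pairs, config)
    ds, js, accs = [], [], []
    for start in range(0, x.shape[0], config.batch_size):
        probs = model.predict_proba(x[start:start + config.batch_size])
        for i in range(probs.shape[0]):
            pred = metrics.binarize(probs[i], config.threshold)
            truth = y[start + i, :, :, 0].astype(np.uint8)
            ds.append(metrics.dice(pred, truth))
            js.append(metrics.iou(pred, truth))
            accs.append(metrics.pixel_accuracy(pred, truth))
    return {"dice": float(np.mean(ds)), "iou": float(np.mean(js)),
            "accuracy": float(np.mean(accs))}


def cross_validate(pairs: list[ImagePair], config: TrainConfig
                   ) -> tuple[list[FoldResult], dict[str, float]]:
    """K-fold cross-validation; folds are disjoint and cover every sample."""
    if len(pairs) < config.folds:
        raise ValueError(f"need at least {config.folds} samples for "
                         f"{config.folds}-fold cross-validation")
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    results: list[FoldResult] = []
    for fold, (tr_idx, va_idx) in enumerate(kf.split(pairs)):
        tr = [pairs[i] for i in tr_idx]
        va = [pairs[i] for i in va_idx]
        model, hist = train_model(tr, config, val_pairs=va)
        m = evaluate_model(model, va, config)
        results.append(FoldResult(fold=fold, train_loss=hist["train_loss"],
                                  val_loss=hist["val_loss"], dice=m["dice"],
                                  iou=m["iou"], accuracy=m["accuracy"]))
    averaged = {
        "dice": float(np.mean([r.dice for r in results])),
        "iou": float(np.mean([r.iou for r in results])),
        "accuracy": float(np.mean([r.accuracy for r in results])),
    }
    return results, averaged


def predict_mask(model: PermutateUNet, pair: ImagePair,
                 config: TrainConfig) -> SegmentationResult:
    """Segment one pair; scores against the ground truth when present."""
    x, _ = fuse_to_inputs(
        [pair if pair.mask is not None else
         ImagePair(mri=pair.mri, pet=pair.pet,
                   mask=np.zeros(pair.shape, dtype=np.uint8), id=pair.id)],
        config)
    prob = model.predict_proba(x)[0]
    mask = metrics.binarize(prob, config.threshold)
    if pair.mask is not None:
        return SegmentationResult(
            probability=prob, mask=mask,
            dice=metrics.dice(mask, pair.mask),
            iou=metrics.iou(mask, pair.mask),
            accuracy=metrics.pixel_accuracy(mask, pair.mask))
    return SegmentationResult(probability=prob, mask=mask)
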