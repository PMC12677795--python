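"""Permutate U-Net: architecture description, analytic parameter accounting,
and an executable numpy model.

The architecture is a five-level encoder-decoder with a 2048-filter middle
block. Encoder filter counts double from ``base_filters`` (64, 128, 256, 512,
1024); the decoder follows an asymmetric channel plan in which the second
convolution of blocks 2-4 halves the channel count, so decoder widths step
down 1024, 512/256, 256/128, 128/64, 64/64 before a 1x1 sigmoid head. Each
half-block is conv3x3 -> ReLU -> conv3x3 -> BatchNorm -> ReLU; downsampling is
2x2 max pooling, upsampling a 2x2 stride-2 transposed convolution whose output
is concatenated with the matching encoder activation. At full width the model
has 122,480,513 trainable parameters.

``width_multiplier`` scales every filter count for desk-scale training; all
scaled counts must remain positive integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np

from . import nn

__all__ = [
    "NetworkSpec",
    "LayerReport",
    "ChannelPlan",
    "conv2d_param_count",
    "transpose_conv_param_count",
    "batchnorm_param_count",
    "layer_reports",
    "count_parameters",
    "build_network",
    "PermutateUNet",
]

# Decoder channel plan at full width: per block
# (transpose_in, transpose_out, conv1_out, conv2_out).
_DECODER_PLAN_FULL = [
    (2048, 1024, 1024, 1024),
    (1024, 512, 512, 256),
    (256, 256, 256, 128),
    (128, 128, 128, 64),
    (64, 64, 64, 64),
]


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the Permutate U-Net."""

    input_h: int = 256
    input_w: int = 256
    input_channels: int = 3
    base_filters: int = 64
    depth: int = 5
    middle_filters: int = 2048
    conv_kernel: int = 3
    transpose_kernel: int = 2
    final_kernel: int = 1
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        div = 2 ** self.depth * 2
        if self.input_h % div or self.input_w % div:
            raise ValueError(
                f"input dims {self.input_h}x{self.input_w} must be divisible by "
                f"{div} (depth {self.depth} poolings plus the middle pooling)")
        if self.depth != 5:
            raise ValueError("the architecture is defined for depth 5")
        # validate that every scaled filter count is a positive integer
        self.encoder_channels()

    def _scale(self, c: int) -> int:
        scaled = Fraction(c) * Fraction(self.width_multiplier).limit_denominator(10**6)
        if scaled.denominator != 1 or scaled.numerator < 1:
            raise ValueError(
                f"width_multiplier {self.width_multiplier} gives non-integral or "
                f"non-positive channel count for {c} filters")
        return int(scaled)

    def encoder_channels(self) -> list[int]:
        return [self._scale(self.base_filters * 2 ** i) for i in range(self.depth)]

    def middle_channels(self) -> int:
        return self._scale(self.middle_filters)

    def decoder_plan(self) -> "ChannelPlan":
        return ChannelPlan([tuple(self._scale(c) for c in blk)
                            for blk in _DECODER_PLAN_FULL])

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class ChannelPlan:
    """Per-decoder-block (transpose_in, transpose_out, conv1_out, conv2_out)."""

    blocks: list[tuple[int, int, int, int]]


@dataclass(frozen=True)
class LayerReport:
    """One row of the per-layer architecture report."""

    block: str
    layer: str
    input_shape: tuple[int, int, int]
    filters: int | None
    output_shape: tuple[int, int, int]
    params: int
    trainable: int


def conv2d_param_count(in_ch: int, out_ch: int, kernel: int) -> int:
    """Weights plus bias of a 2-D convolution: k^2 * c_in * c_out + c_out."""
    if in_ch < 1 or out_ch < 1 or kernel < 1:
        raise ValueError("channel counts and kernel must be positive")
    return kernel * kernel * in_ch * out_ch + out_ch


def transpose_conv_param_count(in_ch: int, out_ch: int, kernel: int) -> int:
    """Transposed convolutions carry the same weight/bias count as convolutions."""
    return conv2d_param_count(in_ch, out_ch, kernel)


def batchnorm_param_count(channels: int) -> tuple[int, int]:
    """(total, trainable): scale+shift trainable, running mean/var not."""
    if channels < 1:
        raise ValueError("channels must be positive")
    return 4 * channels, 2 * channels


def layer_reports(spec: NetworkSpec) -> list[LayerReport]:
    """Per-layer report of the full layer sequence, in architecture order."""
    rows: list[LayerReport] = []
    h, w = spec.input_h, spec.input_w
    k = spec.conv_kernel
    enc = spec.encoder_channels()
    c_in = spec.input_channels

    def shape(hh, ww, cc):
        return (hh, ww, cc)

    rows.append(LayerReport("Down Sampling Block-1", "Input", shape(h, w, c_in),
                            None, shape(h, w, c_in), 0, 0))
    prev = c_in
    for i, c in enumerate(enc, start=1):
        blk = f"Down Sampling Block-{i}"
        if i > 1:
            rows.append(LayerReport(blk, "MaxPooling", shape(h, w, prev), prev,
                                    shape(h // 2, w // 2, prev), 0, 0))
            h, w = h // 2, w // 2
        p1 = conv2d_param_count(prev, c, k)
        rows.append(LayerReport(blk, "Conv2D", shape(h, w, prev), c, shape(h, w, c), p1, p1))
        rows.append(LayerReport(blk, "Activation", shape(h, w, c), None, shape(h, w, c), 0, 0))
        p2 = conv2d_param_count(c, c, k)
        rows.append(LayerReport(blk, "Conv2D", shape(h, w, c), c, shape(h, w, c), p2, p2))
        bn_t, bn_tr = batchnorm_param_count(c)
        rows.append(LayerReport(blk, "BatchNormalization", shape(h, w, c), None,
                                shape(h, w, c), bn_t, bn_tr))
        rows.append(LayerReport(blk, "Activation", shape(h, w, c), None, shape(h, w, c), 0, 0))
        prev = c

    mid = spec.middle_channels()
    rows.append(LayerReport("Middle Layer", "MaxPooling", shape(h, w, prev), prev,
                            shape(h // 2, w // 2, prev), 0, 0))
    h, w = h // 2, w // 2
    p1 = conv2d_param_count(prev, mid, k)
    rows.append(LayerReport("Middle Layer", "Conv2D", shape(h, w, prev), mid,
                            shape(h, w, mid), p1, p1))
    rows.append(LayerReport("Middle Layer", "Activation", shape(h, w, mid), None,
                            shape(h, w, mid), 0, 0))
    p2 = conv2d_param_count(mid, mid, k)
    rows.append(LayerReport("Middle Layer", "Conv2D", shape(h, w, mid), mid,
                            shape(h, w, mid), p2, p2))
    bn_t, bn_tr = batchnorm_param_count(mid)
    rows.append(LayerReport("Middle Layer", "BatchNormalization", shape(h, w, mid), None,
                            shape(h, w, mid), bn_t, bn_tr))
    rows.append(LayerReport("Middle Layer", "Activation", shape(h, w, mid), None,
                            shape(h, w, mid), 0, 0))

    plan = spec.decoder_plan()
    for j, (t_in, t_out, c1, c2) in enumerate(plan.blocks, start=1):
        blk = f"Up Sampling Block-{j}"
        skip = enc[spec.depth - j]
        pt = transpose_conv_param_count(t_in, t_out, spec.transpose_kernel)
        rows.append(LayerReport(blk, "Conv2DTranspose", shape(h, w, t_in), t_out,
                                shape(h * 2, w * 2, t_out), pt, pt))
        h, w = h * 2, w * 2
        rows.append(LayerReport(blk, "Concatenate", shape(h, w, t_out), None,
                                shape(h, w, t_out + skip), 0, 0))
        p1 = conv2d_param_count(t_out + skip, c1, k)
        rows.append(LayerReport(blk, "Conv2D", shape(h, w, t_out + skip), c1,
                                shape(h, w, c1), p1, p1))
        rows.append(LayerReport(blk, "Activation", shape(h, w, c1), None, shape(h, w, c1), 0, 0))
        p2 = conv2d_param_count(c1, c2, k)
        rows.append(LayerReport(blk, "Conv2D", shape(h, w, c1), c2, shape(h, w, c2), p2, p2))
        bn_t, bn_tr = batchnorm_param_count(c2)
        rows.append(LayerReport(blk, "BatchNormalization", shape(h, w, c2), None,
                                shape(h, w, c2), bn_t, bn_tr))
        rows.append(LayerReport(blk, "Activation", shape(h, w, c2), None, shape(h, w, c2), 0, 0))

    ph = conv2d_param_count(plan.blocks[-1][3], 1, spec.final_kernel)
    rows.append(LayerReport("Output", "Conv2D", shape(h, w, plan.blocks[-1][3]), 1,
                            shape(h, w, 1), ph, ph))
    return rows


def count_parameters(spec: NetworkSpec) -> tuple[int, int, list[LayerReport]]:
    """Analytic (total, trainable, per-layer report) for the layer sequence."""
    rows = layer_reports(spec)
    total = sum(r.params for r in rows)
    trainable = sum(r.trainable for r in rows)
    return total, trainable, rows


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> BatchNorm -> ReLU."""

    def __init__(self, c_in, c1, c2, k, rng, dtype):
        self.conv1 = nn.Conv2D(c_in, c1, k, rng, dtype)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2D(c1, c2, k, rng, dtype)
        self.bn = nn.BatchNorm2D(c2, dtype=dtype)
        self.relu2 = nn.ReLU()
        self.layers = [self.conv1, self.relu1, self.conv2, self.bn, self.relu2]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class PermutateUNet:
    """Executable Permutate U-Net with forward and backward passes.

    ``forward`` returns logits; ``predict_proba`` applies the sigmoid head.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> None:
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = spec.conv_kernel
        enc = spec.encoder_channels()
        mid = spec.middle_channels()
        plan = spec.decoder_plan()

        self.enc_blocks: list[_ConvBlock] = []
        self.pools: list[nn.MaxPool2x2] = []
        prev = spec.input_channels
        for c in enc:
            self.enc_blocks.append(_ConvBlock(prev, c, c, k, rng, dtype))
            prev = c
        for _ in range(spec.depth):  # pools before blocks 2..5 and the middle
            self.pools.append(nn.MaxPool2x2())
        self.middle = _ConvBlock(enc[-1], mid, mid, k, rng, dtype)

        self.upsamples: list[nn.ConvTranspose2D] = []
        self.dec_blocks: list[_ConvBlock] = []
        self.skip_channels: list[int] = []
        for j, (t_in, t_out, c1, c2) in enumerate(plan.blocks):
            skip = enc[spec.depth - 1 - j]
            self.upsamples.append(nn.ConvTranspose2D(t_in, t_out, rng, dtype,
                                                     kernel=spec.transpose_kernel))
            self.dec_blocks.append(_ConvBlock(t_out + skip, c1, c2, k, rng, dtype))
            self.skip_channels.append(skip)
        self.head = nn.Conv2D(plan.blocks[-1][3], 1, spec.final_kernel, rng, dtype)

    # -- introspection -------------------------------------------------------
    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for i, blk in enumerate(self.enc_blocks):
            if i > 0:
                out.append(self.pools[i - 1])
            out.extend(blk.layers)
        out.append(self.pools[-1])
        out.extend(self.middle.layers)
        for up, dec in zip(self.upsamples, self.dec_blocks):
            out.append(up)
            out.extend(dec.layers)
        out.append(self.head)
        return out

    def parameter_count(self) -> tuple[int, int]:
        """(total, trainable) counted from the instantiated arrays."""
        total = trainable = 0
        for l in self.layers():
            for v in l.params.values():
                total += v.size
                trainable += v.size
            if isinstance(l, nn.BatchNorm2D):
                total += l.running_mean.size + l.running_var.size
        return total, trainable

    # -- execution -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.input_h or x.shape[2] != self.spec.input_w \
                or x.shape[3] != self.spec.input_channels:
            raise ValueError(
                f"expected input (B, {self.spec.input_h}, {self.spec.input_w}, "
                f"{self.spec.input_channels}), got {x.shape}")
        x = x.astype(self.dtype, copy=False)
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            if i > 0:
                x = self.pools[i - 1].forward(x, training)
            x = blk.forward(x, training)
            skips.append(x)
        x = self.pools[-1].forward(x, training)
        x = self.middle.forward(x, training)
        for j, (up, dec) in enumerate(zip(self.upsamples, self.dec_blocks)):
            x = up.forward(x, training)
            skip = skips[self.spec.depth - 1 - j]
            x = np.concatenate([x, skip], axis=-1)
            x = dec.forward(x, training)
        self._training = training
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * self.spec.depth
        for j in range(self.spec.depth - 1, -1, -1):
            d = self.dec_blocks[j].backward(d)
            t_out = self.upsamples[j].c_out
            d_up, d_skip = d[..., :t_out], d[..., t_out:]
            enc_i = self.spec.depth - 1 - j
            dskips[enc_i] = d_skip if dskips[enc_i] is None else dskips[enc_i] + d_skip
            d = self.upsamples[j].backward(np.ascontiguousarray(d_up))
        d = self.middle.backward(d)
        d = self.pools[-1].backward(d)
        for i in range(self.spec.depth - 1, -1, -1):
            d = d + dskips[i] if dskips[i] is not None else d
            d = self.enc_blocks[i].backward(d)
            if i > 0:
                d = self.pools[i - 1].backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probability map, shape (B, H, W)."""
        return nn.sigmoid(self.forward(x, training=False))[..., 0]

    # -- persistence ---------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self.layers()):
            for k, v in l.params.items():
                out[f"layer{i:03d}.{k}"] = v
            if isinstance(l, nn.BatchNorm2D):
                out[f"layer{i:03d}.running_mean"] = l.running_mean
                out[f"layer{i:03d}.running_var"] = l.running_var
        return out

    def save(self, path: str) -> None:
        np.savez(path, __spec__=np.array(self.spec.to_json()), **self.state_arrays())

    @classmethod
    def load(cls, path: str) -> "PermutateUNet":
        data = np.load(path, allow_pickle=False)
        spec = NetworkSpec.from_json(str(data["__spec__"]))
        model = cls(spec, seed=0)
        for i, l in enumerate(model.layers()):
            for k in l.params:
                l.params[k][...] = data[f"layer{i:03d}.{k}"]
                l.grads[k] = np.zeros_like(l.params[k])
            if isinstance(l, nn.BatchNorm2D):
                l.running_mean[...] = data[f"layer{i:03d}.running_mean"]
                l.running_var[...] = data[f"layer{i:03d}.running_var"]
        return model


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> PermutateUNet:
    """Instantiate the executable model for a spec (weights seeded by ``seed``)."""
    return PermutateUNet(spec, seed=seed, dtype=dtype)
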