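"""Minimal numpy neural-network layers with hand-written backpropagation.

Layers operate on NHWC float arrays. Every layer exposes ``forward(x, training)``
and ``backward(dy)``; parameterised layers keep their weights in ``params`` and
accumulate gradients of the scalar loss in ``grads``. The implementation favours
large matrix multiplications (shift-and-GEMM convolutions) so that desk-scale
training of the segmentation network runs in minutes on one CPU core.

All layers are verified against central-difference numerical gradients in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "dice_loss_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2D(Layer):
    """2-D convolution, odd square kernel, 'same' zero padding, stride 1, bias.

    Weight layout (k, k, c_in, c_out). He-normal initialisation.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("Conv2D supports odd kernels only (same padding)")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out))
        self.params = {"w": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self.grads = {"w": np.zeros_like(self.params["w"]),
                      "b": np.zeros_like(self.params["b"])}
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        p = self.k // 2
        w, b = self.params["w"], self.params["b"]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        B, H, W = x.shape[0], x.shape[1], x.shape[2]
        y = np.broadcast_to(b, (B, H, W, self.c_out)).copy()
        for kh in range(self.k):
            for kw in range(self.k):
                y += xp[:, kh:kh + H, kw:kw + W, :] @ w[kh, kw]
        if training:
            self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward before training-mode forward"
        w = self.params["w"]
        B, H, W = dy.shape[0], dy.shape[1], dy.shape[2]
        p = self.k // 2
        dxp = np.zeros_like(xp)
        dw, db = self.grads["w"], self.grads["b"]
        db += dy.sum(axis=(0, 1, 2))
        dyf = dy.reshape(-1, self.c_out)
        for kh in range(self.k):
            for kw in range(self.k):
                patch = xp[:, kh:kh + H, kw:kw + W, :].reshape(-1, self.c_in)
                dw[kh, kw] += patch.T @ dyf
                dxp[:, kh:kh + H, kw:kw + W, :] += dy @ w[kh, kw].T
        self._xp = None
        return dxp[:, p:p + H, p:p + W, :]


class ConvTranspose2D(Layer):
    """Transposed convolution with kernel 2, stride 2 (non-overlapping upsample)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, kernel: int = 2) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(kernel, kernel, c_in, c_out))
        self.params = {"w": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self.grads = {"w": np.zeros_like(self.params["w"]),
                      "b": np.zeros_like(self.params["b"])}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        k = self.k
        B, H, W = x.shape[0], x.shape[1], x.shape[2]
        # t[b,i,j,kh,kw,o] = sum_c x[b,i,j,c] * w[kh,kw,c,o]
        t = np.tensordot(x, self.params["w"], axes=([3], [2]))
        y = t.transpose(0, 1, 3, 2, 4, 5).reshape(B, H * k, W * k, self.c_out)
        y = y + self.params["b"]
        if training:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        k = self.k
        B, H, W = x.shape[0], x.shape[1], x.shape[2]
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        t = dy.reshape(B, H, k, W, k, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        # dx[b,i,j,c] = sum_{kh,kw,o} t[b,i,j,kh,kw,o] * w[kh,kw,c,o]
        dx = np.tensordot(t, self.params["w"], axes=([3, 4, 5], [0, 1, 3]))
        # dw[c,kh,kw,o] -> transpose to (kh,kw,c,o)
        dw = np.tensordot(x, t, axes=([0, 1, 2], [0, 1, 2]))
        self.grads["w"] += dw.transpose(1, 2, 0, 3)
        self._x = None
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalisation over (batch, height, width).

    Trainable scale/shift plus running mean/variance buffers used at inference;
    population (biased) variance, matching the parameter accounting of four
    stored values per channel of which two are trainable.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.grads = {"gamma": np.zeros(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        if training:
            self._cache = (xhat, std)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, std = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] += dy.sum(axis=(0, 1, 2))
        g = self.params["gamma"]
        mean_dy = dy.mean(axis=(0, 1, 2))
        mean_dy_xhat = (dy * xhat).mean(axis=(0, 1, 2))
        dx = (g / std) * (dy - mean_dy - xhat * mean_dy_xhat)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2. Ties send the gradient to the first maximum."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {H}x{W}")
        xr = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(B, H // 2, W // 2, C, 4)
        if training:
            self._arg = xr.argmax(axis=-1)
            self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        onehot = np.zeros((B, H // 2, W // 2, C, 4), dtype=dy.dtype)
        np.put_along_axis(onehot, self._arg[..., None], 1.0, axis=-1)
        onehot *= dy[..., None]
        dx = onehot.reshape(B, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._arg = None
        return dx.reshape(B, H, W, C)


class Adam:
    """Adaptive-moment optimiser over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dL/dlogits)."""
    n = logits.size
    # log(1+exp(z)) computed stably as max(z,0) + log1p(exp(-|z|))
    loss = float(np.mean(np.maximum(logits, 0) - logits * target
                         + np.log1p(np.exp(-np.abs(logits)))))
    dz = (sigmoid(logits) - target) / n
    return loss, dz.astype(logits.dtype)


def dice_loss_with_logits(logits: np.ndarray, target: np.ndarray,
                          smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Soft Dice loss 1 - (2*sum(p*y)+s)/(sum(p)+sum(y)+s) on sigmoid probabilities."""
    p = sigmoid(logits)
    inter = float((p * target).sum())
    denom = float(p.sum() + target.sum()) + smooth
    dice = (2.0 * inter + smooth) / denom
    loss = 1.0 - dice
    # d dice / d p = 2*y/denom - (2*inter+s)/denom^2
    ddice_dp = 2.0 * target / denom - (2.0 * inter + smooth) / denom ** 2
    dz = -ddice_dp * p * (1.0 - p)
    return float(loss), dz.astype(logits.dtype)
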