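"""Minimal CPU neural-network engine for the WFCN segmentation models.

Implements exactly the pieces a U-Net needs — 'same' 3x3 / 1x1 convolutions
via im2col + GEMM, ReLU, 2x2 max-pooling, nearest-neighbour 2x upsampling,
channel concatenation, softmax cross-entropy and the Adam optimizer — with
hand-written backward passes.  All tensors are ``(batch, channels, rows,
cols)`` float32; computation is pure numpy, so runs are deterministic for a
fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Engine dtype.  float32 is the training default; float64 is useful for
#: numerical verification (e.g. finite-difference gradient checks).
DTYPE = np.float32

__all__ = [
    "Param", "Conv2d", "ReLU", "MaxPool2", "UpsampleNearest2",
    "concat_channels", "split_channels", "softmax", "softmax_cross_entropy",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """'Same' convolution with square kernel (1 or 3), stride 1.

    He-normal initialization from the supplied generator; weights stored as
    ``(C_out, C_in * k * k)`` for the im2col GEMM.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv") -> None:
        if kernel_size not in (1, 3):
            raise ValueError("kernel_size must be 1 or 3")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, fan_in))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias")
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"{self.weight.name}: expected {self.in_channels} input "
                f"channels, got {c}")
        k = self.kernel_size
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(b * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            win = sliding_window_view(xp, (k, k), axis=(2, 3))  # b,c,h,w,k,k
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
            cols = cols.reshape(b * h * w, c * k * k)
        out = cols @ self.weight.value.T + self.bias.value
        self._cols = cols
        self._in_shape = x.shape
        return out.reshape(b, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._in_shape is not None
        b, c, h, w = self._in_shape
        k = self.kernel_size
        g = np.ascontiguousarray(grad_out.transpose(0, 2, 3, 1))
        g = g.reshape(b * h * w, self.out_channels)
        self.weight.grad += g.T @ self._cols
        self.bias.grad += g.sum(axis=0)
        dcols = g @ self.weight.value  # (b*h*w, c*k*k)
        if k == 1:
            dx = dcols.reshape(b, h, w, c).transpose(0, 3, 1, 2)
            return np.ascontiguousarray(dx)
        dcols = dcols.reshape(b, h, w, c, k, k)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        return dxp[:, :, 1:1 + h, 1:1 + w]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return np.where(self._mask, grad_out, np.float32(0.0))


class MaxPool2:
    """2x2 max pooling, stride 2.  Ties resolve to the first maximum."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even sides, got {(h, w)}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._argmax is not None and self._in_shape is not None
        b, c, h, w = self._in_shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxr, self._argmax[..., None], grad_out[..., None],
                          axis=-1)
        dxr = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr.reshape(b, c, h, w))


class UpsampleNearest2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b, c, h, w = grad_out.shape
        return grad_out.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def concat_channels(parts: list[np.ndarray]) -> np.ndarray:
    return np.concatenate(parts, axis=1)


def split_channels(grad: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    return list(np.split(grad, np.cumsum(sizes)[:-1], axis=1))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          class_weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean pixelwise cross-entropy on two-class softmax.

    Parameters
    ----------
    logits : (B, K, H, W) float array
    targets : (B, H, W) integer class labels
    class_weights : optional (K,) per-class loss weights

    Returns
    -------
    loss : float
    grad : (B, K, H, W) gradient of the mean loss w.r.t. the logits
    """
    b, k, h, w = logits.shape
    p = softmax(logits.astype(np.float64), axis=1)
    onehot = np.eye(k, dtype=np.float64)[targets].transpose(0, 3, 1, 2)
    if class_weights is None:
        pix_w = np.ones((b, h, w))
    else:
        pix_w = np.asarray(class_weights, dtype=np.float64)[targets]
    denom = pix_w.sum()
    p_true = np.clip((p * onehot).sum(axis=1), 1e-12, None)
    loss = float(-(pix_w * np.log(p_true)).sum() / denom)
    grad = (p - onehot) * pix_w[:, None, :, :] / denom
    return loss, grad.astype(DTYPE)


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)
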