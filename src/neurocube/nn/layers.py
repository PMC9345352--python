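"""Volumetric layers with explicit backprop.

All convolutions are stride-1 with "same" zero padding; spatial shape is only
changed by :class:`MaxPool3d` (2x down) and :class:`ConvTranspose3d` (2x up).
Convolution is computed as a sum over kernel offsets of channel-mixing
``tensordot`` contractions, which keeps memory flat (no im2col buffers) and
routes the heavy lifting through BLAS.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .core import Module, Param, he_init

__all__ = [
    "Conv3d",
    "DepthwiseConv3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "ConvTranspose3d",
    "Linear",
    "Dropout",
    "Sequential",
    "Add",
]


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))


class Conv3d(Module):
    """3D convolution, kernel ``k`` (odd), stride 1, dilation ``d``, same padding.

    Weight shape ``(out_ch, in_ch, k, k, k)``.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 zero_init: bool = False) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k, self.dilation = in_ch, out_ch, k, dilation
        fan_in = in_ch * k ** 3
        if zero_init:
            w = np.zeros((out_ch, in_ch, k, k, k), dtype=np.float32)
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            w = he_init(rng, (out_ch, in_ch, k, k, k), fan_in)
        self.weight = Param(w, "conv.weight")
        self.bias = Param(np.zeros(out_ch, dtype=np.float32), "conv.bias") if bias else None
        self._x_pad: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.k // 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        n, _, dd, hh, ww = x.shape
        xp = _pad_spatial(x, self.pad)
        self._x_pad = xp
        w = self.weight.data
        d = self.dilation
        out = np.zeros((n, self.out_ch, dd, hh, ww), dtype=np.float32)
        if self.k == 1:
            out += np.moveaxis(np.tensordot(w[:, :, 0, 0, 0], x, axes=([1], [1])), 0, 1)
        else:
            for i, j, l in product(range(self.k), repeat=3):
                xs = xp[:, :, i * d:i * d + dd, j * d:j * d + hh, l * d:l * d + ww]
                out += np.moveaxis(np.tensordot(w[:, :, i, j, l], xs, axes=([1], [1])), 0, 1)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._x_pad
        assert xp is not None
        n, _, dd, hh, ww = grad.shape
        w = self.weight.data
        d = self.dilation
        gxp = np.zeros_like(xp)
        for i, j, l in product(range(self.k), repeat=3):
            sl = (slice(None), slice(None),
                  slice(i * d, i * d + dd), slice(j * d, j * d + hh), slice(l * d, l * d + ww))
            xs = xp[sl]
            # dW: contract grad (N,O,D,H,W) with xs (N,I,D,H,W) over N and space
            self.weight.grad[:, :, i, j, l] += np.tensordot(
                grad, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            gxp[sl] += np.moveaxis(
                np.tensordot(w[:, :, i, j, l].T, grad, axes=([1], [1])), 0, 1)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        p = self.pad
        self._x_pad = None
        if p == 0:
            return gxp
        return gxp[:, :, p:-p, p:-p, p:-p]


class DepthwiseConv3d(Module):
    """One 3D kernel per channel (groups == channels); used for dilated squeeze."""

    def __init__(self, ch: int, k: int = 3, dilation: int = 2, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.ch, self.k, self.dilation = ch, k, dilation
        if zero_init:
            w = np.zeros((ch, k, k, k), dtype=np.float32)
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            w = he_init(rng, (ch, k, k, k), k ** 3)
        self.weight = Param(w, "dwconv.weight")
        self.bias = Param(np.zeros(ch, dtype=np.float32), "dwconv.bias") if bias else None
        self._x_pad: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.k // 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.ch:
            raise ValueError(f"expected {self.ch} channels, got {x.shape[1]}")
        n, _, dd, hh, ww = x.shape
        xp = _pad_spatial(x, self.pad)
        self._x_pad = xp
        d = self.dilation
        out = np.zeros_like(x)
        for i, j, l in product(range(self.k), repeat=3):
            xs = xp[:, :, i * d:i * d + dd, j * d:j * d + hh, l * d:l * d + ww]
            out += self.weight.data[None, :, i, j, l, None, None, None] * xs
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._x_pad
        assert xp is not None
        n, _, dd, hh, ww = grad.shape
        d = self.dilation
        gxp = np.zeros_like(xp)
        for i, j, l in product(range(self.k), repeat=3):
            sl = (slice(None), slice(None),
                  slice(i * d, i * d + dd), slice(j * d, j * d + hh), slice(l * d, l * d + ww))
            self.weight.grad[:, i, j, l] += (grad * xp[sl]).sum(axis=(0, 2, 3, 4))
            gxp[sl] += self.weight.data[None, :, i, j, l, None, None, None] * grad
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        p = self.pad
        self._x_pad = None
        return gxp[:, :, p:-p, p:-p, p:-p]


class BatchNorm3d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(np.ones(ch, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(ch, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._stats_seen = False
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            # adopt the first batch outright so eval statistics are sane even
            # after very short trainings
            m = 1.0 if not self._stats_seen else self.momentum
            self._stats_seen = True
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        self._cache = (xhat, inv_std)
        return (self.gamma.data[None, :, None, None, None] * xhat
                + self.beta.data[None, :, None, None, None]).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        m = float(np.prod([grad.shape[a] for a in axes]))
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        if not self.training:
            return (grad * g * inv_std[None, :, None, None, None]).astype(np.float32)
        dxhat = grad * g
        term = (dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m)
        return (term * inv_std[None, :, None, None, None]).astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, grad, 0.0).astype(np.float32)
        self._mask = None
        return g


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        return self._y.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = (grad * self._y * (1.0 - self._y)).astype(np.float32)
        self._y = None
        return g


class MaxPool3d(Module):
    """2x2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape[2:]}")
        xv = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xv = xv.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        self._arg = np.argmax(xv, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xv, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        gv = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(gv, self._arg[..., None], grad[..., None], axis=-1)
        gv = gv.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        gv = gv.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        self._arg = None
        return gv


class ConvTranspose3d(Module):
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    Weight shape ``(in_ch, out_ch, 2, 2, 2)``; non-overlapping windows make the
    forward a single contraction plus an interleave.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch), "convT.weight")
        self.bias = Param(np.zeros(out_ch, dtype=np.float32), "convT.bias") if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        self._x = x
        n, _, d, h, w = x.shape
        # (N,D,H,W,O,2,2,2)
        t = np.tensordot(x, self.weight.data, axes=([1], [0]))
        t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)
        out = t.reshape(n, self.out_ch, 2 * d, 2 * h, 2 * w)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        n, _, d2, h2, w2 = grad.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        g = grad.reshape(n, self.out_ch, d, 2, h, 2, w, 2)
        g = g.transpose(0, 2, 4, 6, 1, 3, 5, 7)  # (N,D,H,W,O,2,2,2)
        self.weight.grad += np.tensordot(x, g, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        gx = np.tensordot(g, self.weight.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        return np.ascontiguousarray(np.moveaxis(gx, -1, 1), dtype=np.float32)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = Param(he_init(rng, (out_dim, in_dim), in_dim), "linear.weight")
        self.bias = Param(np.zeros(out_dim, dtype=np.float32), "linear.bias") if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_dim:
            raise ValueError(f"expected input dim {self.in_dim}, got {x.shape[1]}")
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        gx = grad @ self.weight.data
        self._x = None
        return gx.astype(np.float32)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Needs an rng per construction."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        g = (grad * self._mask).astype(np.float32)
        self._mask = None
        return g


class Sequential(Module):
    def __init__(self, *mods: Module) -> None:
        self.mods = list(mods)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.mods:
            x = m.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.mods):
            grad = m.backward(grad)
        return grad


class Add(Module):
    """Elementwise sum of two branches' outputs; backward fans the grad out."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:  # type: ignore[override]
        return a + b

    def backward(self, grad: np.ndarray):  # type: ignore[override]
        return grad, grad
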