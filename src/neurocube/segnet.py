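"""The improved 3D U-Net for multi-class ROI segmentation.

Architecture
------------
A four-level encoder-decoder (the fourth level is the bottleneck).  Level 1
opens with a 1x1x1 stem convolution to 16 channels followed by a
*recombination block* to 32 channels; levels are joined by 2x max pooling on
the way down and stride-2 transposed convolution on the way up.  Besides the
usual per-resolution skip connections (element-wise addition after a 1x1x1
projection), an extra bottleneck skip at 1/4 resolution projects the
64-channel encoder tensor to 96 channels with a 1x1x1 convolution and adds it
to the matching decoder tensor.  A 1x1x1 head with voxelwise softmax produces
the class probabilities; training minimizes soft Dice loss over the
foreground classes.

The recombination block is a residual unit: 1x1x1 expansion from C to 4C,
3x3x3 convolution + batch norm, ReLU, SegS-E attention, 1x1x1 reduction to
C', added to a 1x1x1 shortcut projection of the input (so gradients reach the
stem through the shortcut even when the residual path is zero).

The SegS-E block is a squeeze-and-excitation-style gate: a depthwise 3x3x3
dilated convolution (rate 2, one kernel per channel) followed by a 1x1x1
channel-mixing convolution produces a weight map W with the input's shape,
which multiplies the input element-wise (Hadamard product).  The weight map
is linear by default; an optional sigmoid squashing is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    DepthwiseConv3d,
    MaxPool3d,
    Module,
    ReLU,
    Sigmoid,
    new_rng,
    softmax,
)
from .nn.losses import one_hot, soft_dice, softmax_dice_loss

__all__ = ["SegNetConfig", "SegSEBlock", "RecombinationBlock", "SegNet",
           "build_segnet", "dice_loss", "softmax_dice_loss"]


@dataclass
class SegNetConfig:
    in_channels: int = 1
    n_classes: int = 6
    levels: int = 4
    stem_channels: int = 16
    channel_schedule: tuple[int, ...] = (32, 64, 96, 128)
    expansion: int = 4
    dilation_rate: int = 2
    se_gate: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if len(self.channel_schedule) != self.levels:
            raise ValueError("channel_schedule length must equal levels")
        if self.expansion < 1 or self.stem_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid channel/class configuration")
        if any(c < 1 for c in self.channel_schedule):
            raise ValueError("channel counts must be positive")
        if self.se_gate not in ("linear", "sigmoid"):
            raise ValueError("se_gate must be 'linear' or 'sigmoid'")


class SegSEBlock(Module):
    """Spatial squeeze-and-excitation: X~ = W (.) X with W from a dilated
    depthwise + pointwise convolution of X."""

    def __init__(self, ch: int, dilation: int = 2, gate: str = "linear",
                 rng: np.random.Generator | None = None) -> None:
        self.ch = ch
        self.dilated = DepthwiseConv3d(ch, k=3, dilation=dilation, rng=rng)
        self.pointwise = Conv3d(ch, ch, k=1, rng=rng)
        # start the gate at identity (W ~ 1) so the residual path and its
        # gradient are not suppressed by a zero-mean weight map at init
        if self.pointwise.bias is not None and gate == "linear":
            self.pointwise.bias.data[...] = 1.0
        self.gate = Sigmoid() if gate == "sigmoid" else None
        self._x = None
        self._w = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.ch:
            raise ValueError(f"expected {self.ch} channels, got {x.shape[1]}")
        w = self.pointwise(self.dilated(x))
        if self.gate is not None:
            w = self.gate(w)
        self._x, self._w = x, w
        return (w * x).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, w = self._x, self._w
        self._x = self._w = None
        gw = grad * x
        gx_direct = grad * w
        if self.gate is not None:
            gw = self.gate.backward(gw)
        gx_branch = self.dilated.backward(self.pointwise.backward(gw))
        return (gx_direct + gx_branch).astype(np.float32)


class RecombinationBlock(Module):
    """Residual unit: [1x1x1 -> 4C] -> [3x3x3 + BN] -> ReLU -> SegS-E ->
    [1x1x1 -> C'] plus a 1x1x1 shortcut projection of the input."""

    def __init__(self, in_ch: int, out_ch: int, expansion: int = 4,
                 dilation: int = 2, gate: str = "linear",
                 rng: np.random.Generator | None = None) -> None:
        mid = in_ch * expansion
        self.expand = Conv3d(in_ch, mid, k=1, rng=rng)
        self.conv = Conv3d(mid, mid, k=3, rng=rng)
        self.bn = BatchNorm3d(mid)
        self.act = ReLU()
        self.se = SegSEBlock(mid, dilation=dilation, gate=gate, rng=rng)
        self.reduce = Conv3d(mid, out_ch, k=1, rng=rng)
        self.shortcut = Conv3d(in_ch, out_ch, k=1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = self.reduce(self.se(self.act(self.bn(self.conv(self.expand(x))))))
        return b + self.shortcut(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g_res = self.expand.backward(self.conv.backward(self.bn.backward(
            self.act.backward(self.se.backward(self.reduce.backward(grad))))))
        g_short = self.shortcut.backward(grad)
        return g_res + g_short


class SegNet(Module):
    """Encoder-decoder built from recombination blocks; see module docstring."""

    def __init__(self, cfg: SegNetConfig) -> None:
        self.cfg = cfg
        rng = new_rng(cfg.seed)
        L = cfg.levels
        ch = cfg.channel_schedule
        kw = dict(expansion=cfg.expansion, dilation=cfg.dilation_rate,
                  gate=cfg.se_gate, rng=rng)
        self.stem = Conv3d(cfg.in_channels, cfg.stem_channels, k=1, rng=rng)
        self.enc = [RecombinationBlock(cfg.stem_channels if i == 0 else ch[i - 1],
                                       ch[i], **kw) for i in range(L)]
        self.pools = [MaxPool3d() for _ in range(L - 1)]
        self.ups = [ConvTranspose3d(ch[i + 1], ch[i], rng=rng) for i in range(L - 1)]
        self.skip_proj = [Conv3d(ch[i], ch[i], k=1, rng=rng) for i in range(L - 1)]
        self.dec = [RecombinationBlock(ch[i], ch[i], **kw) for i in range(L - 1)]
        # bottleneck skip: the encoder tensor entering level L-2 (at 1/2^(L-2)
        # resolution) projected up to that level's channel count
        self.bproj = Conv3d(ch[L - 3], ch[L - 2], k=1, rng=rng) if L >= 3 else None
        self.head = Conv3d(ch[0], cfg.n_classes, k=1, rng=rng)
        self._cache: dict = {}

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, n_classes, D, H, W); spatial shape preserved."""
        L = self.cfg.levels
        div = 2 ** (L - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {div}")
        c = self._cache = {}
        cur = self.stem(x)
        enc_out = []
        for i in range(L):
            if i > 0:
                cur = self.pools[i - 1](cur)
                if self.bproj is not None and i == L - 2:
                    c["p_pre"] = cur
            cur = self.enc[i](cur)
            enc_out.append(cur)
        c["enc_out"] = enc_out
        for j in range(L - 1, 0, -1):
            cur = self.ups[j - 1](cur)
            cur = cur + self.skip_proj[j - 1](enc_out[j - 1])
            if self.bproj is not None and j - 1 == L - 2:
                cur = cur + self.bproj(c["p_pre"])
            cur = self.dec[j - 1](cur)
        return self.head(cur)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        L = self.cfg.levels
        g = self.head.backward(dlogits)
        g_skip: list[np.ndarray | None] = [None] * L
        g_ppre = None
        for j in range(1, L):
            g = self.dec[j - 1].backward(g)
            g_skip[j - 1] = self.skip_proj[j - 1].backward(g)
            if self.bproj is not None and j - 1 == L - 2:
                g_ppre = self.bproj.backward(g)
            g = self.ups[j - 1].backward(g)
        for i in range(L - 1, -1, -1):
            if g_skip[i] is not None:
                g = g + g_skip[i]
            g = self.enc[i].backward(g)
            if i > 0:
                if g_ppre is not None and i == L - 2:
                    g = g + g_ppre
                g = self.pools[i - 1].backward(g)
        self._cache = {}
        return self.stem.backward(g)

    # -- inference ---------------------------------------------------------
    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Voxelwise class probabilities (softmax over the class axis)."""
        return softmax(self.forward(x))


def build_segnet(cfg: SegNetConfig) -> SegNet:
    return SegNet(cfg)


def dice_loss(pred_probs: np.ndarray, target_labels: np.ndarray,
              n_classes: int, eps: float = 1e-5) -> float:
    """1 - mean soft Dice over foreground classes, from probabilities.

    ``pred_probs``: (N, K, D, H, W) voxelwise-normalized; ``target_labels``:
    (N, D, H, W) integers.  Zero for one-hot predictions equal to the target,
    approximately one for fully disjoint one-hot predictions.
    """
    if pred_probs.shape[1] != n_classes:
        raise ValueError("n_classes does not match probability channels")
    if pred_probs.shape[0] != target_labels.shape[0] or \
            pred_probs.shape[2:] != target_labels.shape[1:]:
        raise ValueError("prediction/target shape mismatch")
    d = soft_dice(pred_probs.astype(np.float32), one_hot(target_labels, n_classes),
                  eps=eps)
    return 1.0 - float(d.mean())


def make_optimizer(model: SegNet, lr: float = 1e-3) -> Adam:
    return Adam(model.params(), lr=lr)
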