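"""Squeeze-and-excitation channel attention and the ResNet34 encoder.

The SE block compresses each channel of a feature map U (C x H x W) to a
scalar by global average pooling (squeeze), passes the C-vector through a
two-layer bottleneck W2 * relu(W1 * z) with reduction ratio r and a final
sigmoid (excitation), and rescales every channel of U by its weight
s_c in (0, 1). Embedded in a ResNet basic block it sits on the residual
branch, before the shortcut addition.

The encoder is ResNet34 with SE in every basic block (toggleable for the
plain-UNet ablation); it exposes the five downsampling taps at scales
1/2, 1/4, 1/8, 1/16, 1/32 with channel widths 64, 64, 128, 256, 512.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


class ShapeError(ValueError):
    pass


# ---------------------------------------------------------- SE primitives

def squeeze(u) -> np.ndarray:
    """Global average pool: z_c = mean over the spatial grid, per channel.

    Accepts a (C,H,W) array (single map) or (N,C,H,W) batch; returns
    (C,) or (N,C) respectively.
    """
    u = u.data if isinstance(u, Tensor) else np.asarray(u, dtype=np.float64)
    if u.ndim == 3:
        return u.mean(axis=(1, 2))
    if u.ndim == 4:
        return u.mean(axis=(2, 3))
    raise ShapeError("squeeze expects (C,H,W) or (N,C,H,W)")


def excitation(z: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Channel weights s = sigmoid(W2 @ relu(W1 @ z)), each in (0, 1).

    W1 is (C/r, C) and W2 is (C, C/r) for reduction ratio r.
    """
    z = np.asarray(z, dtype=np.float64)
    w1 = np.asarray(w1, dtype=np.float64)
    w2 = np.asarray(w2, dtype=np.float64)
    c = z.shape[-1]
    if w1.shape[1] != c or w2.shape[0] != c or w1.shape[0] != w2.shape[1]:
        raise ShapeError(
            f"excitation shape mismatch: z has C={c}, W1 {w1.shape}, W2 {w2.shape}")
    h = np.maximum(z @ w1.T, 0.0)
    return 1.0 / (1.0 + np.exp(-(h @ w2.T)))


def rescale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-channel recalibration x~_c = s_c * U_c; shape-preserving."""
    u = np.asarray(u, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if u.ndim == 3:
        if s.shape != (u.shape[0],):
            raise ShapeError("channel weight length must equal C")
        return u * s[:, None, None]
    if s.shape != u.shape[:2]:
        raise ShapeError("channel weights must be (N, C)")
    return u * s[:, :, None, None]


# ------------------------------------------------------------- NN modules

class SEModule(nn.Module):
    """Squeeze-excitation-rescale as a differentiable module."""

    def __init__(self, channels, reduction=16, rng=None):
        super().__init__()
        if channels % reduction != 0:
            raise ShapeError(
                f"channels ({channels}) must be divisible by reduction ({reduction})")
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)

    def forward(self, x):
        z = nn.global_avg_pool(x)
        s = nn.sigmoid(self.fc2(nn.relu(self.fc1(z))))
        return nn.channel_scale(x, s)


class SEBasicBlock(nn.Module):
    """ResNet basic block (3x3 conv-bn-relu-3x3 conv-bn) with optional SE
    on the residual branch before the shortcut addition."""

    def __init__(self, in_ch, out_ch, stride=1, use_se=True, reduction=16, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.use_se = use_se
        if use_se:
            self.se = SEModule(out_ch, reduction, rng=rng)
        self.has_projection = stride != 1 or in_ch != out_ch
        if self.has_projection:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        self.in_ch = in_ch

    def forward(self, x):
        if x.shape[1] != self.in_ch:
            raise ShapeError(
                f"block expects {self.in_ch} input channels, got {x.shape[1]}")
        f = self.bn2(self.conv2(nn.relu(self.bn1(self.conv1(x)))))
        if self.use_se:
            f = self.se(f)
        short = self.proj_bn(self.proj(x)) if self.has_projection else x
        return nn.relu(nn.add(f, short))


# ResNet34 stage plan: (blocks, channels) after the stem
_RESNET34_STAGES = [(3, 64), (4, 128), (6, 256), (3, 512)]


class ResNet34Encoder(nn.Module):
    """ResNet34 backbone exposing five downsampling taps.

    Tap schedule: post-stem (/2, 64ch), layer1 after 3x3/2 maxpool
    (/4, 64ch), layer2 (/8, 128ch), layer3 (/16, 256ch), layer4
    (/32, 512ch). SE is embedded in every basic block when use_se is on;
    switching it off yields the plain ResNet34 ablation without changing
    any tap shape.
    """

    tap_channels = (64, 64, 128, 256, 512)
    tap_scales = (2, 4, 8, 16, 32)

    def __init__(self, use_se=True, se_reduction=16, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(64)
        in_ch = 64
        for li, (blocks, ch) in enumerate(_RESNET34_STAGES, start=1):
            stride = 1 if li == 1 else 2
            mods = []
            for bi in range(blocks):
                mods.append(SEBasicBlock(in_ch, ch, stride=stride if bi == 0 else 1,
                                         use_se=use_se, reduction=se_reduction, rng=rng))
                in_ch = ch
            setattr(self, f"layer{li}", nn.Sequential(*mods))
        self.use_se = use_se

    def forward(self, x):
        """x: (N,3,H,W) with H, W divisible by 32 -> list of 5 tap Tensors."""
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ShapeError(f"input size {h}x{w} must be divisible by 32")
        t1 = nn.relu(self.stem_bn(self.stem_conv(x)))          # /2, 64
        p = nn.maxpool2d(t1, kernel=3, stride=2, pad=1)        # /4
        t2 = self.layer1(p)                                    # /4, 64
        t3 = self.layer2(t2)                                   # /8, 128
        t4 = self.layer3(t3)                                   # /16, 256
        t5 = self.layer4(t4)                                   # /32, 512
        return [t1, t2, t3, t4, t5]
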