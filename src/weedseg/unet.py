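"""Improved UNet: ResNet34-backboned encoder-decoder with optional SE
attention and shallow-feature fusion.

The decoder performs four transposed-convolution upsamplings, each
concatenated with the matching encoder tap (classic UNet skips), then a
fifth upsampling to full resolution. With fusion enabled, every encoder
tap is additionally compressed by a 1x1 convolution and restored to full
resolution by a chain of 2x2 stride-2 transposed convolutions; the five
restored maps are concatenated with the decoder output before the final
1x1 classifier. The network predicts K = 3 classes (background, soybean,
grass); broadleaf weeds are recovered downstream by morphology.

The four ablation configurations are spanned by ``use_se`` x
``enable_fusion``: plain ResNet34-UNet, +SE, +fusion structure, or both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import ResNet34Encoder, ShapeError
from .nn import Tensor

N_CLASSES = 3


@dataclass
class FusionConfig:
    enable_fusion: bool = True
    fusion_channels: int = 16  # per-tap width after the 1x1 compression

    def __post_init__(self):
        if self.fusion_channels < 1:
            raise ValueError("fusion_channels must be >= 1")


class RestoreTap(nn.Module):
    """Restore a tap at scale 1/s to full resolution with log2(s) chained
    2x2 stride-2 transposed convolutions."""

    def __init__(self, channels, scale, rng=None):
        super().__init__()
        if scale < 2 or scale & (scale - 1):
            raise ShapeError(f"scale must be a power of two >= 2, got {scale}")
        self.scale = scale
        steps = scale.bit_length() - 1
        self.chain = nn.Sequential(
            *[nn.ConvTranspose2d(channels, channels, 2, rng=rng) for _ in range(steps)])

    def forward(self, x, full_size=None):
        out = self.chain(x)
        if full_size is not None and out.shape[2:] != tuple(full_size):
            raise ShapeError(
                f"restored size {out.shape[2:]} != expected {tuple(full_size)}")
        return out


class Reduce1x1(nn.Module):
    """Pointwise (1x1) convolution: per-pixel linear map of the channels."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 1, bias=True, rng=rng)

    def forward(self, x):
        return self.conv(x)


class _DecoderStage(nn.Module):
    """Transposed-conv upsample, concat the skip tap, two 3x3 conv-bn-relu."""

    def __init__(self, in_ch, skip_ch, out_ch, rng=None):
        super().__init__()
        self.up = nn.ConvTranspose2d(in_ch, out_ch, 2, rng=rng)
        self.conv1 = nn.Conv2d(out_ch + skip_ch, out_ch, 3, pad=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x, skip):
        x = self.up(x)
        x = nn.concat([x, skip], axis=1)
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


class ImprovedUNet(nn.Module):
    """SE-ResNet34 UNet with five-tap shallow-feature fusion.

    Parameters
    ----------
    use_se : embed squeeze-excitation in every encoder basic block.
    enable_fusion : concatenate the five restored shallow taps into the
        final prediction map.
    se_reduction : SE bottleneck reduction ratio r.
    fusion_channels : per-tap channel width after 1x1 compression.
    seed : weight initialization seed.
    """

    def __init__(self, use_se=True, enable_fusion=True, se_reduction=16,
                 fusion_channels=16, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.encoder = ResNet34Encoder(use_se=use_se, se_reduction=se_reduction, rng=rng)
        taps = ResNet34Encoder.tap_channels          # (64, 64, 128, 256, 512)
        # decoder widths mirror classic UNet halving: 512->256->128->64->64
        self.dec4 = _DecoderStage(512, taps[3], 256, rng=rng)
        self.dec3 = _DecoderStage(256, taps[2], 128, rng=rng)
        self.dec2 = _DecoderStage(128, taps[1], 64, rng=rng)
        self.dec1 = _DecoderStage(64, taps[0], 64, rng=rng)
        self.final_up = nn.ConvTranspose2d(64, 64, 2, rng=rng)
        self.final_bn = nn.BatchNorm2d(64)
        self.config = FusionConfig(enable_fusion, fusion_channels)
        self.use_se = use_se
        self.se_reduction = se_reduction
        head_ch = 64
        if enable_fusion:
            for i, (ch, scale) in enumerate(zip(taps, ResNet34Encoder.tap_scales)):
                setattr(self, f"reduce{i}", Reduce1x1(ch, fusion_channels, rng=rng))
                setattr(self, f"restore{i}", RestoreTap(fusion_channels, scale, rng=rng))
            head_ch += 5 * fusion_channels
        self.classifier = nn.Conv2d(head_ch, N_CLASSES, 1, bias=True, rng=rng)

    def encoder_parameters(self):
        return list(self.encoder.parameters())

    def decoder_parameters(self):
        enc = {id(p) for p in self.encoder.parameters()}
        return [p for p in self.parameters() if id(p) not in enc]

    def forward(self, x) -> Tensor:
        """(N,3,H,W) float in [0,1] -> (N,3,H,W) class logits."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ShapeError(f"input size {h}x{w} must be divisible by 32")
        t1, t2, t3, t4, t5 = self.encoder(x)
        d = self.dec4(t5, t4)          # /16
        d = self.dec3(d, t3)           # /8
        d = self.dec2(d, t2)           # /4
        d = self.dec1(d, t1)           # /2
        d = nn.relu(self.final_bn(self.final_up(d)))   # /1
        if self.config.enable_fusion:
            taps = [t1, t2, t3, t4, t5]
            restored = [getattr(self, f"restore{i}")(
                getattr(self, f"reduce{i}")(t), full_size=(h, w))
                for i, t in enumerate(taps)]
            d = nn.concat([d] + restored, axis=1)
        return self.classifier(d)


def save_checkpoint(model: ImprovedUNet, path):
    """Serialize weights + architecture flags to a numpy .npz archive."""
    meta = dict(use_se=int(model.use_se),
                enable_fusion=int(model.config.enable_fusion),
                fusion_channels=model.config.fusion_channels,
                se_reduction=model.se_reduction)
    arrays = {f"meta_{k}": np.asarray(v) for k, v in meta.items()}
    arrays.update({f"state {k}": v for k, v in model.state_dict().items()})
    np.savez(path, **arrays)


def load_checkpoint(path) -> ImprovedUNet:
    with np.load(path) as z:
        model = ImprovedUNet(use_se=bool(z["meta_use_se"]),
                             enable_fusion=bool(z["meta_enable_fusion"]),
                             fusion_channels=int(z["meta_fusion_channels"]),
                             se_reduction=int(z["meta_se_reduction"]))
        state = {k[len("state "):]: z[k] for k in z.files if k.startswith("state ")}
    model.load_state_dict(state)
    return model


def predict_mask(logits) -> np.ndarray:
    """Per-pixel argmax over the K=3 class channels; ties go to the
    lowest class index (numpy argmax convention).

    Accepts (K,H,W) or (N,K,H,W); returns (H,W) or (N,H,W) int masks.
    """
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    if arr.ndim == 3:
        return arr.argmax(axis=0)
    return arr.argmax(axis=1)


def forward_image(model: ImprovedUNet, img: np.ndarray) -> np.ndarray:
    """Run one H x W x 3 uint8 image through the net; returns (3,H,W) logits."""
    x = np.asarray(img, dtype=np.float32).transpose(2, 0, 1)[None] / 255.0
    model.eval()
    with nn.no_grad():
        out = model(Tensor(x))
    return out.data[0]


def segment_image(model: ImprovedUNet, img: np.ndarray) -> np.ndarray:
    """Predict an H x W class mask (values in {0,1,2}) for one image."""
    return predict_mask(forward_image(model, img))
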