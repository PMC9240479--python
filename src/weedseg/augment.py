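"""Dataset expansion and training-time augmentation.

Two regimes:

* **Offline expansion** multiplies the captured set before splitting
  (700 source scenes -> 4200 with the default five variants per image).
  Variants use exact right-angle rotations and flips — bit-invertible on
  the label mask — plus photometric jitter that touches only the image.
* **Online transforms** run per sample during training: random square
  crop, arbitrary-angle rotation, optional Gaussian blur (image only),
  per-channel additive shift (image only), then resize to the network
  input size (512 x 512 by default). Masks always travel through the
  identical geometric chain with nearest-neighbor interpolation so no
  interpolated pseudo-labels appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize


class AugmentError(ValueError):
    pass


@dataclass
class AugmentPolicy:
    """Offline variant count and online transform parameter ranges."""

    offline_variants_per_image: int = 5
    crop_range: tuple = (0.6, 1.0)      # fraction of the short side
    rotation_range: tuple = (-30.0, 30.0)  # degrees
    blur_kernels: tuple = (0, 3, 5)     # 0 = no blur; odd Gaussian kernels
    channel_shift: int = 20             # max |additive shift| per RGB channel
    target_size: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.offline_variants_per_image < 0:
            raise AugmentError("variants must be >= 0")
        if not (0 < self.crop_range[0] <= self.crop_range[1] <= 1):
            raise AugmentError("crop fractions must satisfy 0 < lo <= hi <= 1")
        if any(k % 2 == 0 and k != 0 for k in self.blur_kernels):
            raise AugmentError("blur kernels must be odd (or 0 for none)")


# Exact, invertible geometric ops used by the offline expansion.
GEOMETRIC_OPS = {
    "rot90": lambda a: np.rot90(a, 1).copy(),
    "rot180": lambda a: np.rot90(a, 2).copy(),
    "rot270": lambda a: np.rot90(a, 3).copy(),
    "fliplr": lambda a: np.fliplr(a).copy(),
    "flipud": lambda a: np.flipud(a).copy(),
}
INVERSE_OPS = {
    "rot90": "rot270", "rot180": "rot180", "rot270": "rot90",
    "fliplr": "fliplr", "flipud": "flipud",
}


def _jitter(img, rng, policy):
    shift = rng.integers(-policy.channel_shift, policy.channel_shift + 1, size=3)
    return np.clip(img.astype(np.int32) + shift[None, None], 0, 255).astype(np.uint8)


def expand_offline(pairs, policy: AugmentPolicy = AugmentPolicy()):
    """Expand (image, mask) pairs: originals plus N variants each.

    Returns (expanded pairs, records): record i names the source index
    and geometric op of each output, so image/mask alignment can be
    re-checked by replaying the op on the mask alone.
    """
    rng = np.random.default_rng(policy.seed)
    op_names = list(GEOMETRIC_OPS)
    out, records = [], []
    for si, pair in enumerate(pairs):
        if len(pair) != 2:
            raise AugmentError(f"entry {si} is not an (image, mask) pair")
        img, mask = pair
        img, mask = np.asarray(img), np.asarray(mask)
        if img.shape[:2] != mask.shape:
            raise AugmentError(
                f"pair {si}: image {img.shape[:2]} vs mask {mask.shape} size mismatch")
        out.append((img, mask))
        records.append({"source": si, "op": None})
        for k in range(policy.offline_variants_per_image):
            name = op_names[k % len(op_names)]
            op = GEOMETRIC_OPS[name]
            v_img = _jitter(op(img), rng, policy)
            out.append((v_img, op(mask)))
            records.append({"source": si, "op": name})
    return out, records


def _square_crop(img, mask, rng, policy):
    h, w = mask.shape
    short = min(h, w)
    frac = rng.uniform(*policy.crop_range)
    side = max(8, int(round(frac * short)))
    if side > short:
        side = short
    y0 = int(rng.integers(0, h - side + 1))
    x0 = int(rng.integers(0, w - side + 1))
    return img[y0:y0 + side, x0:x0 + side], mask[y0:y0 + side, x0:x0 + side]


def online_transform(pair, policy: AugmentPolicy = AugmentPolicy(), rng=None):
    """One randomized training sample at target_size x target_size.

    Chain: random square crop -> random rotation (corners filled with
    black / background) -> optional Gaussian blur (image only) ->
    per-channel shift (image only) -> resize (bilinear image,
    nearest-neighbor mask). Deterministic for a given Generator state.
    """
    rng = np.random.default_rng(policy.seed) if rng is None else rng
    img, mask = np.asarray(pair[0]), np.asarray(pair[1])
    if img.shape[:2] != mask.shape:
        raise AugmentError("image/mask size mismatch")

    img, mask = _square_crop(img, mask, rng, policy)

    angle = float(rng.uniform(*policy.rotation_range))
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, cval=0.0)
        img = np.clip(img, 0, 255).astype(np.uint8)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, cval=0)

    kernel = int(policy.blur_kernels[rng.integers(0, len(policy.blur_kernels))])
    if kernel > 0:
        img = ndimage.gaussian_filter(
            img.astype(np.float32), sigma=(kernel / 3.0, kernel / 3.0, 0.0))
        img = np.clip(img, 0, 255).astype(np.uint8)

    if policy.channel_shift > 0:
        img = _jitter(img, rng, policy)

    t = policy.target_size
    if img.shape[:2] != (t, t):
        img = resize(img, (t, t), order=1, preserve_range=True,
                     anti_aliasing=False).astype(np.uint8)
        mask = resize(mask, (t, t), order=0, preserve_range=True,
                      anti_aliasing=False).astype(mask.dtype)
    return img, mask


def identity_policy(target_size: int = 512, seed: int = 0) -> AugmentPolicy:
    """Degenerate ranges: online_transform only resizes to the target."""
    return AugmentPolicy(crop_range=(1.0, 1.0), rotation_range=(0.0, 0.0),
                         blur_kernels=(0,), channel_shift=0,
                         target_size=target_size, seed=seed)
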