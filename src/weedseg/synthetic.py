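"""Synthetic soybean-field scene generator with pixel-exact ground truth.

Emulates the three plant morphologies seen in row-crop field imagery:

* soybean — clusters of 2-3 broad elliptical leaflets (trifoliolate habit),
* grass weeds — thin elongated curved blades (bounding-box aspect >= 5),
* broadleaf weeds — single large rounded leaves,

over a brownish soil background with Gaussian texture noise and a few
gray stone ellipses. Every painted pixel is recorded in a four-class
ground-truth mask (overlap priority grass > soybean > broadleaf), so the
vegetation, segmentation, metric, and broadleaf-extraction stages can all
be validated without field data. Scenes are deterministic in their seed.

The generator does not model lighting, perspective, growth stages, or
leaf venation; plants are flat painted shapes. Conclusions drawn from it
concern pipeline correctness, not field-scale accuracy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np

BACKGROUND, SOYBEAN, GRASS, BROADLEAF = 0, 1, 2, 3


class SceneError(RuntimeError):
    pass


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field scene.

    ``green_range`` keeps plant green channels well above the soil green
    level so the excess-green index separates vegetation from soil; the
    margin is part of the study conditions, not a tuning knob.
    """

    size: int = 256
    n_soybean: int = 3
    n_grass: int = 3
    n_broadleaf: int = 2
    soil_color: tuple = (120, 90, 60)
    soil_noise: float = 12.0
    green_range: tuple = (130, 210)
    occlusion_prob: float = 0.2
    n_stones: int = 3
    plant_scale: float | None = None  # None: plants scale with size/256
    seed: int = 0

    def __post_init__(self):
        if self.size < 64:
            raise ValueError("scene size must be >= 64")
        if min(self.n_soybean, self.n_grass, self.n_broadleaf) < 0:
            raise ValueError("plant counts must be >= 0")
        if self.green_range[0] <= self.soil_color[1] + 3 * self.soil_noise:
            raise ValueError("plant green range must sit above soil green + noise")


def _ellipse_pixels(size, cy, cx, ry, rx, angle):
    """Integer pixel coordinates inside a rotated ellipse, clipped to the scene."""
    r = int(np.ceil(max(ry, rx))) + 1
    ys, xs = np.mgrid[-r:r + 1, -r:r + 1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * xs + sa * ys
    v = -sa * xs + ca * ys
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    yy = ys[inside] + int(round(cy))
    xx = xs[inside] + int(round(cx))
    keep = (yy >= 0) & (yy < size) & (xx >= 0) & (xx < size)
    return yy[keep], xx[keep]


def _paint(img, owner, yy, xx, color, cls, priority):
    """Paint pixels, respecting class priority grass > soybean > broadleaf > bg."""
    cur = owner[yy, xx]
    win = priority[cls] > np.array([priority[c] for c in cur])
    yy, xx = yy[win], xx[win]
    img[yy, xx] = color
    owner[yy, xx] = cls


_PRIORITY = {BACKGROUND: 0, BROADLEAF: 1, SOYBEAN: 2, GRASS: 3}


def _green(rng, spec):
    g = rng.integers(spec.green_range[0], spec.green_range[1] + 1)
    return np.array([rng.integers(20, 70), g, rng.integers(20, 70)], dtype=np.uint8)


def _scale(spec):
    return spec.plant_scale if spec.plant_scale is not None else spec.size / 256.0


def _draw_soybean(img, owner, rng, spec, cy, cx):
    """2-3 broad elliptical leaflets fanned around a node."""
    n_leaf = int(rng.integers(2, 4))
    base = rng.uniform(0, 2 * np.pi)
    scale = _scale(spec)
    for k in range(n_leaf):
        ang = base + k * (2 * np.pi / n_leaf) + rng.uniform(-0.3, 0.3)
        ry = rng.uniform(10, 16) * scale
        rx = ry * rng.uniform(0.55, 0.75)          # broad, mildly oblong
        off = ry * 0.9
        yy, xx = _ellipse_pixels(spec.size, cy + off * np.sin(ang),
                                 cx + off * np.cos(ang), ry, rx, ang + np.pi / 2)
        _paint(img, owner, yy, xx, _green(rng, spec), SOYBEAN, _PRIORITY)


def _draw_grass(img, owner, rng, spec, cy, cx):
    """A thin curved blade: chain of small disks along an arc (aspect >= 5)."""
    scale = _scale(spec)
    length = rng.uniform(45, 75) * scale
    width = max(1.0, length / rng.uniform(14.0, 20.0))  # enforces elongation
    ang = rng.uniform(0, 2 * np.pi)
    for _ in range(20):  # keep the whole blade in frame (no stubby clipped blades)
        ey, ex = cy + length * np.sin(ang), cx + length * np.cos(ang)
        if 2 <= ey < spec.size - 2 and 2 <= ex < spec.size - 2:
            break
        ang = rng.uniform(0, 2 * np.pi)
    curv = rng.uniform(-0.005, 0.005)                   # gentle bow, no hooks
    color = _green(rng, spec)
    steps = max(int(length), 8)
    for t in np.linspace(0, length, steps):
        a = ang + curv * t
        y = cy + t * np.sin(a)
        x = cx + t * np.cos(a)
        r = width * (1.0 - 0.5 * t / length)            # tapered tip
        yy, xx = _ellipse_pixels(spec.size, y, x, max(r, 0.8), max(r, 0.8), 0.0)
        _paint(img, owner, yy, xx, color, GRASS, _PRIORITY)


def _draw_broadleaf(img, owner, rng, spec, cy, cx):
    """One large rounded leaf: near-circular ellipse."""
    scale = _scale(spec)
    ry = rng.uniform(16, 24) * scale
    rx = ry * rng.uniform(0.85, 1.0)
    yy, xx = _ellipse_pixels(spec.size, cy, cx, ry, rx, rng.uniform(0, np.pi))
    _paint(img, owner, yy, xx, _green(rng, spec), BROADLEAF, _PRIORITY)


def generate_scene(spec: SceneSpec):
    """Render one scene; returns (image H x W x 3 uint8, mask H x W int in {0..3}).

    Plant placement retries until the plant paints at least a few visible
    pixels; a full retry budget exhaustion raises :class:`SceneError`.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    img = np.empty((s, s, 3), dtype=np.uint8)
    base = np.array(spec.soil_color, dtype=np.float64)
    noise = rng.normal(0.0, spec.soil_noise, size=(s, s, 3))
    img[:] = np.clip(base[None, None] + noise, 0, 255).astype(np.uint8)
    owner = np.full((s, s), BACKGROUND, dtype=np.int64)

    for _ in range(spec.n_stones):
        cy, cx = rng.uniform(0, s, 2)
        ry = rng.uniform(3, 8) * s / 256.0
        yy, xx = _ellipse_pixels(s, cy, cx, ry, ry * rng.uniform(0.6, 1.0),
                                 rng.uniform(0, np.pi))
        gray = rng.integers(130, 180)
        img[yy, xx] = (gray, gray, gray)

    draw = {SOYBEAN: _draw_soybean, GRASS: _draw_grass, BROADLEAF: _draw_broadleaf}
    # broadleaf first so soybean/grass can occlude it (priority also enforces this)
    plan = ([BROADLEAF] * spec.n_broadleaf + [SOYBEAN] * spec.n_soybean
            + [GRASS] * spec.n_grass)
    margin = int(0.12 * s)
    for cls in plan:
        for attempt in range(50):
            cy = rng.uniform(margin, s - margin)
            cx = rng.uniform(margin, s - margin)
            if spec.occlusion_prob < rng.uniform() and attempt < 49:
                # keep some clearance from already-painted plants
                y0, x0 = int(cy), int(cx)
                if owner[max(y0 - 4, 0):y0 + 5, max(x0 - 4, 0):x0 + 5].any():
                    continue
            # draw on scratch copies; commit only if enough pixels landed
            img_try, owner_try = img.copy(), owner.copy()
            draw[cls](img_try, owner_try, rng, spec, cy, cx)
            if int((owner_try == cls).sum()) - int((owner == cls).sum()) >= 12:
                img, owner = img_try, owner_try
                break
        else:
            raise SceneError(f"could not place a class-{cls} plant in 50 attempts")
    return img, owner


def strip_broadleaf(mask: np.ndarray) -> np.ndarray:
    """Relabel broadleaf (3) to background (0): the network-facing labels.

    The segmentation network is trained on soybean and grass only;
    broadleaf weeds are deliberately unannotated and recovered later by
    morphological post-processing.
    """
    out = np.asarray(mask).copy()
    out[out == BROADLEAF] = BACKGROUND
    return out


def generate_dataset(spec: SceneSpec, n: int, seed: int | None = None):
    """Generate n scenes with per-scene derived seeds plus a manifest.

    Returns (pairs, manifest): pairs is a list of (image, mask); the
    manifest rows carry each scene's seed and per-class pixel tallies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.default_rng(spec.seed if seed is None else seed)
    scene_seeds = root.integers(0, 2 ** 31 - 1, size=n)
    pairs, manifest = [], []
    for i, s in enumerate(scene_seeds):
        sub = replace(spec, seed=int(s))
        img, mask = generate_scene(sub)
        pairs.append((img, mask))
        counts = np.bincount(mask.ravel(), minlength=4)
        manifest.append({
            "index": i, "seed": int(s),
            "background_px": int(counts[0]), "soybean_px": int(counts[1]),
            "grass_px": int(counts[2]), "broadleaf_px": int(counts[3]),
        })
    return pairs, manifest


def write_manifest(path, manifest):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
        writer.writeheader()
        writer.writerows(manifest)
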