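"""Image and label-mask I/O, polygon annotation import, dataset splitting.

Label masks travel as palette-encoded PNGs with four fixed classes:
background black [0,0,0], soybean green [0,128,0], grass weed red
[128,0,0], and broadleaf weed yellow [128,128,0]. The network itself
predicts only classes 0-2; broadleaf (3) appears in masks only after
morphological post-processing or in synthetic ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


class DataIOError(ValueError):
    """Raised for malformed masks, palettes, annotations, or splits."""


@dataclass(frozen=True)
class PaletteSpec:
    """Ordered class-name / class-index / RGB-triple table.

    The default palette is the four-class soybean-field convention;
    invariants (4 entries, indices 0..3, distinct colors) are enforced.
    """

    entries: tuple = (
        ("background", 0, (0, 0, 0)),
        ("soybean", 1, (0, 128, 0)),
        ("grass", 2, (128, 0, 0)),
        ("broadleaf", 3, (128, 128, 0)),
    )

    def __post_init__(self):
        if len(self.entries) != 4:
            raise DataIOError("palette must have exactly 4 entries")
        idxs = [e[1] for e in self.entries]
        if idxs != [0, 1, 2, 3]:
            raise DataIOError("palette class indices must be 0..3 in order")
        colors = [tuple(e[2]) for e in self.entries]
        if len(set(colors)) != len(colors):
            raise DataIOError("palette colors must be pairwise distinct")

    @property
    def names(self):
        return [e[0] for e in self.entries]

    @property
    def colors(self):
        return np.array([e[2] for e in self.entries], dtype=np.uint8)

    def index_of(self, name: str) -> int:
        for n, i, _ in self.entries:
            if n == name:
                return i
        raise DataIOError(f"unknown class name: {name!r}")


DEFAULT_PALETTE = PaletteSpec()


def encode_mask(mask: np.ndarray, palette: PaletteSpec = DEFAULT_PALETTE) -> np.ndarray:
    """Class-index mask (H,W) -> RGB uint8 image (H,W,3) via the palette."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DataIOError("mask must be 2-D")
    if mask.min(initial=0) < 0 or mask.max(initial=0) > 3:
        bad = np.unique(mask[(mask < 0) | (mask > 3)])
        raise DataIOError(f"mask contains values without palette entry: {bad.tolist()}")
    return palette.colors[mask.astype(np.intp)]


def decode_mask(img: np.ndarray, palette: PaletteSpec = DEFAULT_PALETTE) -> np.ndarray:
    """RGB image (H,W,3) -> class-index mask (H,W); exact inverse of encode_mask.

    Every pixel must match a palette color bit-exactly; the first offending
    coordinate is reported otherwise.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DataIOError("mask image must be H x W x 3")
    colors = palette.colors
    mask = np.full(img.shape[:2], -1, dtype=np.int64)
    for idx, color in enumerate(colors):
        mask[(img == color).all(axis=2)] = idx
    if (mask < 0).any():
        ys, xs = np.nonzero(mask < 0)
        y, x = int(ys[0]), int(xs[0])
        raise DataIOError(
            f"off-palette pixel {img[y, x].tolist()} at (row={y}, col={x})")
    return mask


def _points_in_polygon(rows, cols, poly):
    """Even-odd (ray casting) test; pixel centers at integer + 0.5.

    poly is a sequence of (x, y) vertices, x = column, y = row.
    """
    px = np.asarray(cols, dtype=np.float64) + 0.5
    py = np.asarray(rows, dtype=np.float64) + 0.5
    inside = np.zeros(px.shape, dtype=bool)
    pts = np.asarray(poly, dtype=np.float64)
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        crosses = ((y1 <= py) & (py < y2)) | ((y2 <= py) & (py < y1))
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xin)
    return inside


def import_polygons(annotation: dict, height: int, width: int,
                    palette: PaletteSpec = DEFAULT_PALETTE) -> np.ndarray:
    """Rasterize a labelme-style annotation document into a LabelMask.

    ``annotation["shapes"]`` is a list of ``{"label": name, "points": [[x,y],...]}``.
    Polygons are filled by the even-odd rule with pixel centers at
    integer + 0.5; later polygons overwrite earlier ones; unpainted
    pixels are background.
    """
    mask = np.zeros((height, width), dtype=np.int64)
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    for shape in annotation.get("shapes", []):
        label = shape["label"]
        idx = palette.index_of(label)  # raises DataIOError on unknown name
        pts = shape["points"]
        for x, y in pts:
            if not (0 <= x <= width and 0 <= y <= height):
                raise DataIOError(f"polygon point ({x}, {y}) out of bounds")
        inside = _points_in_polygon(rr.ravel(), cc.ravel(), pts).reshape(height, width)
        mask[inside] = idx
    return mask


def load_polygon_file(path, height, width, palette=DEFAULT_PALETTE):
    with open(path) as fh:
        return import_polygons(json.load(fh), height, width, palette)


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)


def split_dataset(ids, fractions=(6.0 / 7.0, 2.0 / 21.0, 1.0 / 21.0), seed=0) -> DatasetSplit:
    """Randomly partition sample ids into train/validation/test.

    Sizes are floor-allocated from the fractions with the remainder
    assigned to train; the default fractions reproduce the 3600/400/200
    partition of 4200 samples. Deterministic for a fixed seed.
    """
    ids = list(ids)
    if not ids:
        raise DataIOError("cannot split an empty id list")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise DataIOError("need three non-negative fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataIOError(f"fractions must sum to 1 (got {sum(fractions)})")
    n = len(ids)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
    )


# ------------------------------------------------------------- file I/O

def read_image(path) -> np.ndarray:
    """Read a PNG/JPG image as H x W x 3 uint8."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, img: np.ndarray):
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def read_mask(path, palette: PaletteSpec = DEFAULT_PALETTE) -> np.ndarray:
    """Read a palette or RGB PNG mask into a class-index array."""
    path = Path(path)
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        raise DataIOError("JPEG is refused for masks (lossy compression corrupts labels)")
    with Image.open(path) as im:
        if im.mode == "P":
            idx = np.asarray(im)
            if idx.max(initial=0) > 3:
                raise DataIOError("palette PNG contains class index > 3")
            return idx.astype(np.int64)
        return decode_mask(np.asarray(im.convert("RGB")), palette)


def write_mask(path, mask: np.ndarray, palette: PaletteSpec = DEFAULT_PALETTE):
    """Write a class-index mask as an indexed (palette) PNG, bit-exact colors."""
    path = Path(path)
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        raise DataIOError("JPEG is refused for masks (lossy compression corrupts labels)")
    mask = np.asarray(mask)
    if mask.min(initial=0) < 0 or mask.max(initial=0) > 3:
        raise DataIOError("mask contains values without palette entry")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    flat = palette.colors.ravel().tolist()
    im.putpalette(flat + [0] * (768 - len(flat)))
    im.save(path)
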