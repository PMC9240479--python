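"""Morphological broadleaf-weed extraction.

The segmentation network predicts only soybean and grass. Broadleaf
weeds are recovered by set algebra on binary masks: take the
excess-green vegetation mask, subtract the predicted soybean region and
the (dilated) predicted grass region, area-filter the remaining
connected components to kill speckle noise, and compose a final
four-class map where the survivors are labeled broadleaf ([128,128,0]).

Component analysis and dilation run on scipy.ndimage; tests check them
against an independent flood-fill oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import DEFAULT_PALETTE, PaletteSpec
from .synthetic import BACKGROUND, BROADLEAF, GRASS, SOYBEAN
from .vegetation import vegetation_mask


class BroadleafError(ValueError):
    pass


@dataclass(frozen=True)
class StructuringElement:
    """Square or disk footprint of odd size for morphological dilation."""

    shape: str = "square"
    size: int = 5

    def __post_init__(self):
        if self.shape not in ("square", "disk"):
            raise BroadleafError(f"unknown SE shape {self.shape!r}")
        if self.size < 1 or self.size % 2 == 0:
            raise BroadleafError("SE size must be odd and >= 1")

    def footprint(self) -> np.ndarray:
        if self.shape == "square":
            return np.ones((self.size, self.size), dtype=bool)
        r = self.size // 2
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        return yy * yy + xx * xx <= r * r


# 8-connectivity: diagonal leaf tips still count as one component
_CONN8 = np.ones((3, 3), dtype=int)


def dilate(mask: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Binary dilation; the input is always a subset of the output."""
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool),
                                   structure=se.footprint())


def remove_predicted(green: np.ndarray, soybean_pred: np.ndarray,
                     grass_pred_dilated: np.ndarray) -> np.ndarray:
    """green AND NOT (soybean OR dilated grass): the broadleaf candidates."""
    green = np.asarray(green, dtype=bool)
    soy = np.asarray(soybean_pred, dtype=bool)
    grass = np.asarray(grass_pred_dilated, dtype=bool)
    if not (green.shape == soy.shape == grass.shape):
        raise BroadleafError("mask size mismatch")
    return green & ~(soy | grass)


def filter_components(mask: np.ndarray, min_area: int = 64):
    """Erase 8-connected components smaller than min_area pixels.

    Returns (filtered mask, components) where components is a list of
    ``(component id, pixel count, (rows, cols))`` for the survivors.
    """
    if min_area < 0:
        raise BroadleafError("min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_CONN8)
    if n == 0:
        return mask.copy(), []
    counts = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = counts[1:] >= min_area
    out = keep[labels]
    components = []
    for cid in range(1, n + 1):
        if keep[cid]:
            coords = np.nonzero(labels == cid)
            components.append((cid, int(counts[cid]), coords))
    return out, components


def compose_final(soybean_pred: np.ndarray, grass_pred: np.ndarray,
                  broadleaf: np.ndarray,
                  palette: PaletteSpec = DEFAULT_PALETTE) -> np.ndarray:
    """Merge the three binary masks into one four-class LabelMask.

    Overlaps resolve by priority grass > soybean > broadleaf > background;
    the result encodes with the standard palette (broadleaf = [128,128,0]).
    """
    soy = np.asarray(soybean_pred, dtype=bool)
    grass = np.asarray(grass_pred, dtype=bool)
    broad = np.asarray(broadleaf, dtype=bool)
    if not (soy.shape == grass.shape == broad.shape):
        raise BroadleafError("mask size mismatch")
    out = np.full(soy.shape, BACKGROUND, dtype=np.int64)
    out[broad] = BROADLEAF
    out[soy] = SOYBEAN
    out[grass] = GRASS
    return out


def extract_broadleaf(img: np.ndarray, predicted_mask: np.ndarray,
                      se: StructuringElement = StructuringElement(),
                      min_area: int = 64) -> np.ndarray:
    """Full post-processing pipeline for one image.

    ``predicted_mask`` is the network's 3-class output (or any stand-in
    oracle with values in {0, 1, 2}). Steps: excess-green vegetation mask
    -> dilate the grass prediction -> remove predicted soybean + grass
    from the vegetation mask -> area-filter the remainder -> compose the
    final four-class map. Soybean predictions are not dilated.
    """
    predicted_mask = np.asarray(predicted_mask)
    green = vegetation_mask(img)
    soy = predicted_mask == SOYBEAN
    grass = predicted_mask == GRASS
    candidates = remove_predicted(green, soy, dilate(grass, se))
    broad, _ = filter_components(candidates, min_area)
    return compose_final(soy, grass, broad)
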