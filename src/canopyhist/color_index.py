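"""Per-pixel color indices of an RGB canopy image.

Six indices are supported, all arithmetic combinations of the 8-bit R, G, B
channel values cast to double precision:

========  =====================  ==================
name      formula                theoretical range
========  =====================  ==================
GR        G / R                  [0, 5] (clipped)
GB        G / B                  [0, 5] (clipped)
NRI       R / (R + G + B)        [0, 1]
NGI       G / (R + G + B)        [0, 1]
NBI       B / (R + G + B)        [0, 1]
GMRN      (G - R) / (R + G + B)  [-1, 1]
========  =====================  ==================

GR and GB are unbounded above; for histogramming they are assigned the
fixed range [0, 5] and out-of-range pixels are clipped into the end bins,
so that histogram bins stay comparable across samples.  Pixels whose
denominator is zero carry no defined index value and are masked invalid
rather than clamped; downstream statistics exclude them.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Tuple

import numpy as np

from .image_io import CanopyImage

logger = logging.getLogger(__name__)

INDEX_NAMES: Tuple[str, ...] = ("GR", "GB", "NRI", "NGI", "NBI", "GMRN")

#: Fixed value range used for histogramming each index.
THEORETICAL_RANGES: Dict[str, Tuple[float, float]] = {
    "GR": (0.0, 5.0),
    "GB": (0.0, 5.0),
    "NRI": (0.0, 1.0),
    "NGI": (0.0, 1.0),
    "NBI": (0.0, 1.0),
    "GMRN": (-1.0, 1.0),
}


@dataclasses.dataclass
class IndexRaster:
    """A real-valued raster for one color index plus its validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    index_name: str
    theoretical_range: Tuple[float, float]

    def valid_values(self) -> np.ndarray:
        """The defined index values as a flat array."""
        return self.values[self.valid_mask]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


def compute_index(image: CanopyImage, index_name: str) -> IndexRaster:
    """Compute one color-index raster from an RGB image.

    Pixels with a zero denominator (pure black for the sum-based indices,
    R=0 for GR, B=0 for GB) are masked invalid.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(
            f"unknown color index {index_name!r}; expected one of {INDEX_NAMES}"
        )
    px = image.pixels.astype(np.float64)
    r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]
    if index_name == "GR":
        num, den = g, r
    elif index_name == "GB":
        num, den = g, b
    else:
        s = r + g + b
        if index_name == "NRI":
            num, den = r, s
        elif index_name == "NGI":
            num, den = g, s
        elif index_name == "NBI":
            num, den = b, s
        else:  # GMRN
            num, den = g - r, s
    valid = den != 0.0
    values = np.full(den.shape, np.nan)
    np.divide(num, den, out=values, where=valid)
    masked_frac = 1.0 - valid.mean()
    if masked_frac > 0:
        logger.debug(
            "index %s on sample %s: %.3f%% of pixels masked (zero denominator)",
            index_name, image.sample_id, 100.0 * masked_frac,
        )
    return IndexRaster(
        values=values,
        valid_mask=valid,
        index_name=index_name,
        theoretical_range=THEORETICAL_RANGES[index_name],
    )


def compute_all_indices(image: CanopyImage) -> Dict[str, IndexRaster]:
    """All six color-index rasters, keyed by index name."""
    return {name: compute_index(image, name) for name in INDEX_NAMES}


def export_index_tiff(raster: IndexRaster, path) -> None:
    """Write an index raster as a single-band float TIFF for inspection."""
    import tifffile

    tifffile.imwrite(str(path), raster.values.astype(np.float32))
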