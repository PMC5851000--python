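"""Vegetation indices computed per pixel from multispectral reflectance.

Five indices of the normalized-difference family are supported:

====== ==========================================================
NDVI   (NIR - Red) / (NIR + Red)
GNDVI  (NIR - Green) / (NIR + Green)
RENDVI (NIR - RedEdge) / (NIR + RedEdge)
SAVI   (1 + L) (NIR - Red) / (NIR + Red + L)
EVI    G (NIR - Red) / (NIR + c1 Red - c2 Blue + L)
====== ==========================================================

Indices are evaluated element-wise on 2-D band rasters; pixels whose
denominator is exactly zero are flagged invalid in a mask rather than
propagated as NaN/inf.  The plot-level regression target is the arithmetic
mean of the per-pixel map over its valid pixels (mean pooling) — note this
differs from evaluating the index on mean reflectances for mixed pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import VIParams

INDEX_NAMES = ("NDVI", "GNDVI", "RENDVI", "SAVI", "EVI")

#: bands each index needs, in reflectance units
REQUIRED_BANDS = {
    "NDVI": ("nir", "red"),
    "GNDVI": ("nir", "green"),
    "RENDVI": ("nir", "rededge"),
    "SAVI": ("nir", "red"),
    "EVI": ("nir", "red", "blue"),
}


class BandError(KeyError):
    """A band required by the requested index is missing."""


class EmptyPlotError(ValueError):
    """A plot has no valid pixels to average."""


@dataclass
class VIMap:
    """Per-pixel index values with a validity mask."""

    values: np.ndarray
    index_name: str
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must share a shape")


def _get_bands(bands, names):
    """Accept a FieldScene-like object (with .band) or a mapping of arrays."""
    out = []
    for n in names:
        if hasattr(bands, "band"):
            try:
                arr = bands.band(n)
            except KeyError as exc:
                raise BandError(f"scene is missing band {n!r}") from exc
        elif isinstance(bands, Mapping):
            if n not in bands:
                raise BandError(f"band {n!r} missing (have {sorted(bands)})")
            arr = bands[n]
        else:
            raise TypeError("bands must be a FieldScene or a mapping name -> raster")
        out.append(np.asarray(arr))
    return out


def vi_map(bands, index_name: str, params: VIParams | None = None) -> VIMap:
    """Evaluate one index per pixel.

    Parameters
    ----------
    bands
        A :class:`~plotvi.synthetic.FieldScene` or a mapping from band name
        (``blue, green, red, rededge, nir``) to a 2-D reflectance raster.
    index_name
        One of :data:`INDEX_NAMES` (case-insensitive).
    params
        Coefficients for SAVI/EVI; defaults used when omitted.
    """
    name = index_name.upper()
    if name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")
    p = params or VIParams()

    if name in ("NDVI", "GNDVI", "RENDVI"):
        other = {"NDVI": "red", "GNDVI": "green", "RENDVI": "rededge"}[name]
        nir, b = _get_bands(bands, ("nir", other))
        num = nir - b
        den = nir + b
    elif name == "SAVI":
        nir, red = _get_bands(bands, ("nir", "red"))
        num = (1.0 + p.savi_L) * (nir - red)
        den = nir + red + p.savi_L
    else:  # EVI
        nir, red, blue = _get_bands(bands, ("nir", "red", "blue"))
        num = p.evi_G * (nir - red)
        den = nir + p.evi_c1 * red - p.evi_c2 * blue + p.evi_L

    valid = den != 0
    values = np.zeros(np.broadcast(num, den).shape, dtype=np.result_type(num, den, float))
    np.divide(num, den, out=values, where=valid)
    return VIMap(values=values, index_name=name, valid_mask=valid)


def plot_mean_vi(vimap: VIMap) -> float:
    """Mean-pooled plot index: arithmetic mean over the valid pixels."""
    if not np.any(vimap.valid_mask):
        raise EmptyPlotError("no valid pixels in plot; cannot average the index map")
    return float(vimap.values[vimap.valid_mask].mean())


def plot_vi(bands, index_name: str, params: VIParams | None = None) -> float:
    """Convenience: :func:`vi_map` followed by :func:`plot_mean_vi`."""
    return plot_mean_vi(vi_map(bands, index_name, params))
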