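"""Plot extraction: geometry, radiometric calibration, cropping and resizing.

A scene is a georeferenced raster; the trial layout is a grid of axis-aligned
plot rectangles in world coordinates.  Sampling converts each rectangle to
intrinsic pixel coordinates through the scene's affine geotransform, crops
all five bands, computes the plot's mean vegetation index at native
resolution, and standardizes the RGB crop to height 15 x width 208 for the
regression network.  Rectangles that fall (partly) outside the raster are
skipped and reported rather than failing the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import VIParams
from .indices import plot_vi

log = logging.getLogger(__name__)

#: standardized (height, width) of a plot image fed to the network
STANDARD_HW = (15, 208)


class GeometryError(ValueError):
    """The geotransform is singular or otherwise unusable."""


class CalibrationError(ValueError):
    """Radiometric calibration input is invalid."""


@dataclass
class GeoTransform:
    """Affine world <-> pixel mapping.

    ``world = origin + R(rotation) @ (scale * pixel)`` with ``pixel`` given as
    (x=column, y=row).  ``scale`` is metres per pixel on each axis.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    scale: tuple[float, float] = (1.0, 1.0)
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.scale[0] == 0 or self.scale[1] == 0:
            raise GeometryError("geotransform scale components must be nonzero")

    def pixel_to_world(self, px: Sequence[float]) -> tuple[float, float]:
        x = self.scale[0] * px[0]
        y = self.scale[1] * px[1]
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return (self.origin[0] + c * x - s * y, self.origin[1] + s * x + c * y)

    def world_to_pixel(self, pt: Sequence[float]) -> tuple[float, float]:
        dx = pt[0] - self.origin[0]
        dy = pt[1] - self.origin[1]
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        x = c * dx + s * dy
        y = -s * dx + c * dy
        return (x / self.scale[0], y / self.scale[1])


def world_to_pixel(pt: Sequence[float], gt: GeoTransform) -> tuple[float, float]:
    """Exact affine inverse; continuous coordinates (column, row)."""
    return gt.world_to_pixel(pt)


@dataclass
class PlotRect:
    """One plot footprint: an axis-aligned rectangle in world coordinates."""

    plot_id: str
    bay_id: str
    range_idx: int
    row_idx: int
    min_x: float
    min_y: float
    max_x: float
    max_y: float

    def __post_init__(self) -> None:
        if not (self.max_x > self.min_x and self.max_y > self.min_y):
            raise ValueError(f"plot {self.plot_id}: rectangle must have positive area")


@dataclass
class PlotGrid:
    """The plot rectangles of one bay (or several)."""

    rects: list[PlotRect] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rects)

    def __iter__(self):
        return iter(self.rects)

    def to_csv(self, path) -> None:
        pd.DataFrame([vars(r) for r in self.rects]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlotGrid":
        df = pd.read_csv(path)
        return cls(rects=[PlotRect(**row) for row in df.to_dict("records")])


@dataclass
class PlotSample:
    """A standardized plot observation: RGB image plus its index target."""

    rgb: np.ndarray  # (15, 208, 3) float32 in [0, 1], channels R, G, B
    target_vi: float
    plot_id: str
    bay_id: str
    stage: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_vi):
            raise ValueError(f"plot {self.plot_id}: non-finite target VI")


def radiometric_scale(dn: np.ndarray, panel_dn: float, panel_reflectance: float) -> np.ndarray:
    """Convert raw digital numbers to reflectance via the calibration panel.

    ``reflectance = DN * panel_reflectance / panel_dn``, clipped to [0, 1].
    ``panel_dn`` is the mean DN observed over the reflectance panel whose
    true reflectance is ``panel_reflectance``.
    """
    if panel_dn <= 0:
        raise CalibrationError(f"panel_dn must be > 0, got {panel_dn}")
    refl = np.asarray(dn, dtype=np.float64) * (panel_reflectance / panel_dn)
    return np.clip(refl, 0.0, 1.0)


# ---- resizing --------------------------------------------------------------


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix of box-overlap weights.

    Output cell i covers the input interval [i*n_in/n_out, (i+1)*n_in/n_out);
    weights are the overlap lengths normalized to sum to 1, so downscaling is
    exact area averaging (mean-preserving for integer ratios).
    """
    w = np.zeros((n_out, n_in))
    step = n_in / n_out
    for i in range(n_out):
        lo, hi = i * step, (i + 1) * step
        j0, j1 = int(math.floor(lo)), int(math.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / w.sum(axis=1, keepdims=True)


def _bilinear_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) matrix of bilinear (tent) interpolation weights."""
    w = np.zeros((n_out, n_in))
    # align pixel centres: centre of output i maps to (i + .5) * n_in/n_out - .5
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    j0 = np.floor(pos).astype(int)
    frac = pos - j0
    j1 = np.minimum(j0 + 1, n_in - 1)
    w[np.arange(n_out), j0] += 1 - frac
    w[np.arange(n_out), j1] += frac
    return w


def resize_image(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Resize an (H, W[, C]) image.

    Area-weighted averaging per axis when shrinking (radiometry-preserving),
    bilinear when enlarging.  Applied separably as matrix products.
    """
    img = np.asarray(img, dtype=np.float64)
    h_in, w_in = img.shape[:2]
    h_out, w_out = out_hw
    wh = _area_weights(h_in, h_out) if h_out <= h_in else _bilinear_weights(h_in, h_out)
    ww = _area_weights(w_in, w_out) if w_out <= w_in else _bilinear_weights(w_in, w_out)
    out = np.tensordot(wh, img, axes=(1, 0))          # (h_out, W[, C])
    out = np.tensordot(ww, out, axes=(1, 1))          # (w_out, h_out[, C])
    return np.moveaxis(out, 0, 1)


# ---- sampling --------------------------------------------------------------


def rect_to_pixel_bounds(rect: PlotRect, gt: GeoTransform) -> tuple[int, int, int, int]:
    """Rasterize a world rectangle to half-open pixel ranges.

    Returns (row0, row1, col0, col1) with the convention
    [floor(min), floor(max)) on each axis, so adjacent rectangles tile the
    raster without double-counting boundary pixels.
    """
    corners = [(rect.min_x, rect.min_y), (rect.min_x, rect.max_y),
               (rect.max_x, rect.min_y), (rect.max_x, rect.max_y)]
    px = [gt.world_to_pixel(c) for c in corners]
    cols = [p[0] for p in px]
    rows = [p[1] for p in px]
    # guard against float fuzz putting an aligned edge a hair below its pixel
    eps = 1e-9
    c0, c1 = math.floor(min(cols) + eps), math.floor(max(cols) + eps)
    r0, r1 = math.floor(min(rows) + eps), math.floor(max(rows) + eps)
    return r0, r1, c0, c1


def sample_plots(
    scene,
    grid: PlotGrid | None = None,
    index_name: str = "NDVI",
    params: VIParams | None = None,
    standard_hw: tuple[int, int] = STANDARD_HW,
) -> tuple[list[PlotSample], list[str]]:
    """Crop every plot of a scene into a standardized RGB sample.

    For each in-bounds rectangle the five bands are cropped at native
    resolution, the plot's target index is the mean of the per-pixel index
    map over that crop, and the RGB (red, green, blue bands) crop is resized
    to ``standard_hw``.  Returns ``(samples, excluded_plot_ids)``; plots
    falling outside the raster are excluded with a warning, mirroring how
    unmapped plots are dropped from an aerial survey.
    """
    grid = grid if grid is not None else scene.grid
    if grid is None:
        raise ValueError("no plot grid supplied and the scene carries none")
    h, w = scene.shape
    samples: list[PlotSample] = []
    excluded: list[str] = []
    for rect in grid:
        r0, r1, c0, c1 = rect_to_pixel_bounds(rect, scene.geotransform)
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r1 <= r0 or c1 <= c0:
            log.warning("plot %s falls outside the raster; excluded", rect.plot_id)
            excluded.append(rect.plot_id)
            continue
        crop = {name: scene.band(name)[r0:r1, c0:c1] for name in scene.band_names}
        target = plot_vi(crop, index_name, params)
        rgb = np.stack([crop["red"], crop["green"], crop["blue"]], axis=-1)
        rgb = resize_image(rgb, standard_hw).astype(np.float32)
        samples.append(PlotSample(rgb=rgb, target_vi=target, plot_id=rect.plot_id,
                                  bay_id=rect.bay_id, stage=scene.stage))
    if excluded:
        log.info("excluded %d of %d plots outside the raster", len(excluded), len(grid))
    return samples, excluded


def samples_manifest(samples: Iterable[PlotSample]) -> pd.DataFrame:
    """Tabular view of a sample collection (no pixel data)."""
    return pd.DataFrame(
        [{"plot_id": s.plot_id, "bay_id": s.bay_id, "stage": s.stage,
          "target_vi": s.target_vi} for s in samples])
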