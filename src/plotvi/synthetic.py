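"""Synthetic multispectral field trial generator.

Produces georeferenced 5-band reflectance scenes (blue, green, red, rededge,
nir) that emulate an aerial survey of a row-plot breeding trial: bays of
single-row plots on a soil background, imaged at several growth stages as
vegetation cover rises and then senesces.  Each plot pixel is drawn
i.i.d. Bernoulli(cover) vegetation over soil; a per-stage fraction of the
vegetation pixels is senescent; zero-mean Gaussian sensor noise is added and
reflectance clipped to [0, 1].  Plots within one stage differ through jitter
of cover and senescence and a per-plot soil brightness gain, so the
plot-level index varies realistically within a bay.

All randomness derives from the config seed plus (bay, stage), so any scene
is reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .config import BAND_NAMES, ConfigError, SyntheticConfig
from .sampling import GeoTransform, PlotGrid, PlotRect, radiometric_scale

#: well-separated world origins per bay (metres)
_BAY_SPACING_M = 1000.0
_MARGIN_PX = 8

#: Spectra preset for the chromatic-ablation studies.  The three materials
#: share one luminance (0.299 R + 0.587 G + 0.114 B identical) and lie on a
#: single green<->red line in RGB space (constant blue, G and R moving along
#: the luma-neutral chlorophyll axis).  Consequences: a grayscale view of a
#: plot carries no index signal, and the plot's *mean* colour collapses to
#: one scalar that cannot identify the three mixture fractions — yet the
#: three pure pixel colours remain distinct, so spatially resolved colour
#: still identifies every pixel's material.  Index signal survives only in
#: the spatial-chromatic pattern.
ABLATION_SPECTRA = {
    "veg_spectrum": (0.18, 0.27475, 0.07325, 0.35, 0.50),
    "soil_spectrum": (0.18, 0.20, 0.22, 0.26, 0.30),
    "senescent_spectrum": (0.18, 0.16113, 0.29631, 0.30, 0.32),
}


def ablation_config(**overrides) -> SyntheticConfig:
    """A :class:`SyntheticConfig` using the equal-luma collinear preset.

    Soil gain is disabled by default here: a brightness gain would move the
    soil colour off the common line and leak mixture information back into
    the mean pixel.
    """
    kw = dict(ABLATION_SPECTRA)
    kw.setdefault("soil_gain_range", (1.0, 1.0))
    kw.update(overrides)
    return SyntheticConfig(**kw)


@dataclass
class FieldScene:
    """One bay at one growth stage: five reflectance rasters plus the grid."""

    bands: np.ndarray  # (5, H, W) float32 reflectance in [0, 1], BAND_NAMES order
    geotransform: GeoTransform
    grid: PlotGrid | None
    bay_id: str
    stage: int

    band_names = BAND_NAMES

    def __post_init__(self) -> None:
        if self.bands.ndim != 3 or self.bands.shape[0] != len(BAND_NAMES):
            raise ValueError(f"bands must be (5, H, W), got {self.bands.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_NAMES.index(name)]

    def rgb(self) -> np.ndarray:
        """(H, W, 3) view in R, G, B channel order."""
        return np.stack([self.band("red"), self.band("green"), self.band("blue")], axis=-1)


@dataclass
class DNScene:
    """Raw 16-bit digital numbers plus the rendered calibration-panel patch."""

    dn: np.ndarray      # (5, H, W) uint16
    panel: np.ndarray   # (5, p, p) uint16 patch of the reflectance panel
    panel_reflectance: float
    gain: float

    def panel_dn(self) -> np.ndarray:
        """Per-band mean DN over the panel patch."""
        return self.panel.reshape(self.panel.shape[0], -1).mean(axis=1)

    def to_reflectance(self) -> np.ndarray:
        """Invert the encoding via the panel (per-band calibration)."""
        pdn = self.panel_dn()
        return np.stack([radiometric_scale(self.dn[i], pdn[i], self.panel_reflectance)
                         for i in range(self.dn.shape[0])])


# ---- layout ---------------------------------------------------------------


def _layout(cfg: SyntheticConfig) -> tuple[int, int]:
    """(n_ranges, n_cols): arrange plots_per_bay in a near-square raster."""
    ph, pw = cfg.plot_px
    cell_h, cell_w = ph + cfg.gap_px, pw + cfg.gap_px
    n_cols = max(1, round(math.sqrt(cfg.plots_per_bay * cell_h / cell_w)))
    n_ranges = math.ceil(cfg.plots_per_bay / n_cols)
    return n_ranges, n_cols


def scene_shape(cfg: SyntheticConfig) -> tuple[int, int]:
    n_ranges, n_cols = _layout(cfg)
    ph, pw = cfg.plot_px
    h = 2 * _MARGIN_PX + n_ranges * (ph + cfg.gap_px) - cfg.gap_px
    w = 2 * _MARGIN_PX + n_cols * (pw + cfg.gap_px) - cfg.gap_px
    return h, w


def _bay_index(cfg: SyntheticConfig, bay) -> int:
    if isinstance(bay, str):
        try:
            return cfg.bay_ids.index(bay)
        except ValueError:
            raise ConfigError(f"unknown bay {bay!r}; have {cfg.bay_ids}") from None
    bay = int(bay)
    if not 0 <= bay < cfg.n_bays:
        raise ConfigError(f"bay index {bay} out of range for {cfg.n_bays} bays")
    return bay


def bay_geotransform(cfg: SyntheticConfig, bay) -> GeoTransform:
    idx = _bay_index(cfg, bay)
    return GeoTransform(origin=(idx * _BAY_SPACING_M, 0.0), scale=(cfg.gsd, cfg.gsd))


def build_grid(cfg: SyntheticConfig, bay) -> PlotGrid:
    """World-coordinate plot rectangles of one bay, aligned to pixel edges."""
    idx = _bay_index(cfg, bay)
    bay_id = cfg.bay_ids[idx]
    gt = bay_geotransform(cfg, bay)
    n_ranges, n_cols = _layout(cfg)
    ph, pw = cfg.plot_px
    rects = []
    for k in range(cfg.plots_per_bay):
        i, j = divmod(k, n_cols)
        r0 = _MARGIN_PX + i * (ph + cfg.gap_px)
        c0 = _MARGIN_PX + j * (pw + cfg.gap_px)
        x0, y0 = gt.pixel_to_world((c0, r0))
        x1, y1 = gt.pixel_to_world((c0 + pw, r0 + ph))
        rects.append(PlotRect(plot_id=f"{bay_id}-p{k:04d}", bay_id=bay_id,
                              range_idx=i, row_idx=j,
                              min_x=x0, min_y=y0, max_x=x1, max_y=y1))
    return PlotGrid(rects=rects)


# ---- rendering ------------------------------------------------------------


def _scene_rng(cfg: SyntheticConfig, bay_idx: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(bay_idx, stage)))


def generate_field(cfg: SyntheticConfig, bay, stage: int) -> FieldScene:
    """Render one bay at one growth stage.

    Deterministic given ``(cfg.seed, bay, stage)``.  Raises a configuration
    error for an out-of-range stage.
    """
    if not 0 <= stage < cfg.n_stages:
        raise ConfigError(f"stage {stage} out of range for n_stages={cfg.n_stages}")
    idx = _bay_index(cfg, bay)
    bay_id = cfg.bay_ids[idx]
    rng = _scene_rng(cfg, idx, stage)
    h, w = scene_shape(cfg)
    soil = np.asarray(cfg.soil_spectrum, dtype=np.float64)
    veg = np.asarray(cfg.veg_spectrum, dtype=np.float64)
    sen = np.asarray(cfg.senescent_spectrum, dtype=np.float64)
    if cfg.senescent_nir_curve is not None:
        sen = sen.copy()
        sen[BAND_NAMES.index("nir")] = cfg.senescent_nir_curve[stage]
    bands = np.broadcast_to(soil[:, None, None], (len(BAND_NAMES), h, w)).copy()

    grid = build_grid(cfg, bay)
    gt = bay_geotransform(cfg, bay)
    cover0 = cfg.cover_curve[stage]
    sen0 = cfg.senescence_curve[stage]
    ph, pw = cfg.plot_px
    for rect in grid:
        c0, r0 = gt.world_to_pixel((rect.min_x, rect.min_y))
        r0, c0 = int(round(r0)), int(round(c0))
        cover = cover0 if cfg.cover_jitter_sd == 0 else float(
            np.clip(cover0 + rng.normal(0.0, cfg.cover_jitter_sd), 0.0, 1.0))
        sfrac = sen0 if cfg.senescence_jitter_sd == 0 else float(
            np.clip(sen0 + rng.normal(0.0, cfg.senescence_jitter_sd), 0.0, 1.0))
        gain_soil = float(rng.uniform(*cfg.soil_gain_range))
        # per-plot canopy brightness (illumination / canopy structure); a
        # multiplicative gain leaves every ratio index unchanged, so it
        # perturbs RGB appearance without perturbing the target
        gain_veg = float(rng.uniform(*cfg.veg_gain_range))
        veg_mask = rng.random((ph, pw)) < cover
        sen_mask = veg_mask & (rng.random((ph, pw)) < sfrac)
        block = np.where(veg_mask, 0.0, 1.0)[None] * (soil[:, None, None] * gain_soil)
        block += (veg_mask & ~sen_mask)[None] * (veg[:, None, None] * gain_veg)
        block += sen_mask[None] * (sen[:, None, None] * gain_veg)
        bands[:, r0:r0 + ph, c0:c0 + pw] = block
    if cfg.noise_sd > 0:
        bands = bands + rng.normal(0.0, cfg.noise_sd, bands.shape)
    bands = np.clip(bands, 0.0, 1.0).astype(np.float32)
    return FieldScene(bands=bands, geotransform=gt, grid=grid, bay_id=bay_id, stage=stage)


def encode_dn(scene: FieldScene, cfg: SyntheticConfig, gain: float = 1.0,
              panel_px: int = 8) -> DNScene:
    """Encode reflectance to 16-bit digital numbers with a panel patch.

    ``DN = round(reflectance * dn_max * gain)`` clipped to the 16-bit range;
    the returned panel patch renders the calibration panel (uniform true
    reflectance ``cfg.panel_reflectance``) under the same gain, so
    :func:`~plotvi.sampling.radiometric_scale` inverts the encoding up to
    rounding.
    """
    if cfg.dn_max <= 0:
        raise ConfigError("dn_max must be positive")
    if gain <= 0:
        raise ConfigError("encoding gain must be positive")
    scale = cfg.dn_max * gain
    dn = np.clip(np.rint(scene.bands.astype(np.float64) * scale), 0, 65535).astype(np.uint16)
    panel_val = int(np.clip(round(cfg.panel_reflectance * scale), 0, 65535))
    panel = np.full((len(BAND_NAMES), panel_px, panel_px), panel_val, dtype=np.uint16)
    return DNScene(dn=dn, panel=panel, panel_reflectance=cfg.panel_reflectance, gain=gain)


# ---- bookkeeping helpers ---------------------------------------------------


@dataclass
class PlotObservation:
    """Lightweight (plot, bay, stage) record used for split bookkeeping."""

    plot_id: str
    bay_id: str
    stage: int


def trial_observations(cfg: SyntheticConfig) -> list[PlotObservation]:
    """All plot x stage observation records of the trial, without rendering."""
    obs = []
    for b in range(cfg.n_bays):
        grid = build_grid(cfg, b)
        for stage in range(cfg.n_stages):
            obs.extend(PlotObservation(r.plot_id, r.bay_id, stage) for r in grid)
    return obs


def ground_reference_plots(cfg: SyntheticConfig, per_line: int = 12,
                           lines_per_bay: int = 2) -> list[str]:
    """Plots assigned a handheld ground-sensor reference measurement.

    Mirrors the survey design: a fixed number of lines per bay, each covering
    ``per_line`` consecutive plots (default 2 x 12 = 24 plots per bay).
    """
    ids = []
    for b in range(cfg.n_bays):
        grid = build_grid(cfg, b)
        n = len(grid.rects)
        starts = [round(i * n / lines_per_bay) for i in range(lines_per_bay)]
        for s in starts:
            ids.extend(r.plot_id for r in grid.rects[s:s + min(per_line, n)])
    return ids


# ---- scene I/O -------------------------------------------------------------


def write_scene(scene: FieldScene, path, as_dn: bool = False,
                cfg: SyntheticConfig | None = None) -> None:
    """Write a scene as a 5-page TIFF plus a JSON metadata sidecar.

    Bands are stored one per page in ``BAND_NAMES`` order, float32
    reflectance by default or uint16 DN when ``as_dn`` (requires ``cfg``).
    """
    path = Path(path)
    if as_dn:
        if cfg is None:
            raise ValueError("cfg is required to encode digital numbers")
        data = encode_dn(scene, cfg).dn
    else:
        data = scene.bands
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "bay_id": scene.bay_id,
        "stage": scene.stage,
        "band_names": list(BAND_NAMES),
        "geotransform": {"origin": list(scene.geotransform.origin),
                         "scale": list(scene.geotransform.scale),
                         "rotation": scene.geotransform.rotation},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    if scene.grid is not None:
        scene.grid.to_csv(path.with_suffix(".grid.csv"))


def read_scene(path) -> FieldScene:
    """Read a scene written by :func:`write_scene` (reflectance layout)."""
    path = Path(path)
    bands = np.asarray(tifffile.imread(path))
    if bands.dtype == np.uint16:
        bands = bands.astype(np.float32) / 65535.0
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    gt = GeoTransform(origin=tuple(meta["geotransform"]["origin"]),
                      scale=tuple(meta["geotransform"]["scale"]),
                      rotation=meta["geotransform"]["rotation"])
    grid_path = path.with_suffix(".grid.csv")
    grid = PlotGrid.from_csv(grid_path) if grid_path.exists() else None
    return FieldScene(bands=bands.astype(np.float32), geotransform=gt, grid=grid,
                      bay_id=meta["bay_id"], stage=int(meta["stage"]))
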