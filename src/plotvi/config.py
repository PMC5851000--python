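"""Configuration objects for the simulator, the indices, the network and training.

Every tunable the pipeline uses lives in one of the frozen-ish dataclasses
below, so a run is fully described by a :class:`RunConfig` plus a seed.
Validation happens at construction time; downstream code may assume a config
that exists is internally consistent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Band order used everywhere a 5-band stack appears.
BAND_NAMES = ("blue", "green", "red", "rededge", "nir")

EXPERIMENTS = ("dnn-rgb", "dnn-gray", "lr-rgb", "dnn-t")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_spectrum(name: str, values: Sequence[float]) -> tuple[float, ...]:
    values = tuple(float(v) for v in values)
    if len(values) != len(BAND_NAMES):
        raise ConfigError(f"{name} must have {len(BAND_NAMES)} bands, got {len(values)}")
    if any(not (0.0 <= v <= 1.0) for v in values):
        raise ConfigError(f"{name} reflectances must lie in [0, 1]: {values}")
    return values


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multispectral field trial.

    The defaults emulate the layout of a wheat breeding trial: 3 bays of 576
    single-row plots imaged at 7 time points, with vegetation cover rising
    through the season and senescence taking over late.  Spectra are per-band
    reflectances in ``BAND_NAMES`` order (blue, green, red, rededge, nir).

    Beyond the stage-level curves, plots within a stage differ: per-plot
    cover and senescence are jittered around the stage value and each plot's
    soil patch gets a random brightness gain (dry vs moist soil).  These make
    the plot-level VI a non-trivial regression target.
    """

    n_bays: int = 3
    plots_per_bay: int = 576
    n_stages: int = 7
    plot_px: tuple[int, int] = (20, 260)  # native (height, width) of a plot footprint
    gsd: float = 0.015  # metres per pixel
    veg_spectrum: tuple[float, ...] = (0.04, 0.08, 0.05, 0.30, 0.50)
    soil_spectrum: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)
    senescent_spectrum: tuple[float, ...] = (0.15, 0.20, 0.25, 0.28, 0.30)
    cover_curve: tuple[float, ...] = (0.10, 0.30, 0.55, 0.75, 0.85, 0.85, 0.80)
    senescence_curve: tuple[float, ...] = (0.0, 0.0, 0.0, 0.05, 0.15, 0.45, 0.85)
    noise_sd: float = 0.01
    panel_reflectance: float = 0.5
    dn_max: int = 65535
    seed: int = 0
    # per-plot heterogeneity (sd of the truncated-normal jitter / gain range)
    cover_jitter_sd: float = 0.12
    senescence_jitter_sd: float = 0.10
    soil_gain_range: tuple[float, float] = (0.85, 1.15)
    veg_gain_range: tuple[float, float] = (1.0, 1.0)
    #: per-stage NIR reflectance of the senescent material, or None for a
    #: constant spectrum.  Late-season desiccation collapses NIR while the
    #: visible bands barely change, so a declining curve makes the terminal
    #: stages' index genuinely unknowable from colour alone.
    senescent_nir_curve: tuple[float, ...] | None = None
    gap_px: int = 4  # soil gap between neighbouring plots, pixels

    def __post_init__(self) -> None:
        self.veg_spectrum = _check_spectrum("veg_spectrum", self.veg_spectrum)
        self.soil_spectrum = _check_spectrum("soil_spectrum", self.soil_spectrum)
        self.senescent_spectrum = _check_spectrum("senescent_spectrum", self.senescent_spectrum)
        self.cover_curve = tuple(float(v) for v in self.cover_curve)
        self.senescence_curve = tuple(float(v) for v in self.senescence_curve)
        for name, curve in (("cover_curve", self.cover_curve),
                            ("senescence_curve", self.senescence_curve)):
            if len(curve) != self.n_stages:
                raise ConfigError(
                    f"{name} must have n_stages={self.n_stages} entries, got {len(curve)}")
            if any(not (0.0 <= v <= 1.0) for v in curve):
                raise ConfigError(f"{name} fractions must lie in [0, 1]: {curve}")
        if self.senescent_nir_curve is not None:
            self.senescent_nir_curve = tuple(float(v) for v in self.senescent_nir_curve)
            if len(self.senescent_nir_curve) != self.n_stages:
                raise ConfigError("senescent_nir_curve must have n_stages entries")
            if any(not (0.0 <= v <= 1.0) for v in self.senescent_nir_curve):
                raise ConfigError("senescent_nir_curve values must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0.0 < self.panel_reflectance <= 1.0):
            raise ConfigError("panel_reflectance must lie in (0, 1]")
        if self.dn_max <= 0:
            raise ConfigError("dn_max must be a positive integer")
        if self.n_bays < 1 or self.plots_per_bay < 1 or self.n_stages < 1:
            raise ConfigError("layout counts must be positive")
        # healthy canopy must have positive NDVI by construction
        nir = self.veg_spectrum[BAND_NAMES.index("nir")]
        red = self.veg_spectrum[BAND_NAMES.index("red")]
        if not nir > red:
            raise ConfigError("veg_spectrum must have NIR > red reflectance")

    @property
    def bay_ids(self) -> tuple[str, ...]:
        return tuple(f"bay{i + 1}" for i in range(self.n_bays))


@dataclass
class VIParams:
    """Coefficients of the soil/atmosphere-corrected indices.

    The normalized-difference indices need no constants; SAVI takes a soil
    adjustment factor ``L`` and EVI a gain ``G``, aerosol coefficients ``c1``
    (red) and ``c2`` (blue) and a canopy background term ``L``.  Defaults are
    the literature's standard values (SAVI L=0.5; EVI G=2.5, c1=6, c2=7.5,
    L=1).
    """

    savi_L: float = 0.5
    evi_G: float = 2.5
    evi_c1: float = 6.0
    evi_c2: float = 7.5
    evi_L: float = 1.0

    def __post_init__(self) -> None:
        import math

        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigError(f"{f.name} must be finite")
        if self.savi_L < 0:
            raise ConfigError("savi_L must be >= 0")


@dataclass
class NetConfig:
    """Architecture of the convolutional VI regressor.

    conv(20, 5x5, same) -> maxpool 2x2 -> conv(50, 5x5, same) -> maxpool 2x2
    -> flatten -> fc(fc_hidden) -> ReLU -> dropout -> fc(1).

    Same-padding is required: with valid convolutions the 15-pixel input
    height collapses to zero before the second pooling stage.
    """

    input_hw: tuple[int, int] = (15, 208)
    in_channels: int = 3
    conv1_maps: int = 20
    conv1_kernel: int = 5
    pool: int = 2
    conv2_maps: int = 50
    conv2_kernel: int = 5
    fc_hidden: int = 500
    dropout_rate: float = 0.5
    init_scale: float = 1.0  # multiplier on the standard He/Glorot widths

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.in_channels not in (1, 3):
            raise ConfigError("in_channels must be 1 (grayscale) or 3 (RGB)")
        h, w = self.input_hw
        for stage in ("pool1", "pool2"):
            h, w = h // self.pool, w // self.pool
            if h < 1 or w < 1:
                raise ConfigError(
                    f"spatial dimensions collapse to {h}x{w} at {stage}; "
                    "input too small for the layer stack")


@dataclass
class TrainConfig:
    """SGD hyperparameters.

    The optimizer is plain SGD with momentum and weight decay on a Euclidean
    (half mean-squared) loss; the learning rate follows the inverse-decay
    policy ``base_lr * (1 + lr_gamma * iter) ** -lr_power``.  Mini-batches of
    72 images are drawn without replacement each epoch and images are flipped
    left-right with probability 1/2 when ``augment_flip`` is on.
    """

    base_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    lr_gamma: float = 0.9
    lr_power: float = 0.75
    batch_size: int = 72
    epochs: int = 50
    seed: int = 0
    augment_flip: bool = True

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ConfigError("base_lr must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ConfigError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")


@dataclass
class RunConfig:
    """One end-to-end experiment: simulate, sample, train, evaluate."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    vi_index: str = "NDVI"
    vi_params: VIParams = field(default_factory=VIParams)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    experiment: str = "dnn-rgb"
    output_dir: str = "plotvi-run"
    log_level: str = "INFO"
    n_folds: int | None = None  # None = all folds of the chosen scheme

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")

    # ---- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("synthetic", SyntheticConfig), ("vi_params", VIParams),
                         ("net", NetConfig), ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
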