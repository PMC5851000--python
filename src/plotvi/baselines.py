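"""Ablation baselines: spectral (grayscale), spatial (mean pixel + linear
regression) and temporal (leave-one-stage-out splits).

Each baseline removes one kind of information from the RGB plot image to
quantify its contribution to index estimation: DNN-GRAY discards colour,
LR-RGB discards spatial structure, and DNN-T withholds one imaging date.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

#: ITU-R BT.601 luma weights for R, G, B
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class MeanPixel(NamedTuple):
    """A plot image spatially collapsed to its per-channel means."""

    r_mean: float
    g_mean: float
    b_mean: float


class FitError(np.linalg.LinAlgError):
    """Linear-model fit failed (e.g. rank-deficient design)."""


def to_grayscale(rgb: np.ndarray, weights: str = "luma") -> np.ndarray:
    """Collapse an (H, W, 3) image to a single luminance channel (H, W, 1).

    ``weights='luma'`` uses the standard 0.299/0.587/0.114 coefficients;
    ``'equal'`` averages the three channels.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {rgb.shape}")
    if weights == "luma":
        w = np.asarray(LUMA_WEIGHTS)
    elif weights == "equal":
        w = np.full(3, 1.0 / 3.0)
    else:
        raise ValueError("weights must be 'luma' or 'equal'")
    return (rgb @ w)[..., None].astype(rgb.dtype)


def mean_pixel(rgb: np.ndarray) -> MeanPixel:
    """Average each channel over space: the 1x1x3 'image' of a plot."""
    rgb = np.asarray(rgb)
    if rgb.size == 0:
        raise ValueError("cannot take the mean pixel of an empty image")
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {rgb.shape}")
    m = rgb.reshape(-1, 3).mean(axis=0)
    return MeanPixel(float(m[0]), float(m[1]), float(m[2]))


@dataclass
class LinearVIModel:
    """Ordinary least squares from mean pixel to plot index."""

    coefficients: np.ndarray  # (3,) weights for (R, G, B) means
    intercept: float

    def predict(self, pixels) -> np.ndarray | float:
        arr = np.asarray(pixels, dtype=np.float64)
        single = arr.ndim == 1
        out = np.atleast_2d(arr) @ self.coefficients + self.intercept
        return float(out[0]) if single else out

    def to_text(self) -> str:
        names = ("coef_r", "coef_g", "coef_b")
        lines = [f"{n} {v:.12g}" for n, v in zip(names, self.coefficients)]
        lines.append(f"intercept {self.intercept:.12g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LinearVIModel":
        vals = dict(line.split() for line in text.strip().splitlines())
        coef = np.array([float(vals["coef_r"]), float(vals["coef_g"]),
                         float(vals["coef_b"])])
        return cls(coefficients=coef, intercept=float(vals["intercept"]))


def fit_lr_rgb(pixels: Sequence[Sequence[float]], targets: Sequence[float]) -> LinearVIModel:
    """Least-squares fit of plot VI on the three channel means, with intercept."""
    x = np.asarray(pixels, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("pixels must be an (n, 3) array of channel means")
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 (mean pixel, target) pairs of equal length")
    design = np.column_stack([x, np.ones(len(x))])
    rank = np.linalg.matrix_rank(design)
    if rank < 4:
        # name the offending channels for the error message
        channels = np.array(["R", "G", "B"])
        sd = x.std(axis=0)
        flat = channels[sd < 1e-12 * max(1.0, np.abs(x).max())]
        detail = f" (constant channels: {', '.join(flat)})" if flat.size else ""
        raise FitError(f"rank-deficient design, rank {rank} < 4: "
                       f"channel means are collinear{detail}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearVIModel(coefficients=beta[:3], intercept=float(beta[3]))


def temporal_holdout_splits(samples: Sequence) -> list[tuple[int, list, list]]:
    """Leave-one-stage-out splits: one (stage, train, test) triple per stage.

    For every growth stage present, the test set is that stage's samples and
    the training set everything else; the pairs partition the data.
    """
    stages = sorted({s.stage for s in samples})
    if len(stages) < 2:
        raise ValueError("temporal hold-out needs at least 2 growth stages")
    splits = []
    for stage in stages:
        train = [s for s in samples if s.stage != stage]
        test = [s for s in samples if s.stage == stage]
        splits.append((stage, train, test))
    return splits
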