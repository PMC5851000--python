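"""Model/Results interface over the VI estimators.

Two model families share the same idiom — build the model from plot samples,
``fit()`` it, and work with the returned results object:

>>> res = VIRegression(train_samples).fit()
>>> res.predict(test_samples)
>>> report = res.evaluate(test_samples)
>>> print(res.summary())

:class:`VIRegression` is the convolutional network (RGB by default, grayscale
input for the spectral ablation); :class:`LinearVIRegression` is the
mean-pixel linear baseline.  Both results objects expose ``predict``,
``evaluate`` (returning an :class:`~plotvi.evaluation.EvalReport`) and a
plain-text ``summary``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .baselines import LinearVIModel, fit_lr_rgb, mean_pixel, to_grayscale
from .config import NetConfig, TrainConfig
from .evaluation import EvalReport, summarize
from .sampling import PlotSample


def samples_to_arrays(samples: Sequence[PlotSample],
                      grayscale: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N, H, W, C) images and (N,) targets."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    imgs = [to_grayscale(s.rgb) if grayscale else s.rgb for s in samples]
    x = np.stack(imgs).astype(np.float32)
    y = np.array([s.target_vi for s in samples], dtype=np.float32)
    return x, y


class VIRegression:
    """Convolutional regression of plot VI on the plot's RGB (or gray) image."""

    def __init__(self, samples: Sequence[PlotSample],
                 net_config: NetConfig | None = None,
                 train_config: TrainConfig | None = None,
                 grayscale: bool = False):
        self.samples = list(samples)
        self.grayscale = grayscale
        in_channels = 1 if grayscale else 3
        self.net_config = net_config or NetConfig(in_channels=in_channels)
        if self.net_config.in_channels != in_channels:
            self.net_config = replace(self.net_config, in_channels=in_channels)
        self.train_config = train_config or TrainConfig()

    def fit(self, seed: int | None = None) -> "VIRegressionResults":
        """Train with SGD; ``seed`` overrides the train config's seed."""
        cfg = self.train_config if seed is None else replace(self.train_config, seed=seed)
        x, y = samples_to_arrays(self.samples, grayscale=self.grayscale)
        trained = nn.build_model(self.net_config, seed=cfg.seed)
        trained = nn.train(trained, x, y, cfg)
        return VIRegressionResults(self, trained)


class VIRegressionResults:
    """A fitted :class:`VIRegression`: trained weights, log, predictions."""

    def __init__(self, model: VIRegression, trained: nn.TrainedModel):
        self.model = model
        self.trained = trained

    @property
    def training_log(self) -> pd.DataFrame:
        return self.trained.training_log

    def _images(self, samples_or_images):
        if len(samples_or_images) and isinstance(samples_or_images[0], PlotSample):
            x, _ = samples_to_arrays(samples_or_images, grayscale=self.model.grayscale)
            return x
        return np.asarray(samples_or_images, dtype=np.float32)

    def predict(self, samples_or_images) -> np.ndarray:
        """Estimated VI for plot samples or raw image arrays."""
        return np.atleast_1d(self.trained.predict(self._images(samples_or_images)))

    def evaluate(self, test_samples: Sequence[PlotSample],
                 model_name: str | None = None) -> EvalReport:
        est = self.predict(test_samples)
        obs = np.array([s.target_vi for s in test_samples])
        stages = np.array([s.stage for s in test_samples])
        name = model_name or ("DNN-GRAY" if self.model.grayscale else "DNN-RGB")
        return summarize(obs, est, stages, model_name=name,
                         n_train=len(self.model.samples), n_test=len(test_samples))

    def save(self, path) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        cfg = self.model.net_config
        log = self.training_log
        head = "grayscale" if self.model.grayscale else "RGB"
        lines = [
            f"Convolutional VI regression ({head} input)",
            f"  input {cfg.input_hw[0]}x{cfg.input_hw[1]}x{cfg.in_channels}"
            f" -> conv{cfg.conv1_maps}(5x5) -> pool -> conv{cfg.conv2_maps}(5x5)"
            f" -> pool -> fc{cfg.fc_hidden} -> fc1",
            f"  n_obs = {len(self.model.samples)}, iterations = {len(log)}",
        ]
        if len(log):
            k = max(1, len(log) // 10)
            lines.append(f"  loss: first-10-iter mean {log['loss'].iloc[:10].mean():.5f}, "
                         f"last-{k}-iter mean {log['loss'].iloc[-k:].mean():.5f}")
            lines.append(f"  final learning rate {log['lr'].iloc[-1]:.3e}")
        return "\n".join(lines)


class LinearVIRegression:
    """Mean-pixel linear baseline: OLS of plot VI on per-channel means."""

    def __init__(self, samples: Sequence[PlotSample]):
        self.samples = list(samples)

    def fit(self) -> "LinearVIRegressionResults":
        pixels = np.array([mean_pixel(s.rgb) for s in self.samples])
        targets = np.array([s.target_vi for s in self.samples])
        return LinearVIRegressionResults(self, fit_lr_rgb(pixels, targets))


class LinearVIRegressionResults:
    def __init__(self, model: LinearVIRegression, fitted: LinearVIModel):
        self.model = model
        self.fitted = fitted

    @property
    def params(self) -> np.ndarray:
        """(coef_r, coef_g, coef_b, intercept)."""
        return np.append(self.fitted.coefficients, self.fitted.intercept)

    def predict(self, samples_or_pixels) -> np.ndarray:
        items = samples_or_pixels
        if len(items) and isinstance(items[0], PlotSample):
            pixels = np.array([mean_pixel(s.rgb) for s in items])
        else:
            pixels = np.asarray(items, dtype=np.float64)
        return np.atleast_1d(self.fitted.predict(pixels))

    def evaluate(self, test_samples: Sequence[PlotSample],
                 model_name: str = "LR-RGB") -> EvalReport:
        est = self.predict(test_samples)
        obs = np.array([s.target_vi for s in test_samples])
        stages = np.array([s.stage for s in test_samples])
        return summarize(obs, est, stages, model_name=model_name,
                         n_train=len(self.model.samples), n_test=len(test_samples))

    def summary(self) -> str:
        c = self.fitted.coefficients
        return ("Linear VI regression on mean pixel\n"
                f"  VI = {c[0]:+.4f} R + {c[1]:+.4f} G + {c[2]:+.4f} B "
                f"{self.fitted.intercept:+.4f}\n"
                f"  n_obs = {len(self.model.samples)}")
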