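"""End-to-end experiment orchestration: simulate -> sample -> train -> evaluate.

``run_experiment`` renders every bay at every growth stage, extracts the plot
samples, trains the selected estimator under the appropriate validation
scheme (leave-one-bay-out for dnn-rgb / dnn-gray / lr-rgb, leave-one-stage-out
for dnn-t), pools the held-out predictions and writes the evaluation report
plus a manifest with the seed and config hash.  Identical config and seed
reproduce the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .baselines import temporal_holdout_splits
from .config import RunConfig, TrainConfig
from .evaluation import EvalReport, make_bay_folds, split_by_fold, summarize
from .model import LinearVIRegression, VIRegression
from .sampling import PlotSample, sample_plots
from .synthetic import generate_field

log = logging.getLogger(__name__)


def build_samples(cfg: RunConfig) -> tuple[list[PlotSample], list[str]]:
    """Render all scenes and crop every plot; returns (samples, excluded ids)."""
    samples: list[PlotSample] = []
    excluded: list[str] = []
    for bay in range(cfg.synthetic.n_bays):
        for stage in range(cfg.synthetic.n_stages):
            scene = generate_field(cfg.synthetic, bay, stage)
            s, ex = sample_plots(scene, index_name=cfg.vi_index, params=cfg.vi_params)
            samples.extend(s)
            excluded.extend(ex)
            log.info("bay %d stage %d: %d plots sampled, %d excluded",
                     bay, stage, len(s), len(ex))
    return samples, excluded


def _fold_seed(base_seed: int, fold_id: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(101, fold_id))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _fit_and_predict(experiment: str, train_samples, test_samples,
                     cfg: RunConfig, seed: int):
    if experiment == "lr-rgb":
        res = LinearVIRegression(train_samples).fit()
    else:
        gray = experiment == "dnn-gray"
        res = VIRegression(train_samples, net_config=None if gray else cfg.net,
                           train_config=cfg.train, grayscale=gray).fit(seed=seed)
    return res, res.predict(test_samples)


def run_experiment(cfg: RunConfig, output_dir=None) -> EvalReport:
    """Run one configured experiment end to end.

    Held-out predictions are pooled across folds into a single report named
    after the experiment.  Artifacts written to ``output_dir`` (defaults to
    ``cfg.output_dir``): ``report.csv``, ``report.json``, ``manifest.json``
    and per-fold trained models.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    samples, excluded = build_samples(cfg)
    log.info("total %d samples (%d excluded plots)", len(samples), len(excluded))

    if cfg.experiment == "dnn-t":
        splits = [(f"stage{stage}", train, test)
                  for stage, train, test in temporal_holdout_splits(samples)]
    else:
        folds = make_bay_folds(samples)
        splits = []
        for fold in folds:
            train, test = split_by_fold(samples, fold)
            splits.append((f"bay-fold{fold.fold_id}", train, test))
    if cfg.n_folds is not None:
        splits = splits[: cfg.n_folds]

    obs, est, stages = [], [], []
    n_train_total = 0
    for i, (name, train_samples, test_samples) in enumerate(splits):
        seed = _fold_seed(cfg.train.seed, i)
        log.info("%s: training %s on %d samples, testing on %d",
                 name, cfg.experiment, len(train_samples), len(test_samples))
        res, pred = _fit_and_predict(cfg.experiment, train_samples, test_samples, cfg, seed)
        obs.extend(s.target_vi for s in test_samples)
        est.extend(pred.tolist())
        stages.extend(s.stage for s in test_samples)
        n_train_total += len(train_samples)
        if cfg.experiment == "lr-rgb":
            (out / f"model-{name}.txt").write_text(res.fitted.to_text())
        else:
            res.save(out / f"model-{name}.zip")

    report = summarize(obs, est, stages, model_name=cfg.experiment,
                       n_train=n_train_total, n_test=len(obs))
    report.to_dataframe().to_csv(out / "report.csv", index=False, float_format="%.10g")
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    manifest = {
        "experiment": cfg.experiment,
        "seed": cfg.train.seed,
        "synthetic_seed": cfg.synthetic.seed,
        "config_digest": cfg.digest(),
        "n_samples": len(samples),
        "n_excluded": len(excluded),
        "folds": [name for name, *_ in splits],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    cfg.to_yaml(out / "config.yaml")
    return report


def evaluate_models_on(samples: Sequence[PlotSample], results, names) -> list[EvalReport]:
    """Evaluate several fitted results objects on one common test set."""
    return [res.evaluate(samples, model_name=name) for res, name in zip(results, names)]
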