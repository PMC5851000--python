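"""Evaluation machinery: bay-wise cross-validation, percentage errors,
robust regression of observed vs estimated index, and per-stage summaries.

The validation design is leave-one-bay-out: each fold trains on all bays but
one and tests on the spatially distinct held-out bay.  Accuracy is reported
as the relative percentage error

    error(%) = (VI_obs - VI_est) / VI_obs * 100

(an overestimate is negative), summarized per growth stage by mean, standard
deviation, Pearson correlation and box statistics, and pooled across stages
by a robust (bisquare IRLS) straight-line fit of estimated on observed VI
with its R^2 and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: bisquare tuning constant (95% Gaussian efficiency)
BISQUARE_C = 4.685
#: box-plot whisker multiplier
WHISKER_W = 1.5


class FoldError(ValueError):
    """Cross-validation design cannot be built from the given samples."""


@dataclass
class FoldSpec:
    fold_id: int
    train_bays: tuple[str, ...]
    test_bay: str


def make_bay_folds(samples: Sequence) -> list[FoldSpec]:
    """One fold per bay, that bay held out; ordered by bay label."""
    bays = sorted({s.bay_id for s in samples})
    if len(bays) < 2:
        raise FoldError(f"bay-wise cross-validation needs >= 2 bays, found {bays}")
    return [FoldSpec(fold_id=i,
                     train_bays=tuple(b for b in bays if b != bay),
                     test_bay=bay)
            for i, bay in enumerate(bays)]


def split_by_fold(samples: Sequence, fold: FoldSpec) -> tuple[list, list]:
    train = [s for s in samples if s.bay_id in fold.train_bays]
    test = [s for s in samples if s.bay_id == fold.test_bay]
    return train, test


def percentage_error(observed, estimated) -> np.ndarray | float:
    """Relative error in percent; positive when the model underestimates.

    Elements with ``observed == 0`` are undefined and returned as NaN; the
    summary statistics exclude and count them.
    """
    obs = np.asarray(observed, dtype=np.float64)
    est = np.asarray(estimated, dtype=np.float64)
    scalar = obs.ndim == 0
    obs, est = np.atleast_1d(obs), np.atleast_1d(est)
    out = np.full(obs.shape, np.nan)
    ok = obs != 0
    out[ok] = (obs[ok] - est[ok]) / obs[ok] * 100.0
    return float(out[0]) if scalar else out


# ---- robust regression -----------------------------------------------------


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    rmse: float
    pearson_r: float
    iterations: int = 0

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=np.float64)


def _wls_line(x, y, w):
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    return beta  # (intercept, slope)


def robust_linefit(x, y) -> RegressionFit:
    """Straight line by iteratively reweighted least squares, bisquare weights.

    Tuning constant 4.685 with MAD-based scale; iterate until the parameter
    change falls below 1e-8 or 50 iterations.  When the residual scale is
    zero (an exact fit) all weights are 1 and the result is the OLS line.
    R^2, RMSE and Pearson r are computed on all points against the robust
    line.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (x, y) points of equal length")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the line fit is undefined")

    beta = _wls_line(x, y, np.ones_like(x))
    n_iter = 0
    for n_iter in range(1, 51):
        resid = y - (beta[0] + beta[1] * x)
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            w = np.ones_like(x)  # exact fit: plain OLS
        else:
            u = resid / (BISQUARE_C * scale)
            w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
            if not w.any():
                w = np.ones_like(x)
        new_beta = _wls_line(x, y, w)
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < 1e-8:
            break

    resid = y - (beta[0] + beta[1] * x)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    pearson = float(stats.pearsonr(x, y).statistic) if np.ptp(y) > 0 else 1.0
    return RegressionFit(slope=float(beta[1]), intercept=float(beta[0]),
                         r2=r2, rmse=rmse, pearson_r=pearson, iterations=n_iter)


# ---- summaries -------------------------------------------------------------


@dataclass
class ErrorStats:
    """Moments and box statistics of a set of percentage errors."""

    mean_pct: float
    sd_pct: float
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    n: int
    n_undefined: int = 0

    @classmethod
    def from_errors(cls, errors, n_undefined: int = 0) -> "ErrorStats":
        e = np.asarray(errors, dtype=np.float64).ravel()
        e = e[np.isfinite(e)]
        if e.size == 0:
            raise ValueError("no finite errors to summarize")
        # type-7 (linear interpolation) quartiles
        q1, med, q3 = np.percentile(e, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - WHISKER_W * iqr, q3 + WHISKER_W * iqr
        inside = e[(e >= lo_fence) & (e <= hi_fence)]
        return cls(mean_pct=float(e.mean()), sd_pct=float(e.std(ddof=1)) if e.size > 1 else 0.0,
                   median=float(med), q1=float(q1), q3=float(q3),
                   whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
                   outliers=np.sort(e[(e < lo_fence) | (e > hi_fence)]),
                   n=int(e.size), n_undefined=n_undefined)


@dataclass
class EvalReport:
    """Per-stage and pooled accuracy of one estimation model."""

    model_name: str
    per_stage: dict[int, tuple[ErrorStats, float]]  # stage -> (stats, pearson r)
    pooled: RegressionFit
    n_train: int
    n_test: int
    observed: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    estimated: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    stages: np.ndarray = field(default_factory=lambda: np.empty(0, int), repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for stage in sorted(self.per_stage):
            st, r = self.per_stage[stage]
            rows.append({"model": self.model_name, "stage": stage,
                         "mean_pct": st.mean_pct, "sd_pct": st.sd_pct, "r": r,
                         "median": st.median, "q1": st.q1, "q3": st.q3,
                         "whisker_lo": st.whisker_lo, "whisker_hi": st.whisker_hi,
                         "n": st.n, "n_undefined": st.n_undefined})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "model": self.model_name,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "pooled": {"slope": self.pooled.slope, "intercept": self.pooled.intercept,
                       "r2": self.pooled.r2, "rmse": self.pooled.rmse,
                       "pearson_r": self.pooled.pearson_r},
            "per_stage": {str(k): {"mean_pct": v[0].mean_pct, "sd_pct": v[0].sd_pct,
                                   "r": v[1], "n": v[0].n}
                          for k, v in sorted(self.per_stage.items())},
        }

    def summary(self) -> str:
        lines = [f"Model: {self.model_name}   (train n={self.n_train}, test n={self.n_test})",
                 f"Pooled robust fit: est = {self.pooled.slope:.4f} * obs "
                 f"+ {self.pooled.intercept:+.4f}",
                 f"  R2 = {self.pooled.r2:.4f}   RMSE = {self.pooled.rmse:.4f}   "
                 f"r = {self.pooled.pearson_r:.4f}",
                 "Stage   mean%±sd%          r       n"]
        for stage in sorted(self.per_stage):
            st, r = self.per_stage[stage]
            lines.append(f"{stage:>5}   {st.mean_pct:+7.2f} ± {st.sd_pct:6.2f}   "
                         f"{r:6.3f}  {st.n:>6}")
        return "\n".join(lines)

    # -- plotting (optional, matplotlib) ------------------------------------

    def plot_scatter(self, ax=None):
        """Observed vs estimated VI with the pooled robust line."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.scatter(self.observed, self.estimated, s=4, alpha=0.4)
        xs = np.linspace(self.observed.min(), self.observed.max(), 10)
        ax.plot(xs, self.pooled.predict(xs), "r-",
                label=(f"y={self.pooled.slope:.2f}x{self.pooled.intercept:+.2f}\n"
                       f"$R^2$={self.pooled.r2:.3f}, RMSE={self.pooled.rmse:.3f}"))
        ax.set_xlabel("observed VI")
        ax.set_ylabel("estimated VI")
        ax.set_title(self.model_name)
        ax.legend()
        return ax

    def plot_error_boxes(self, ax=None):
        """Percentage-error box statistics per growth stage."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        stages = sorted(self.per_stage)
        boxes = []
        for s in stages:
            st, _ = self.per_stage[s]
            boxes.append({"med": st.median, "q1": st.q1, "q3": st.q3,
                          "whislo": st.whisker_lo, "whishi": st.whisker_hi,
                          "fliers": []})
        ax.bxp(boxes, positions=stages, showfliers=False)
        ax.set_xlabel("growth stage")
        ax.set_ylabel("estimation error (%)")
        ax.set_title(self.model_name)
        return ax


def summarize(observed, estimated, stages, model_name: str = "model",
              n_train: int = 0, n_test: int | None = None) -> EvalReport:
    """Build an :class:`EvalReport` from pooled per-sample results.

    Per stage: mean ± sd of the percentage errors (undefined ones where the
    observed VI is zero are excluded and counted), Pearson r of observed vs
    estimated, and box statistics.  Pooled: robust line fit over all stages.
    """
    obs = np.asarray(observed, dtype=np.float64).ravel()
    est = np.asarray(estimated, dtype=np.float64).ravel()
    stg = np.asarray(stages).ravel()
    if not (obs.size == est.size == stg.size) or obs.size == 0:
        raise ValueError("observed, estimated and stages must be equal-length, non-empty")
    errors = percentage_error(obs, est)
    per_stage: dict[int, tuple[ErrorStats, float]] = {}
    for stage in sorted(set(stg.tolist())):
        m = stg == stage
        e = errors[m]
        n_undef = int(np.isnan(e).sum())
        st = ErrorStats.from_errors(e[~np.isnan(e)], n_undefined=n_undef)
        if np.ptp(obs[m]) > 0 and np.ptp(est[m]) > 0:
            r = float(stats.pearsonr(obs[m], est[m]).statistic)
        else:
            r = float("nan")
        per_stage[int(stage)] = (st, r)
    try:
        pooled = robust_linefit(obs, est)
    except ValueError:
        # degenerate pooled data (e.g. constant observed values): the
        # stagewise statistics stand, the pooled line is undefined
        pooled = RegressionFit(slope=float("nan"), intercept=float("nan"),
                               r2=float("nan"), rmse=float("nan"),
                               pearson_r=float("nan"))
    return EvalReport(model_name=model_name, per_stage=per_stage, pooled=pooled,
                      n_train=n_train, n_test=n_test if n_test is not None else obs.size,
                      observed=obs, estimated=est, stages=stg.astype(int))
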