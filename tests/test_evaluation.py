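"""Cross-validation folds, percentage errors, robust regression and the
box-statistics summaries, checked against brute-force and statsmodels oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plotvi.evaluation import (ErrorStats, FoldError, make_bay_folds,
                               percentage_error, robust_linefit, split_by_fold,
                               summarize)
from plotvi.synthetic import PlotObservation


def obs_layout(n_bays=3, n_plots=4, n_stages=2):
    return [PlotObservation(f"b{b}-p{p}", f"bay{b + 1}", s)
            for b in range(n_bays) for s in range(n_stages) for p in range(n_plots)]


class TestBayFolds:
    def test_three_bays_three_complementary_folds(self):
        samples = obs_layout()
        folds = make_bay_folds(samples)
        assert [(f.train_bays, f.test_bay) for f in folds] == [
            (("bay2", "bay3"), "bay1"),
            (("bay1", "bay3"), "bay2"),
            (("bay1", "bay2"), "bay3")]

    def test_full_layout_fold_sizes(self):
        # 576 plots x 7 stages: train 8064 (2 bays), test 4032 (1 bay)
        samples = obs_layout(3, 576, 7)
        for fold in make_bay_folds(samples):
            train, test = split_by_fold(samples, fold)
            assert (len(train), len(test)) == (8064, 4032)

    def test_test_sets_partition_all_samples(self):
        samples = obs_layout()
        seen = []
        for fold in make_bay_folds(samples):
            _train, test = split_by_fold(samples, fold)
            seen.extend(id(s) for s in test)
        assert sorted(seen) == sorted(id(s) for s in samples)

    def test_single_bay_raises(self):
        with pytest.raises(FoldError):
            make_bay_folds(obs_layout(n_bays=1))


class TestPercentageError:
    def test_underestimate_is_positive(self):
        assert percentage_error(0.5, 0.49) == pytest.approx(2.0, abs=1e-9)

    def test_equal_values_zero(self):
        assert percentage_error(0.37, 0.37) == 0.0

    def test_overestimate_is_negative(self):
        assert percentage_error(0.4, 0.5) == pytest.approx(-25.0, abs=1e-9)

    def test_zero_observed_flagged_nan(self):
        out = percentage_error([0.0, 0.5], [0.1, 0.5])
        assert np.isnan(out[0]) and out[1] == 0.0


class TestRobustLinefit:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 20)
        fit = robust_linefit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_outlier_influences_robust_fit_less_than_ols(self):
        x = np.linspace(0, 1, 30)
        y = 2 * x + 1.0
        y[7] += 10.0  # gross outlier
        # closed-form OLS oracle via the normal equations
        design = np.column_stack([np.ones_like(x), x])
        ols = np.linalg.solve(design.T @ design, design.T @ y)
        fit = robust_linefit(x, y)
        assert abs(fit.slope - 2.0) < abs(ols[1] - 2.0)
        assert abs(fit.intercept - 1.0) < abs(ols[0] - 1.0)

    def test_identity_data_perfect_correlation(self):
        x = np.linspace(0.1, 0.9, 15)
        assert robust_linefit(x, x).pearson_r == pytest.approx(1.0)

    def test_equals_ols_when_all_weights_unity(self):
        # an exact fit has zero scale, so every bisquare weight is 1 and the
        # robust solution must coincide with ordinary least squares
        x = np.linspace(0, 2, 9)
        y = -0.5 * x + 0.3
        design = np.column_stack([np.ones_like(x), x])
        ols = np.linalg.solve(design.T @ design, design.T @ y)
        fit = robust_linefit(x, y)
        assert fit.intercept == pytest.approx(ols[0], abs=1e-10)
        assert fit.slope == pytest.approx(ols[1], abs=1e-10)

    def test_agrees_with_statsmodels_rlm_on_noisy_data(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.uniform(0, 1, 200)
        y = 1.5 * x + 0.2 + rng.normal(0, 0.05, 200)
        y[::25] += rng.normal(0, 1.0, 8)  # contamination
        fit = robust_linefit(x, y)
        rlm = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(4.685))
        res = rlm.fit(scale_est="mad")
        assert fit.intercept == pytest.approx(res.params[0], abs=5e-3)
        assert fit.slope == pytest.approx(res.params[1], abs=5e-3)

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            robust_linefit(np.full(5, 0.3), np.arange(5.0))


class TestErrorStats:
    @staticmethod
    def brute_force(errors, w=1.5):
        e = sorted(errors)
        q1, med, q3 = (np.percentile(e, q) for q in (25, 50, 75))
        iqr = q3 - q1
        inside = [v for v in e if q1 - w * iqr <= v <= q3 + w * iqr]
        out = [v for v in e if v < q1 - w * iqr or v > q3 + w * iqr]
        return med, q1, q3, min(inside), max(inside), out

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=20))
    def test_box_statistics_match_bruteforce_oracle(self, errors):
        st_ = ErrorStats.from_errors(errors)
        med, q1, q3, lo, hi, out = self.brute_force(errors)
        assert st_.median == pytest.approx(med, abs=1e-9)
        assert st_.q1 == pytest.approx(q1, abs=1e-9)
        assert st_.q3 == pytest.approx(q3, abs=1e-9)
        assert st_.whisker_lo == pytest.approx(lo, abs=1e-9)
        assert st_.whisker_hi == pytest.approx(hi, abs=1e-9)
        np.testing.assert_allclose(st_.outliers, sorted(out), atol=1e-9)

    def test_single_extreme_value_flagged_outlier(self):
        st_ = ErrorStats.from_errors([0.0, 0.0, 0.0, 100.0])
        np.testing.assert_allclose(st_.outliers, [100.0])
        assert st_.whisker_hi == 0.0

    def test_quartiles_bracket_median(self, rng):
        st_ = ErrorStats.from_errors(rng.normal(0, 5, 50))
        assert st_.q1 <= st_.median <= st_.q3


class TestSummarize:
    def test_symmetric_triple_moments(self):
        obs = np.array([1.0, 1.0, 1.0])
        est = obs - obs * np.array([0.01, 0.02, 0.03])  # errors 1, 2, 3 %
        rep = summarize(np.tile(obs, 2), np.tile(est, 2),
                        stages=[0, 0, 0, 1, 1, 1], model_name="m")
        st0 = rep.per_stage[0][0]
        assert st0.mean_pct == pytest.approx(2.0, abs=1e-9)
        assert st0.median == pytest.approx(2.0, abs=1e-9)

    def test_identical_stage_groups_get_identical_rows(self, rng):
        obs = rng.uniform(0.2, 0.8, 10)
        est = obs + rng.normal(0, 0.02, 10)
        rep = summarize(np.tile(obs, 2), np.tile(est, 2),
                        stages=[0] * 10 + [1] * 10, model_name="m")
        a, b = rep.per_stage[0], rep.per_stage[1]
        assert a[0].mean_pct == b[0].mean_pct and a[1] == b[1]

    def test_zero_observed_excluded_and_counted(self):
        obs = np.array([0.0, 0.5, 0.4, 0.8, 0.3])
        est = np.array([0.1, 0.5, 0.4, 0.7, 0.35])
        rep = summarize(obs, est, stages=[0] * 5, model_name="m")
        st0 = rep.per_stage[0][0]
        assert st0.n == 4 and st0.n_undefined == 1

    def test_report_dataframe_shape(self, rng):
        obs = rng.uniform(0.2, 0.8, 30)
        est = obs + rng.normal(0, 0.02, 30)
        rep = summarize(obs, est, stages=np.repeat([0, 1, 2], 10), model_name="m")
        df = rep.to_dataframe()
        assert list(df.stage) == [0, 1, 2]
        assert {"mean_pct", "sd_pct", "r", "median"} <= set(df.columns)
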