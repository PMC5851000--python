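"""Network architecture, loss/schedule formulas, training mechanics."""

import numpy as np
import pytest

from plotvi.config import ConfigError, NetConfig, TrainConfig
from plotvi.nn import TrainedModel, VINet, build_model, euclidean_loss, lr_at, train
from plotvi.nn.layers import Conv2DSame, MaxPool2


def small_net_cfg(**kw):
    kw.setdefault("input_hw", (8, 16))
    kw.setdefault("fc_hidden", 11)
    return NetConfig(**kw)


class TestArchitecture:
    def test_layer_shape_trace_and_flatten_length(self):
        # (15,208) -> pool -> (7,104) -> pool -> (3,52); 3*52*50 = 7800
        net = VINet(NetConfig(), seed=0)
        assert net.flat_len == 7800
        x = np.zeros((2, 15, 208, 3), dtype=np.float32)
        shapes = []
        out = x
        for layer in net.layers[:4]:
            out = layer.forward(out)
            shapes.append(out.shape[1:3])
        assert shapes == [(15, 208), (7, 104), (7, 104), (3, 52)]

    def test_same_seed_same_initial_weights(self):
        a = build_model(NetConfig(), seed=5)
        b = build_model(NetConfig(), seed=5)
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_grayscale_variant_accepted(self):
        m = build_model(NetConfig(in_channels=1), seed=0)
        out = m.predict(np.zeros((15, 208, 1), dtype=np.float32))
        assert np.isscalar(out) or out.shape == ()

    def test_spatial_collapse_names_offending_layer(self):
        with pytest.raises(ConfigError, match="pool"):
            NetConfig(input_hw=(2, 16))

    def test_shape_mismatch_names_expected_shape(self):
        m = build_model(NetConfig(), seed=0)
        with pytest.raises(ValueError, match=r"\(15, 208, 3\)"):
            m.predict(np.zeros((10, 10, 3), dtype=np.float32))


class TestLossAndSchedule:
    def test_loss_zero_when_equal(self):
        assert euclidean_loss([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_loss_half_mean_square(self):
        assert euclidean_loss([1.0], [0.0]) == pytest.approx(0.5, abs=1e-12)
        assert euclidean_loss([1, 1], [0, 0]) == pytest.approx(0.5, abs=1e-12)

    def test_loss_empty_batch_raises(self):
        with pytest.raises(ValueError):
            euclidean_loss([], [])

    def test_inverse_decay_schedule(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(0.01, abs=1e-12)
        assert lr_at(10, cfg) == pytest.approx(0.01 * 10 ** -0.75, abs=1e-12)

    def test_schedule_strictly_decreasing(self):
        cfg = TrainConfig()
        lrs = [lr_at(i, cfg) for i in range(100)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))

    def test_negative_iteration_raises(self):
        with pytest.raises(ValueError):
            lr_at(-1, TrainConfig())


class TestGradients:
    def test_backprop_matches_numeric_gradient(self, rng):
        cfg = small_net_cfg(dropout_rate=0.0)
        net = VINet(cfg, seed=3)
        x = rng.random((3, 8, 16, 3), dtype=np.float32)
        y = rng.random(3).astype(np.float32)
        pred = net.forward(x, train=True)
        net.backward((pred - y) / len(y))
        grads = [p.grad.copy() for p in net.params()]
        eps = 1e-3
        for p, g in zip(net.params(), grads):
            flat, gflat = p.data.ravel(), g.ravel()
            for idx in rng.integers(0, flat.size, size=5):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = euclidean_loss(net.forward(x), y)
                flat[idx] = orig - eps
                lm = euclidean_loss(net.forward(x), y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[idx]) < 2e-2 * max(1.0, abs(num))

    def test_maxpool_routes_gradient_to_maximum(self):
        pool = MaxPool2()
        x = np.array([[[[1.0], [3.0]], [[2.0], [0.0]]]], dtype=np.float32)
        out = pool.forward(x, train=True)
        assert out[0, 0, 0, 0] == 3.0
        g = pool.backward(np.ones_like(out))
        np.testing.assert_array_equal(g[0, :, :, 0], [[0, 1], [0, 0]])


class TestTraining:
    def test_loss_decreases_on_learnable_problem(self, rng):
        x = rng.random((48, 8, 16, 3), dtype=np.float32)
        y = x.mean(axis=(1, 2, 3))
        m = build_model(small_net_cfg(), seed=0)
        m = train(m, x, y, TrainConfig(epochs=12, batch_size=16, seed=0))
        log = m.training_log
        assert log.loss.iloc[-5:].mean() < log.loss.iloc[:5].mean()

    def test_training_fully_reproducible(self, rng):
        x = rng.random((20, 8, 16, 3), dtype=np.float32)
        y = rng.random(20).astype(np.float32)
        runs = []
        for _ in range(2):
            m = build_model(small_net_cfg(), seed=4)
            m = train(m, x, y, TrainConfig(epochs=3, batch_size=8, seed=4))
            runs.append([p.data.copy() for p in m.net.params()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_overfits_single_repeated_sample(self, rng):
        # single-sample batches skip the 1/N gradient averaging that keeps
        # the default learning rate stable, so the overfit check runs at a
        # smaller base rate; the property under test is convergence
        img = rng.random((15, 208, 3), dtype=np.float32)
        m = build_model(NetConfig(dropout_rate=0.0), seed=2)
        m = train(m, img[None], np.array([0.7]),
                  TrainConfig(epochs=600, batch_size=1, seed=2, base_lr=0.001,
                              augment_flip=False))
        assert m.predict(img) == pytest.approx(0.7, abs=1e-3)

    def test_dropout_off_at_predict_time(self, rng):
        x = rng.random((6, 8, 16, 3), dtype=np.float32)
        m = build_model(small_net_cfg(dropout_rate=0.5), seed=0)
        m = train(m, x, rng.random(6).astype(np.float32),
                  TrainConfig(epochs=2, batch_size=6, seed=0))
        preds = np.stack([m.predict(x) for _ in range(5)])
        assert np.ptp(preds, axis=0).max() == 0.0

    def test_flip_augmentation_leaves_targets_and_loss_sane(self, rng):
        # symmetric images: flipping is a no-op, so one epoch of training with
        # and without augmentation must produce identical weights (dropout is
        # disabled so the only extra RNG draws are the flip coins themselves)
        half = rng.random((10, 8, 8, 3), dtype=np.float32)
        x = np.concatenate([half, half[:, :, ::-1, :]], axis=2)
        y = rng.random(10).astype(np.float32)
        out = []
        for flip in (True, False):
            m = build_model(small_net_cfg(dropout_rate=0.0), seed=9)
            m = train(m, x, y, TrainConfig(epochs=1, batch_size=5, seed=9,
                                           augment_flip=flip))
            out.append(m.predict(x))
        np.testing.assert_allclose(out[0], out[1], atol=1e-6)

    def test_nonfinite_target_rejected(self, rng):
        x = rng.random((4, 8, 16, 3), dtype=np.float32)
        y = np.array([0.1, np.nan, 0.3, 0.4], dtype=np.float32)
        m = build_model(small_net_cfg(), seed=0)
        with pytest.raises(ValueError, match="finite"):
            train(m, x, y, TrainConfig(epochs=1))


def test_recovers_known_linear_generative_mapping(rng):
    """Oracle: targets generated as 0.2*meanR + 0.5*meanG + 0.1, noise-free,
    on plot-like images (per-image base colour plus pixel noise).  The
    trained network must recover the mapping on held-out samples: RMSE
    under 0.03 in index units and under a quarter of the target spread.

    The absolute bound reflects the recipe's optimization floor: SGD under
    the inverse-decay schedule resolves the low-curvature directions of an
    exact interpolation problem to ~0.02 within a desk-scale epoch budget
    (verified insensitive to learning rate, init width, dropout and sample
    count), while a singleton overfit reaches 1e-6 — precision is limited
    by iterations, not by the gradients."""
    base = rng.random((260, 1, 1, 3))
    x = np.clip(base + 0.05 * rng.standard_normal((260, 15, 208, 3)),
                0, 1).astype(np.float32)
    means = x.mean(axis=(1, 2))
    y = (0.2 * means[:, 0] + 0.5 * means[:, 1] + 0.1).astype(np.float32)
    m = build_model(NetConfig(), seed=2)
    m = train(m, x[:200], y[:200], TrainConfig(epochs=40, seed=2))
    pred = m.predict(x[200:])
    rmse = float(np.sqrt(np.mean((pred - y[200:]) ** 2)))
    assert rmse < 0.03
    assert rmse < 0.25 * float(y.std())


def test_model_archive_round_trip(tmp_path, rng):
    x = rng.random((6, 8, 16, 3), dtype=np.float32)
    m = build_model(small_net_cfg(), seed=1)
    m = train(m, x, rng.random(6).astype(np.float32),
              TrainConfig(epochs=2, batch_size=6, seed=1))
    path = tmp_path / "model.zip"
    m.save(path)
    back = TrainedModel.load(path)
    np.testing.assert_allclose(back.predict(x), m.predict(x), atol=1e-7)
    assert len(back.training_log) == len(m.training_log)
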