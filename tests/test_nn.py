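"""Layers, loss, network and training loop."""

import numpy as np
import pytest

from sparsepet.nn import NetConfig, TrainConfig, batches_per_epoch, build_network
from sparsepet.nn.layers import BatchNorm2d, Conv2d, ConvTranspose2x2, ReLU
from sparsepet.nn.loss import (
    composite_loss,
    composite_loss_and_grad,
    gaussian_kernel1d,
    masked_mae,
    ssim,
)
from sparsepet.nn.train import train
from sparsepet.nn.unet import ResidualUNet


class TestLayers:
    @pytest.mark.parametrize("stride,H,W", [(1, 12, 10), (1, 9, 7), (2, 12, 10), (2, 9, 7)])
    def test_conv_matches_float64_reference(self, stride, H, W):
        rng = np.random.default_rng(3)
        c = Conv2d(3, 4, 3, stride=stride, rng=rng)
        x = rng.standard_normal((2, H, W, 3)).astype(np.float32)
        y = c.forward(x.copy())
        dy = rng.standard_normal(y.shape).astype(np.float32)
        dx = c.backward(dy)
        # independent float64 reference via explicit shifted sums
        k, p, s = 3, 1, stride
        Wt = c.params["W"].astype(np.float64)
        xp = np.pad(x.astype(np.float64), ((0, 0), (p, p), (p, p), (0, 0)))
        Ho, Wo = y.shape[1], y.shape[2]
        yref = np.zeros((2, Ho, Wo, 4))
        dxp = np.zeros_like(xp)
        dWr = np.zeros_like(Wt)
        d64 = dy.astype(np.float64)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :]
                yref += patch @ Wt[i, j]
                dWr[i, j] = np.einsum("bhwc,bhwf->cf", patch, d64)
                dxp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] += d64 @ Wt[i, j].T
        yref += c.params["b"]
        assert np.allclose(y, yref, atol=1e-5)
        assert np.allclose(dx, dxp[:, p:p + H, p:p + W, :], atol=1e-5)
        assert np.allclose(c.grads["W"], dWr, atol=1e-4)
        assert np.allclose(c.grads["b"], d64.sum(axis=(0, 1, 2)), atol=1e-4)

    def test_convtranspose_matches_scatter_reference(self):
        rng = np.random.default_rng(4)
        t = ConvTranspose2x2(3, 2, rng=rng)
        x = rng.standard_normal((2, 5, 4, 3)).astype(np.float32)
        y = t.forward(x.copy())
        assert y.shape == (2, 10, 8, 2)
        Wt = t.params["W"].astype(np.float64)
        yref = np.zeros((2, 10, 8, 2))
        for h in range(5):
            for w in range(4):
                for dh in range(2):
                    for dw in range(2):
                        yref[:, 2 * h + dh, 2 * w + dw, :] += (
                            x[:, h, w, :].astype(np.float64) @ Wt[:, dh, dw, :]
                        )
        yref += t.params["b"]
        assert np.allclose(y, yref, atol=1e-5)
        # adjoint property: <y, T(x)> == <T^*(y), x> (ignoring bias)
        dy = rng.standard_normal(y.shape).astype(np.float32)
        dx = t.backward(dy)
        lhs = np.sum((y - t.params["b"]).astype(np.float64) * dy)
        rhs = np.sum(dx.astype(np.float64) * x)
        assert lhs == pytest.approx(rhs, rel=1e-4)

    def test_batchnorm_statistics_and_gradient(self):
        rng = np.random.default_rng(5)
        bn = BatchNorm2d(3)
        x = rng.standard_normal((4, 6, 5, 3)).astype(np.float32) * 2 + 1
        y = bn.forward(x, training=True)
        assert np.allclose(y.mean(axis=(0, 1, 2)), 0, atol=1e-5)
        assert np.allclose(y.std(axis=(0, 1, 2)), 1, atol=1e-3)
        # gradient of sum(y*dy) wrt x via central differences (float64 path
        # is approximated; tolerance reflects float32 arithmetic)
        dy = rng.standard_normal(y.shape).astype(np.float32)
        dx = bn.backward(dy)

        def f(xv):
            b2 = BatchNorm2d(3)
            return float(np.sum(b2.forward(xv.astype(np.float32)) * dy))

        eps = 1e-2
        for _ in range(5):
            ix = tuple(rng.integers(0, s) for s in x.shape)
            xp = x.copy(); xp[ix] += eps
            xm = x.copy(); xm[ix] -= eps
            num = (f(xp) - f(xm)) / (2 * eps)
            assert num == pytest.approx(float(dx[ix]), abs=5e-2)

    def test_batchnorm_eval_uses_running_stats(self):
        rng = np.random.default_rng(6)
        bn = BatchNorm2d(2)
        for _ in range(50):
            bn.forward(rng.standard_normal((8, 4, 4, 2)).astype(np.float32) * 3 + 2)
        x = np.zeros((1, 4, 4, 2), dtype=np.float32)
        y = bn.forward(x, training=False)
        expected = (0 - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
        assert np.allclose(y[0, 0, 0], expected, atol=1e-5)

    def test_relu(self):
        r = ReLU()
        x = np.array([[-1.0, 2.0]], dtype=np.float32)[None, ..., None]
        y = r.forward(x)
        assert np.array_equal(y.ravel(), [0.0, 2.0])
        dx = r.backward(np.ones_like(y))
        assert np.array_equal(dx.ravel(), [0.0, 1.0])


class TestNetConfig:
    def test_defaults(self):
        cfg = NetConfig()
        assert cfg.depth == 4 and cfg.base_filters == 32
        assert cfg.res_blocks_per_level == (1, 2, 3, 4)

    def test_validation(self):
        with pytest.raises(ValueError):
            NetConfig(depth=2, base_filters=8, res_blocks_per_level=(1,))
        with pytest.raises(ValueError):
            NetConfig(depth=2, base_filters=8, res_blocks_per_level=(2, 1))
        with pytest.raises(ValueError):
            NetConfig(depth=0, base_filters=8, res_blocks_per_level=())


class TestResidualUNet:
    def test_parameter_count_hand_check(self):
        """depth=1, base_filters=4, one residual block per level, counted by
        hand: stem 40, encoder block 312, downsample 296+16, bottleneck 1200,
        up 132, decoder block 312, final 148+37."""
        net = build_network(NetConfig(1, 4, (1,)), seed=0)
        conv = lambda ci, co: 9 * ci * co + co
        bn = lambda c: 2 * c
        res = lambda c: 2 * conv(c, c) + 2 * bn(c)
        expected = (
            conv(1, 4)            # stem
            + res(4)              # encoder level 0
            + conv(4, 8) + bn(8)  # downsample
            + res(8)              # bottleneck
            + (4 * 8 * 4 + 4)     # transposed conv 8->4
            + res(4)              # decoder level 0
            + conv(4, 4)          # final1
            + conv(4, 1)          # final2
        )
        assert net.n_parameters() == expected == 2493

    def test_output_shape_and_padding(self):
        net = build_network(NetConfig(2, 4, (1, 1)), seed=0)
        x = np.random.default_rng(0).random((3, 33, 30)).astype(np.float32)
        y = net.forward(x)
        assert y.shape == x.shape

    def test_too_small_input_rejected(self):
        net = build_network(NetConfig(4, 4, (1, 1, 1, 1)), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 8, 8), dtype=np.float32))

    def test_state_round_trip(self):
        net = build_network(NetConfig(2, 4, (1, 1)), seed=1)
        rng = np.random.default_rng(2)
        x = rng.random((2, 16, 16)).astype(np.float32)
        net.forward(x)  # populate batchnorm running statistics
        y_ref = net.predict(x)
        state = {k: v.copy() for k, v in net.state_arrays().items()}
        other = build_network(NetConfig(2, 4, (1, 1)), seed=99)
        other.load_state_arrays(state)
        assert np.array_equal(other.predict(x), y_ref)

    def test_whole_net_gradient_direction(self):
        """A single Adam-free gradient step along -grad must not increase a
        smooth surrogate loss (sum of squares) at small step size."""
        net = build_network(NetConfig(1, 4, (1,)), seed=3)
        rng = np.random.default_rng(4)
        x = rng.random((2, 16, 16)).astype(np.float32)
        y = rng.random((2, 16, 16)).astype(np.float32)

        def loss_and_grad():
            pred = net.forward(x)
            return float(np.sum((pred - y) ** 2)), (2 * (pred - y)).astype(np.float32)

        l0, g = loss_and_grad()
        net.backward(g)
        lr = 1e-4
        for layer in net.layers():
            for k in layer.params:
                layer.params[k] -= lr * layer.grads[k]
        l1, _ = loss_and_grad()
        assert l1 < l0


class TestLoss:
    def test_gaussian_kernel_normalised(self):
        k = gaussian_kernel1d(11, 1.5)
        assert k.shape == (11,)
        assert k.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.array_equal(k, k[::-1])

    def test_ssim_identity_is_one(self):
        x = np.random.default_rng(0).random((20, 20))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_ssim_against_skimage(self):
        skimage = pytest.importorskip("skimage.metrics")
        rng = np.random.default_rng(1)
        y = rng.random((24, 26))
        yhat = np.clip(y + 0.1 * rng.standard_normal(y.shape), 0, 1)
        ours = ssim(yhat, y, data_range=1.0)
        theirs = skimage.structural_similarity(
            y, yhat, data_range=1.0, gaussian_weights=True, sigma=1.5,
            win_size=11, use_sample_covariance=False,
        )
        assert ours == pytest.approx(theirs, abs=1e-7)

    def test_masked_mae(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[1.5, 2.0], [0.0, 4.0]])
        m = np.array([[True, False], [True, False]])
        assert masked_mae(a, b, m) == pytest.approx((0.5 + 3.0) / 2)
        with pytest.raises(ValueError):
            masked_mae(a, b, np.zeros_like(m))

    def test_composite_loss_perfect_prediction(self):
        y = np.random.default_rng(2).random((2, 20, 20))
        m = np.ones_like(y, dtype=bool)
        assert composite_loss(y, y, m) == pytest.approx(0.0, abs=1e-9)

    def test_composite_loss_empty_mask_warns(self):
        y = np.random.default_rng(3).random((1, 20, 20))
        with pytest.warns(UserWarning):
            composite_loss(y, y, np.zeros_like(y, dtype=bool))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        y = rng.random((2, 18, 17))
        yhat = np.clip(y + 0.2 * rng.standard_normal(y.shape), 0, 1)
        m = rng.random(y.shape) > 0.4
        loss, grad = composite_loss_and_grad(yhat, y, m)
        assert loss == pytest.approx(composite_loss(yhat, y, m), rel=1e-12)
        eps = 1e-6
        for _ in range(10):
            ix = tuple(rng.integers(0, s) for s in y.shape)
            yp = yhat.copy(); yp[ix] += eps
            ym = yhat.copy(); ym[ix] -= eps
            num = (composite_loss(yp, y, m) - composite_loss(ym, y, m)) / (2 * eps)
            assert num == pytest.approx(float(grad[ix]), abs=1e-6)


class TestTraining:
    def test_batches_per_epoch(self):
        assert batches_per_epoch(23772, 64) == 372
        assert batches_per_epoch(64, 64) == 1
        assert batches_per_epoch(65, 64) == 2

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=200, max_epochs=200)
        with pytest.raises(ValueError):
            TrainConfig(lr0=0.0)

    def test_staircase_decay_and_history(self):
        rng = np.random.default_rng(6)
        x = rng.random((20, 16, 16)).astype(np.float32)
        m = np.ones_like(x, dtype=bool)
        net = build_network(NetConfig(1, 4, (1,)), seed=0)
        cfg = TrainConfig(max_epochs=3, patience=2, batch_size=8, seed=0)
        net, history = train(net, x, x, m, x[:4], x[:4], m[:4], cfg)
        assert [h["epoch"] for h in history] == [0, 1, 2]
        for h in history:
            assert h["lr"] == pytest.approx(cfg.lr0 * cfg.decay_rate ** h["epoch"])

    def test_training_reduces_loss(self):
        """Inpainting smooth images (a structured, learnable task) must
        improve the validation loss substantially."""
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(7)
        y = gaussian_filter(rng.random((24, 16, 16)), sigma=(0, 2, 2))
        y = (y / y.max()).astype(np.float32)
        holes = rng.random(y.shape) > 0.5
        x = (y * holes).astype(np.float32)
        m = np.ones_like(y, dtype=bool)
        net = build_network(NetConfig(1, 4, (1,)), seed=1)
        cfg = TrainConfig(max_epochs=60, patience=59, batch_size=8, seed=0)
        net, history = train(net, x[:20], y[:20], m[:20], x[20:], y[20:], m[20:], cfg)
        # steady learning: clear overall reduction and a decreasing trend
        assert history[-1]["val_loss"] < 0.75 * history[0]["val_loss"]
        losses = [h["val_loss"] for h in history]
        assert min(losses[-10:]) < min(losses[:10])

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        x = rng.random((12, 16, 16)).astype(np.float32)
        m = np.ones_like(x, dtype=bool)
        cfg = TrainConfig(max_epochs=2, patience=1, batch_size=4, seed=5)
        runs = []
        for _ in range(2):
            net = build_network(NetConfig(1, 4, (1,)), seed=2)
            net, history = train(net, x, x, m, x[:2], x[:2], m[:2], cfg)
            runs.append((net.predict(x), history[-1]["val_loss"]))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_nan_raises(self):
        x = np.full((8, 16, 16), np.nan, dtype=np.float32)
        m = np.ones_like(x, dtype=bool)
        net = build_network(NetConfig(1, 4, (1,)), seed=0)
        cfg = TrainConfig(max_epochs=2, patience=1, batch_size=4, seed=0)
        with pytest.raises(RuntimeError):
            train(net, x, x, m, x[:2], x[:2], m[:2], cfg)
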