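"""The autodiff core: forward values against independent references
(scipy.signal for convolution) and gradients against finite differences."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from msfaseg.nn import autodiff as ad
from msfaseg.nn.autodiff import Tensor
from msfaseg.nn.layers import BatchNorm2d, Conv2d, ConvTranspose2d, Dense, Dropout


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_close_grad(analytic, numeric, tol=5e-3):
    scale = max(np.abs(numeric).max(), 1e-6)
    assert np.abs(analytic - numeric).max() / scale < tol


class TestConv2d:
    def test_forward_matches_scipy_correlate(self, rng):
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        w = rng.standard_normal((4, 27)).astype(np.float32)
        b = rng.standard_normal(4).astype(np.float32)
        y = ad.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=1, pad=1).data
        w4 = w.reshape(4, 3, 3, 3)
        for n in range(2):
            for f in range(4):
                ref = b[f] + sum(correlate2d(x[n, c], w4[f, c], mode="same")
                                 for c in range(3))
                np.testing.assert_allclose(y[n, f], ref, atol=1e-4)
        # stride 2 is the stride-1 result sampled at even offsets
        y2 = ad.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=2, pad=1).data
        np.testing.assert_allclose(y2, y[:, :, ::2, ::2], atol=1e-5)

    @pytest.mark.parametrize("stride,kernel", [(1, 3), (2, 3), (1, 1)])
    def test_gradients_match_finite_differences(self, rng, stride, kernel):
        C, F = 3, 2
        pad = kernel // 2
        x = Tensor(rng.standard_normal((2, C, 6, 6)).astype(np.float32),
                   requires_grad=True)
        w = Tensor((rng.standard_normal((F, C * kernel * kernel)) * 0.4)
                   .astype(np.float32), requires_grad=True)
        b = Tensor(rng.standard_normal(F).astype(np.float32), requires_grad=True)

        def loss():
            y = ad.conv2d(Tensor(x.data), Tensor(w.data), Tensor(b.data),
                          stride=stride, pad=pad)
            return float((y.data ** 2).sum())

        y = ad.conv2d(x, w, b, stride=stride, pad=pad)
        y._backward(2 * y.data)
        for p in (x, w, b):
            assert_close_grad(p.grad, numeric_grad(loss, p.data))


class TestConvTranspose2d:
    def test_doubles_spatial_dims(self, rng):
        layer = ConvTranspose2d(3, 5, rng)
        y = layer(Tensor(rng.standard_normal((2, 3, 7, 7)).astype(np.float32)))
        assert y.data.shape == (2, 5, 14, 14)

    def test_adjoint_of_strided_conv(self, rng):
        # transposed conv with weight W is the adjoint of the stride-2 conv
        # with the same W: <conv(y), x> == <conv^T(x), y>
        w = rng.standard_normal((3, 2 * 9)).astype(np.float32)
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        y = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
        up = ad.conv_transpose2d(Tensor(x), Tensor(w), None, (8, 8)).data
        down = ad.conv2d(Tensor(y), Tensor(w), None, stride=2, pad=1).data
        assert float((down * x).sum()) == pytest.approx(float((up * y).sum()),
                                                        rel=1e-4)

    def test_gradients_match_finite_differences(self, rng):
        x = Tensor(rng.standard_normal((2, 2, 3, 3)).astype(np.float32),
                   requires_grad=True)
        w = Tensor((rng.standard_normal((2, 2 * 9)) * 0.4).astype(np.float32),
                   requires_grad=True)
        b = Tensor(rng.standard_normal(2).astype(np.float32), requires_grad=True)

        def loss():
            y = ad.conv_transpose2d(Tensor(x.data), Tensor(w.data),
                                    Tensor(b.data), (6, 6))
            return float((y.data ** 2).sum())

        y = ad.conv_transpose2d(x, w, b, (6, 6))
        y._backward(2 * y.data)
        for p in (x, w, b):
            assert_close_grad(p.grad, numeric_grad(loss, p.data))


class TestBatchNorm:
    def test_training_output_standardized(self, rng):
        bn = BatchNorm2d(3)
        x = Tensor(rng.standard_normal((4, 3, 5, 5)).astype(np.float32) * 3 + 1)
        y = bn(x).data
        assert np.abs(y.mean(axis=(0, 2, 3))).max() < 1e-4
        assert np.abs(y.std(axis=(0, 2, 3)) - 1).max() < 1e-3

    def test_eval_uses_running_stats_deterministically(self, rng):
        bn = BatchNorm2d(2)
        for _ in range(10):
            bn(Tensor(rng.standard_normal((4, 2, 6, 6)).astype(np.float32)))
        bn.eval()
        x = Tensor(rng.standard_normal((2, 2, 6, 6)).astype(np.float32))
        np.testing.assert_array_equal(bn(x).data, bn(x).data)

    def test_gradients_match_finite_differences(self, rng):
        x = Tensor(rng.standard_normal((3, 2, 4, 4)).astype(np.float32),
                   requires_grad=True)
        gamma = Tensor(np.array([1.3, 0.6], np.float32), requires_grad=True)
        beta = Tensor(np.array([0.2, -0.4], np.float32), requires_grad=True)

        def loss():
            rm, rv = np.zeros(2, np.float32), np.ones(2, np.float32)
            y = ad.batch_norm_2d(Tensor(x.data), Tensor(gamma.data),
                                 Tensor(beta.data), rm, rv, 0.1, 1e-5, True)
            return float((y.data ** 3).sum())

        rm, rv = np.zeros(2, np.float32), np.ones(2, np.float32)
        y = ad.batch_norm_2d(x, gamma, beta, rm, rv, 0.1, 1e-5, True)
        y._backward(3 * y.data ** 2)
        for p in (x, gamma, beta):
            assert_close_grad(p.grad, numeric_grad(loss, p.data))


class TestElementwiseOps:
    def test_composite_graph_gradient(self, rng):
        # sigmoid(relu(dense(x))) exercised end to end against finite diff
        d = Dense(4, 3, rng)
        x = Tensor(rng.standard_normal((5, 4)).astype(np.float32),
                   requires_grad=True)

        def loss():
            y = ad.sigmoid(ad.relu(
                ad.add(ad.matmul(Tensor(x.data), Tensor(d.weight.data)),
                       Tensor(d.bias.data))))
            return float((y.data ** 2).sum())

        y = ad.sigmoid(ad.relu(d(x)))
        z = ad.mul(y, y)  # backward() seeds ones, giving grad of sum(y^2)
        z.backward()
        assert_close_grad(x.grad, numeric_grad(loss, x.data))

    def test_channel_gate_and_gap(self, rng):
        x = Tensor(rng.standard_normal((2, 3, 4, 4)).astype(np.float32),
                   requires_grad=True)
        s = Tensor(rng.random((2, 3)).astype(np.float32), requires_grad=True)
        y = ad.channel_gate(x, s)
        np.testing.assert_allclose(y.data, x.data * s.data[:, :, None, None])
        g = ad.global_avg_pool(x)
        np.testing.assert_allclose(g.data, x.data.mean(axis=(2, 3)), atol=1e-6)

    def test_concat_channels_backward_splits(self, rng):
        a = Tensor(rng.standard_normal((1, 2, 3, 3)).astype(np.float32),
                   requires_grad=True)
        b = Tensor(rng.standard_normal((1, 3, 3, 3)).astype(np.float32),
                   requires_grad=True)
        y = ad.concat_channels([a, b])
        assert y.data.shape == (1, 5, 3, 3)
        g = np.arange(45, dtype=np.float32).reshape(1, 5, 3, 3)
        y._backward(g)
        np.testing.assert_array_equal(a.grad, g[:, :2])
        np.testing.assert_array_equal(b.grad, g[:, 2:])


class TestDropout:
    def test_eval_mode_is_identity(self, rng):
        layer = Dropout(0.5, seed=0)
        layer.eval()
        x = Tensor(rng.standard_normal((2, 3, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(layer(x).data, x.data)

    def test_train_mode_preserves_expectation(self):
        layer = Dropout(0.3, seed=0)
        x = Tensor(np.ones((1, 1, 100, 100), np.float32))
        y = layer(x).data
        assert y.mean() == pytest.approx(1.0, abs=0.05)
        kept = y[y > 0]
        assert np.allclose(kept, 1 / 0.7, atol=1e-6)
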