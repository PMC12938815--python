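"""Autodiff engine: gradient correctness, layer semantics, optimizer."""

import numpy as np
import pytest

from vsdecode.nn import (Adam, AvgPool3D, BatchNorm, Conv3D, Sequential,
                         Tensor, avgpool_temporal, bce_with_logits, conv3d,
                         differentiable_ssim, no_grad, ssim_loss)


def numeric_grad(f, arr, idx, eps=1e-2):
    orig = arr[idx]
    arr[idx] = orig + eps
    fp = f()
    arr[idx] = orig - eps
    fm = f()
    arr[idx] = orig
    return (fp - fm) / (2 * eps)


class TestAutodiff:
    def test_elementwise_chain_gradient(self, rng):
        x = Tensor(rng.uniform(0.5, 1.5, (4, 5)).astype(np.float32),
                   requires_grad=True)

        def loss():
            t = (x * 2.0 + 1.0).log() * x.sigmoid() - x.pow(2.0) / 3.0
            return t.mean().item()

        val = (x * 2.0 + 1.0).log() * x.sigmoid() - x.pow(2.0) / 3.0
        val.mean().backward()
        for idx in [(0, 0), (2, 3), (3, 4)]:
            assert x.grad[idx] == pytest.approx(
                numeric_grad(loss, x.data, idx), rel=5e-2, abs=1e-4)

    def test_softplus_gradient_is_sigmoid(self, rng):
        from scipy.special import expit
        x = Tensor(rng.standard_normal((3, 3)).astype(np.float32),
                   requires_grad=True)
        x.softplus().sum().backward()
        assert np.allclose(x.grad, expit(x.data), atol=1e-6)

    def test_broadcast_gradient_shapes(self, rng):
        a = Tensor(rng.standard_normal((4, 1, 3)).astype(np.float32),
                   requires_grad=True)
        b = Tensor(rng.standard_normal((3,)).astype(np.float32),
                   requires_grad=True)
        (a * b + b).sum().backward()
        assert a.grad.shape == a.data.shape
        assert b.grad.shape == b.data.shape

    def test_slice_gradient_scatters(self, rng):
        x = Tensor(rng.standard_normal((2, 6, 3)).astype(np.float32),
                   requires_grad=True)
        x[:, :2].sum().backward()
        assert np.all(x.grad[:, :2] == 1.0)
        assert np.all(x.grad[:, 2:] == 0.0)

    def test_no_grad_builds_no_graph(self):
        x = Tensor(np.ones((2, 2), np.float32), requires_grad=True)
        with no_grad():
            y = (x * 3.0).sum()
        assert y._backward is None and not y.requires_grad


class TestConv3D:
    def test_matches_scipy_correlate(self, rng):
        from scipy.ndimage import correlate
        x = rng.standard_normal((1, 5, 7, 7, 1)).astype(np.float32)
        w = rng.standard_normal((3, 3, 3, 1, 1)).astype(np.float32)
        out = conv3d(Tensor(x), Tensor(w), padding="same").data
        want = correlate(x[0, :, :, :, 0], w[:, :, :, 0, 0],
                         mode="constant", cval=0.0)
        assert np.allclose(out[0, :, :, :, 0], want, atol=1e-5)

    def test_weight_gradient_finite_difference(self, rng):
        x = Tensor(rng.standard_normal((2, 4, 6, 6, 2)).astype(np.float32))
        w = Tensor(rng.standard_normal((3, 3, 3, 2, 3)).astype(np.float32) * 0.1,
                   requires_grad=True)
        b = Tensor(np.zeros(3, np.float32), requires_grad=True)

        def loss():
            return float((conv3d(x, w, b).data ** 2).mean())

        out = conv3d(x, w, b)
        (out * out).mean().backward()
        for idx in [(0, 1, 2, 0, 1), (2, 0, 0, 1, 2)]:
            assert w.grad[idx] == pytest.approx(
                numeric_grad(loss, w.data, idx), rel=5e-2, abs=1e-4)
        assert b.grad is not None

    def test_input_gradient_finite_difference(self, rng):
        x = Tensor(rng.standard_normal((1, 3, 5, 5, 1)).astype(np.float32),
                   requires_grad=True)
        w = Tensor(rng.standard_normal((3, 3, 3, 1, 2)).astype(np.float32) * 0.2)

        def loss():
            return float((conv3d(x, w).data ** 2).mean())

        out = conv3d(x, w)
        (out * out).mean().backward()
        for idx in [(0, 1, 2, 2, 0), (0, 0, 0, 0, 0)]:
            assert x.grad[idx] == pytest.approx(
                numeric_grad(loss, x.data, idx), rel=5e-2, abs=1e-4)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conv3d(Tensor(np.zeros((1, 2, 4, 4, 3))),
                   Tensor(np.zeros((1, 3, 3, 2, 1))))


class TestPoolAndNorm:
    def test_avgpool_temporal_block_mean(self, rng):
        x = rng.standard_normal((2, 6, 3, 3, 2)).astype(np.float32)
        out = avgpool_temporal(Tensor(x), 3).data
        want = x.reshape(2, 2, 3, 3, 3, 2).mean(axis=2)
        assert np.allclose(out, want, atol=1e-7)

    def test_avgpool_indivisible_rejected(self):
        with pytest.raises(ValueError):
            avgpool_temporal(Tensor(np.zeros((1, 5, 2, 2, 1))), 2)

    def test_batchnorm_normalizes_per_channel(self, rng):
        bn = BatchNorm(3)
        x = Tensor(rng.standard_normal((4, 5, 6, 6, 3)).astype(np.float32) * 3 + 1)
        y = bn.forward(x, training=True).data
        flat = y.reshape(-1, 3)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-4)
        assert np.allclose(flat.std(axis=0), 1.0, atol=1e-3)

    def test_batchnorm_inference_uses_running_stats(self, rng):
        bn = BatchNorm(2)
        x = rng.standard_normal((2, 3, 4, 4, 2)).astype(np.float32)
        for _ in range(50):
            bn.forward(Tensor(x), training=True)
        y_eval = bn.forward(Tensor(x), training=False).data
        y_train = bn.forward(Tensor(x), training=True).data
        assert np.allclose(y_eval, y_train, atol=5e-2)


class TestLosses:
    def test_bce_closed_form_at_zero_logits(self):
        logits = Tensor(np.zeros((2, 3, 3), np.float32), requires_grad=True)
        loss = bce_with_logits(logits, np.zeros((2, 3, 3), np.float32))
        assert loss.item() == pytest.approx(np.log(2.0), rel=1e-6)

    def test_ssim_loss_zero_for_identical(self, rng):
        img = rng.random((2, 16, 16)).astype(np.float32)
        assert ssim_loss(Tensor(img), img).item() == pytest.approx(0.0, abs=1e-6)

    def test_differentiable_ssim_matches_skimage(self, rng):
        """Dual-route check: autodiff SSIM vs scikit-image reference."""
        from vsdecode.evaluation import ssim as ref_ssim
        a = rng.random((1, 32, 32)).astype(np.float32)
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1).astype(np.float32)
        mine = differentiable_ssim(Tensor(a), b).item()
        ref = ref_ssim(a[0].astype(float), b[0].astype(float))
        assert mine == pytest.approx(ref, abs=2e-3)

    def test_ssim_gradient_direction(self, rng):
        """A gradient step on the prediction increases SSIM toward the target."""
        tgt = rng.random((1, 16, 16)).astype(np.float32)
        pred = Tensor(np.full((1, 16, 16), 0.5, np.float32), requires_grad=True)
        loss = ssim_loss(pred, tgt)
        loss.backward()
        stepped = pred.data - 0.05 * np.sign(pred.grad)
        new_loss = ssim_loss(Tensor(stepped), tgt).item()
        assert new_loss < loss.item()


class TestOptimizer:
    def test_adam_minimizes_quadratic(self):
        x = Tensor(np.array([4.0, -3.0], np.float32), requires_grad=True)
        opt = Adam([x], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = (x * x).sum()
            loss.backward()
            opt.step()
        assert np.all(np.abs(x.data) < 1e-2)

    def test_frozen_parameters_excluded(self):
        x = Tensor(np.ones(2, np.float32), requires_grad=True)
        y = Tensor(np.ones(2, np.float32), requires_grad=False)
        opt = Adam([x, y], lr=0.1)
        assert opt.params == [x]


def test_sequential_digest_tracks_parameters(rng):
    net = Sequential([Conv3D((1, 3, 3), 1, 2, rng=rng)])
    d0 = net.state_digest()
    net.layers[0].w.data[0, 0, 0, 0, 0] += 1.0
    assert net.state_digest() != d0
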