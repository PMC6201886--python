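"""Layer-level contracts: the batch-normalization equations, convolution
against an independent oracle, pooling, softmax/cross-entropy, and a
numerical gradient check of the assembled network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from deepfocus import focusnet
from deepfocus.focusnet import layers as L


class TestBatchNormForward:
    def test_unit_gaussianization(self, rng):
        """With gamma=1, beta=0 the output has per-feature mean 0 and
        population variance 1 for any batch."""
        u = rng.normal(5.0, 3.0, size=(32, 7))
        state = L.BatchNormState.create(7)
        out, _ = L.batch_norm_forward(u, state, "train")
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-5)
        assert np.allclose(out.var(axis=0), 1.0, atol=1e-5)

    def test_constant_feature_maps_to_beta(self):
        state = L.BatchNormState.create(2)
        state.beta[:] = (0.7, -1.2)
        u = np.full((8, 2), 3.3)
        out, _ = L.batch_norm_forward(u, state, "train")
        assert np.allclose(out[:, 0], 0.7, atol=1e-3)
        assert np.allclose(out[:, 1], -1.2, atol=1e-3)

    def test_hand_computed_three_point_batch(self):
        """(1,2,3) with population variance 2/3 normalizes to about
        (-1.2247, 0, 1.2247)."""
        state = L.BatchNormState.create(1)
        out, _ = L.batch_norm_forward(np.array([[1.0], [2.0], [3.0]]), state, "train")
        assert np.allclose(out.ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-6)

    def test_gamma_beta_affine(self, rng):
        u = rng.normal(0, 1, size=(16, 3))
        state = L.BatchNormState.create(3)
        state.gamma[:] = 2.0
        state.beta[:] = -1.0
        out, _ = L.batch_norm_forward(u, state, "train")
        assert np.allclose(out.mean(axis=0), -1.0, atol=1e-5)
        assert np.allclose(out.std(axis=0), 2.0, atol=1e-4)

    def test_batch_of_one_rejected_in_train_mode(self):
        with pytest.raises(ValueError):
            L.batch_norm_forward(np.ones((1, 4)), L.BatchNormState.create(4), "train")

    def test_infer_mode_uses_running_statistics(self, rng):
        state = L.BatchNormState.create(3)
        u = rng.normal(2.0, 1.5, size=(64, 3))
        for _ in range(50):
            L.batch_norm_forward(u, state, "train")
        out, _ = L.batch_norm_forward(u, state, "infer")
        train_out, _ = L.batch_norm_forward(u, state, "train")
        assert np.allclose(out, train_out, atol=1e-2)

    def test_default_epsilon_is_exp_minus_15(self):
        assert L.DEFAULT_BN_EPS == pytest.approx(np.exp(-15.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(2, 40), k=st.integers(1, 6), seed=st.integers(0, 999))
    def test_gaussianization_property(self, n, k, seed):
        u = np.random.default_rng(seed).normal(0, 10, size=(n, k))
        out, _ = L.batch_norm_forward(u, L.BatchNormState.create(k), "train")
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-5)
        # output variance is var/(var + eps): 1 up to the eps shrinkage,
        # which only matters when the raw batch variance is itself tiny
        v = out.var(axis=0)
        tol = np.maximum(1e-5, 2 * L.DEFAULT_BN_EPS / np.maximum(u.var(axis=0), 1e-300))
        assert np.all(np.abs(v - 1.0) <= tol)


class TestBatchNormLayer:
    def test_layer_matches_reference_function(self, rng):
        """The fused spatial BN layer computes the same transform as the
        reference per-feature equations."""
        x = rng.normal(1.0, 2.0, size=(4, 6, 6, 3)).astype(np.float32)
        layer = L.BatchNorm(3)
        got = layer.forward(x, mode="train")
        ref_state = L.BatchNormState.create(3)
        ref, _ = L.batch_norm_forward(x.reshape(-1, 3), ref_state, "train")
        assert np.allclose(got.reshape(-1, 3), ref, atol=1e-5)
        assert np.allclose(layer.state.running_mean, ref_state.running_mean, atol=1e-6)
        assert np.allclose(layer.state.running_var, ref_state.running_var, atol=1e-6)


class TestConv2D:
    def test_matches_scipy_correlate(self, rng):
        """Forward pass equals channel-wise scipy correlation with
        constant(0) padding."""
        conv = L.Conv2D(2, 3, 3, rng)
        x = rng.normal(0, 1, size=(1, 8, 8, 2)).astype(np.float32)
        y = conv.forward(x)
        expected = np.zeros((8, 8, 3))
        for o in range(3):
            for c in range(2):
                expected[:, :, o] += ndimage.correlate(
                    x[0, :, :, c].astype(float), conv.W[:, :, c, o].astype(float),
                    mode="constant", cval=0.0,
                )
            expected[:, :, o] += conv.b[o]
        assert np.allclose(y[0], expected, atol=1e-4)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            L.Conv2D(1, 1, 4, rng)


class TestMaxPool:
    def test_forward_small_example(self):
        x = np.array([[1, 2, 5, 0], [3, 4, 1, 1], [0, 0, 2, 2], [9, 0, 2, 2]],
                     dtype=np.float32).reshape(1, 4, 4, 1)
        y = L.MaxPool2().forward(x)
        assert np.array_equal(y[0, :, :, 0], [[4, 5], [9, 2]])

    def test_backward_routes_to_argmax(self):
        x = np.array([[1, 2], [3, 4]], dtype=np.float32).reshape(1, 2, 2, 1)
        pool = L.MaxPool2()
        pool.forward(x, mode="train")
        dx = pool.backward(np.array([[[[7.0]]]]))
        assert dx[0, 1, 1, 0] == 7.0 and dx.sum() == 7.0

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            L.MaxPool2().forward(np.zeros((1, 3, 4, 1)))


class TestSoftmaxCrossEntropy:
    def test_softmax_normalizes(self, rng):
        p = L.softmax(rng.normal(0, 5, size=(10, 2)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_loss_gradient_matches_numeric(self, rng):
        logits = rng.normal(0, 1, size=(5, 2))
        y = np.array([0, 1, 1, 0, 1])
        _, grad = L.cross_entropy_loss(logits, y)
        eps = 1e-6
        for i in (0, 3):
            for j in (0, 1):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (L.cross_entropy_loss(lp, y)[0] - L.cross_entropy_loss(lm, y)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestDropout:
    def test_infer_mode_is_identity(self, rng):
        x = rng.normal(0, 1, size=(4, 10)).astype(np.float32)
        assert np.array_equal(L.Dropout(0.5).forward(x, mode="infer"), x)

    def test_inverted_scaling_preserves_mean(self, rng):
        x = np.ones((2000, 50), dtype=np.float32)
        out = L.Dropout(0.2).forward(x, mode="train", rng=rng)
        assert out.mean() == pytest.approx(1.0, abs=0.02)


def test_full_network_gradient_check():
    """Analytic backprop through conv/ReLU/BN/pool/dense/softmax agrees
    with central finite differences (float64, dropout off)."""
    spec = focusnet.ArchitectureSpec(
        conv_channels=(2, 2, 2, 2, 2), conv_kernels=(3, 3, 3, 3, 3), fc_layers=(4,)
    )
    model = focusnet.build_model(spec, rng_seed=0, dropout_p=0.0)
    for layer in model.layers:  # promote to float64 for the check
        for attr in ("W", "b", "dW", "db", "dgamma", "dbeta"):
            if hasattr(layer, attr):
                setattr(layer, attr, getattr(layer, attr).astype(np.float64))
        if isinstance(layer, L.BatchNorm):
            st_ = layer.state
            st_.gamma = st_.gamma.astype(np.float64)
            st_.beta = st_.beta.astype(np.float64)
            st_.running_mean = st_.running_mean.astype(np.float64)
            st_.running_var = st_.running_var.astype(np.float64)

    rng = np.random.default_rng(3)
    x = rng.normal(0, 0.3, size=(4, 64, 64, 3))
    y = np.array([0, 1, 0, 1])

    def loss():
        logits = model.forward(x, mode="train", rng=np.random.default_rng(0))
        return L.cross_entropy_loss(logits, y)[0]

    logits = model.forward(x, mode="train", rng=np.random.default_rng(0))
    _, dlogits = L.cross_entropy_loss(logits, y)
    model.backward(dlogits)
    for layer in model.layers:
        for name, p in layer.params.items():
            g = layer.grads[name]
            idx = tuple(np.unravel_index(np.argmax(np.abs(g)), g.shape))
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)
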