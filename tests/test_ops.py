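"""Pooling/unpooling semantics and autodiff correctness of the NumPy layers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import smsegnet as sm
from smsegnet._nn import ops
from smsegnet._nn.ops import Tensor


# -- max pooling ------------------------------------------------------------

def test_pool_window_example():
    x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
    pooled, idx = sm.max_pool_with_indices(Tensor(x))
    assert pooled.data[0, 0, 0, 0] == 4.0
    assert tuple(idx.offsets[0, 0, 0, 0]) == (1, 1)


def test_pool_tie_breaks_to_first_in_row_major_order():
    x = np.full((1, 1, 2, 2), 7.0)
    pooled, idx = sm.max_pool_with_indices(Tensor(x))
    assert pooled.data[0, 0, 0, 0] == 7.0
    assert tuple(idx.offsets[0, 0, 0, 0]) == (0, 0)


def test_pool_shape_and_channel_preservation(rng):
    x = rng.normal(size=(2, 3, 4, 4))
    pooled, idx = sm.max_pool_with_indices(Tensor(x))
    assert pooled.shape == (2, 3, 2, 2)
    assert idx.source_shape == (4, 4)
    assert idx.pooled_shape == (2, 2)


def test_pool_rejects_odd_dimensions(rng):
    with pytest.raises(ValueError):
        sm.max_pool_with_indices(Tensor(rng.normal(size=(1, 1, 3, 4))))


def _brute_force_pool_unpool(x):
    """Oracle: per 2x2 window, keep the first row-major maximum in place."""
    out = np.zeros_like(x)
    n, c, h, w = x.shape
    for ni in range(n):
        for ci in range(c):
            for i in range(0, h, 2):
                for j in range(0, w, 2):
                    win = x[ni, ci, i:i + 2, j:j + 2]
                    k = int(win.argmax())  # row-major first maximum
                    out[ni, ci, i + k // 2, j + k % 2] = win.flat[k]
    return out


@settings(max_examples=30, deadline=None, derandomize=True)
@given(arrays(np.float64, (1, 2, 8, 8),
              elements=st.floats(-10, 10, allow_nan=False)))
def test_unpool_of_pool_matches_brute_force_oracle(x):
    pooled, idx = sm.max_pool_with_indices(Tensor(x))
    restored = sm.max_unpool(pooled, idx)
    np.testing.assert_array_equal(restored.data, _brute_force_pool_unpool(x))


def test_unpool_zeros_and_shape(rng):
    x = rng.normal(size=(1, 2, 6, 6))
    pooled, idx = sm.max_pool_with_indices(Tensor(x))
    z = sm.max_unpool(Tensor(np.zeros_like(pooled.data)), idx)
    assert z.shape == (1, 2, 6, 6)
    assert np.all(z.data == 0)


def test_unpool_rejects_wrong_level_indices(rng):
    _, idx8 = sm.max_pool_with_indices(Tensor(rng.normal(size=(1, 1, 8, 8))))
    x4 = Tensor(rng.normal(size=(1, 1, 2, 2)))  # pooled from 4x4, not 8x8
    with pytest.raises(ValueError):
        sm.max_unpool(x4, idx8)


# -- upsampling and concat --------------------------------------------------

def test_nearest_upsample_of_constant_is_constant():
    x = Tensor(np.full((1, 2, 3, 3), 5.0))
    up = ops.upsample2(x)
    assert up.shape == (1, 2, 6, 6)
    assert np.all(up.data == 5.0)


def test_concat_channel_arithmetic_and_mismatch(rng):
    a = Tensor(rng.normal(size=(1, 2, 4, 4)))
    b = Tensor(rng.normal(size=(1, 3, 4, 4)))
    assert ops.concat([a, b]).shape == (1, 5, 4, 4)
    with pytest.raises(ValueError):
        ops.concat([a, Tensor(rng.normal(size=(1, 2, 8, 8)))])


# -- softmax / cross-entropy ------------------------------------------------

def test_softmax_is_a_distribution(rng):
    p = ops.softmax(rng.normal(size=(2, 4, 5, 5)))
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all() and (p <= 1).all()


def test_equal_logits_give_uniform_probabilities():
    p = ops.softmax(np.zeros((1, 4, 2, 2)))
    np.testing.assert_allclose(p, 0.25)


def test_uniform_prediction_loss_is_log_c():
    logits = np.zeros((1, 4, 3, 3))
    labels = np.zeros((1, 3, 3), dtype=int)
    loss = ops.softmax_cross_entropy(Tensor(logits), labels)
    np.testing.assert_allclose(float(loss.data), np.log(4), rtol=1e-6)


def test_confident_correct_prediction_has_near_zero_loss():
    labels = np.array([[[1, 2], [3, 0]]])
    logits = np.full((1, 4, 2, 2), -50.0)
    for i in range(2):
        for j in range(2):
            logits[0, labels[0, i, j], i, j] = 50.0
    loss = ops.softmax_cross_entropy(Tensor(logits), labels)
    assert 0 <= float(loss.data) < 1e-6


def test_probability_space_cross_entropy(rng):
    onehot = np.zeros((1, 4, 2, 2))
    onehot[0, 0] = 1.0
    # perfect prediction: zero loss (up to the log floor)
    assert ops.cross_entropy(onehot, onehot) == pytest.approx(0.0, abs=1e-9)
    # uniform prediction over 4 classes: ln 4 per pixel
    uniform = np.full((1, 4, 2, 2), 0.25)
    assert ops.cross_entropy(onehot, uniform) == pytest.approx(np.log(4))
    # agrees with the fused softmax path on arbitrary logits
    logits = rng.normal(size=(1, 4, 2, 2))
    labels = np.zeros((1, 2, 2), dtype=int)
    fused = float(ops.softmax_cross_entropy(Tensor(logits), labels).data)
    assert ops.cross_entropy(onehot, ops.softmax(logits)) == pytest.approx(
        fused, rel=1e-6)
    # a zero-probability true class is floored, not infinite
    wrong = np.zeros_like(onehot)
    wrong[0, 1] = 1.0
    assert np.isfinite(ops.cross_entropy(onehot, wrong))


def test_loss_decreases_as_true_class_probability_rises():
    labels = np.zeros((1, 1, 1), dtype=int)
    losses = []
    for margin in (0.0, 1.0, 2.0):
        logits = np.zeros((1, 4, 1, 1))
        logits[0, 0] = margin
        losses.append(float(ops.softmax_cross_entropy(
            Tensor(logits), labels).data))
    assert losses[0] > losses[1] > losses[2] >= 0


# -- gradients --------------------------------------------------------------

def test_gradients_match_finite_differences(tiny_config):
    """Full-network analytic gradients vs. float64 central differences."""
    net = sm.SMSegNet(tiny_config, seed=1)
    shift = np.random.default_rng(42)
    for t in net.params.values():
        # move off exact ReLU kinks (zero biases on zeroed inputs), where
        # the valid subgradient differs from a two-sided finite difference
        t.data = t.data.astype(np.float64) + shift.normal(0, 0.05, t.data.shape)
    x = np.random.default_rng(1).random((2, 1, 8, 8))
    y = np.random.default_rng(2).integers(0, 4, (2, 8, 8))
    net.zero_grad()
    loss = ops.softmax_cross_entropy(net.logits(x), y)
    loss.backward()

    pick = np.random.default_rng(3)
    worst = 0.0
    for name, t in net.params.items():
        assert t.grad is not None and t.grad.shape == t.data.shape, name
        for _ in range(3):
            i = tuple(pick.integers(0, s) for s in t.data.shape)
            eps, orig = 1e-6, t.data[i]
            t.data[i] = orig + eps
            lp = float(ops.softmax_cross_entropy(net.logits(x), y).data)
            t.data[i] = orig - eps
            lm = float(ops.softmax_cross_entropy(net.logits(x), y).data)
            t.data[i] = orig
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - t.grad[i])
                        / max(1e-8, abs(num), abs(t.grad[i])))
    assert worst < 1e-4
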