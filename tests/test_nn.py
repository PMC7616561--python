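"""Finite-difference verification of the autodiff/conv stack."""

import numpy as np
import pytest

from echo2vox.nn import autograd as ag


def numerical_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(fn, tensors, tol=1e-6):
    for t in tensors:
        t.grad = None
    fn().backward()
    for t in tensors:
        ng = numerical_grad(lambda: fn().data.item(), t.data)
        err = np.abs(t.grad - ng).max() / (np.abs(ng).max() + 1e-12)
        assert err < tol


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.mark.parametrize(
    "stride,pad",
    [(1, 0), (1, 1), (2, 1)],
)
def test_conv2d_gradients(rng, stride, pad):
    x = ag.Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
    w = ag.Tensor(rng.normal(size=(4, 3, 3, 3)), requires_grad=True)
    b = ag.Tensor(rng.normal(size=4), requires_grad=True)
    out_shape = ag.conv(x, w, b, stride, pad).shape
    proj = ag.Tensor(rng.normal(size=out_shape))
    assert_grads_match(lambda: (ag.conv(x, w, b, stride, pad) * proj).sum(), [x, w, b])


def test_conv3d_gradients(rng):
    x = ag.Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
    w = ag.Tensor(rng.normal(size=(3, 2, 3, 3, 3)), requires_grad=True)
    b = ag.Tensor(rng.normal(size=3), requires_grad=True)
    proj = ag.Tensor(rng.normal(size=(1, 3, 4, 4, 4)))
    assert_grads_match(lambda: (ag.conv(x, w, b, 1, 1) * proj).sum(), [x, w, b])


@pytest.mark.parametrize("kernel,opad", [(4, 0), (3, 1)])
def test_conv_transpose3d_doubles_and_differentiates(rng, kernel, opad):
    x = ag.Tensor(rng.normal(size=(1, 3, 3, 3, 3)), requires_grad=True)
    w = ag.Tensor(rng.normal(size=(3, 2, kernel, kernel, kernel)), requires_grad=True)
    b = ag.Tensor(rng.normal(size=2), requires_grad=True)
    out = ag.conv_transpose(x, w, b, 2, 1, opad)
    assert out.shape == (1, 2, 6, 6, 6)
    proj = ag.Tensor(rng.normal(size=out.shape))
    assert_grads_match(lambda: (ag.conv_transpose(x, w, b, 2, 1, opad) * proj).sum(), [x, w, b])


def test_softmax_sigmoid_bce_gradients(rng):
    s = ag.Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
    proj = ag.Tensor(rng.normal(size=(2, 3, 4)))
    assert_grads_match(lambda: (ag.softmax(s, 1) * proj).sum(), [s])
    target = (rng.random((2, 3, 4)) > 0.5).astype(float)
    assert_grads_match(lambda: ag.binary_cross_entropy(ag.sigmoid(s), target), [s], tol=1e-5)


def test_structural_op_gradients(rng):
    a = ag.Tensor(rng.normal(size=(2, 3)), requires_grad=True)
    b = ag.Tensor(rng.normal(size=(2, 3)), requires_grad=True)
    p_stack = ag.Tensor(rng.normal(size=(2, 2, 3)))
    assert_grads_match(lambda: (ag.stack([a, b], 0) * p_stack).sum(), [a, b])
    p_pad = ag.Tensor(rng.normal(size=(2, 5)))
    assert_grads_match(lambda: (ag.pad_axis(a, 1, 1, 1) * p_pad).sum(), [a])
    p_mean = ag.Tensor(rng.normal(size=3))
    assert_grads_match(lambda: (a.mean(axis=0) * p_mean).sum(), [a])
    assert_grads_match(lambda: (a[0:1, :] * ag.Tensor(np.ones((1, 3)))).sum(), [a])


def test_broadcast_add_unbroadcasts_gradient(rng):
    a = ag.Tensor(rng.normal(size=(2, 3)), requires_grad=True)
    bias = ag.Tensor(rng.normal(size=(1, 3)), requires_grad=True)
    proj = ag.Tensor(rng.normal(size=(2, 3)))
    assert_grads_match(lambda: ((a + bias) * proj).sum(), [a, bias])
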