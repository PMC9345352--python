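"""The NumPy layer engine: convolution oracles and finite-difference gradients.

Gradient checks probe a random linear functional of the output (sum of a
fixed weighting) rather than the squared norm, which for train-mode batch
norm is constant in the input and would make the test vacuous.
"""

from itertools import product

import numpy as np
import pytest

from neurocube.nn import (Adam, BatchNorm3d, Conv3d, ConvTranspose3d,
                          DepthwiseConv3d, Dropout, Linear, MaxPool3d, ReLU,
                          new_rng)
from neurocube.nn.losses import (mse_loss, softmax, softmax_cross_entropy,
                                 softmax_dice_loss)


# -- direct convolution oracle -----------------------------------------------

def conv3d_loops(x, w, b, dilation=1):
    """O(everything) reference convolution, same padding, stride 1."""
    n, ci, d, h, wd = x.shape
    co, _, k, _, _ = w.shape
    pad = dilation * (k // 2)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    out = np.zeros((n, co, d, h, wd))
    for nn_, co_, z, y, xx in product(range(n), range(co), range(d), range(h),
                                      range(wd)):
        acc = 0.0
        for ci_, i, j, l in product(range(ci), range(k), range(k), range(k)):
            acc += (w[co_, ci_, i, j, l]
                    * xp[nn_, ci_, z + i * dilation, y + j * dilation,
                         xx + l * dilation])
        out[nn_, co_, z, y, xx] = acc + b[co_]
    return out


@pytest.mark.parametrize("k,dilation", [(1, 1), (3, 1), (3, 2)])
def test_conv3d_matches_loop_oracle(k, dilation, rng):
    x = rng.normal(0, 1, (1, 2, 4, 4, 4)).astype(np.float32)
    conv = Conv3d(2, 3, k=k, dilation=dilation, rng=new_rng(0))
    conv.bias.data[:] = rng.normal(0, 1, 3)
    got = conv.forward(x)
    want = conv3d_loops(x, conv.weight.data, conv.bias.data, dilation)
    np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)


def test_depthwise_matches_loop_oracle(rng):
    x = rng.normal(0, 1, (1, 3, 4, 4, 4)).astype(np.float32)
    dw = DepthwiseConv3d(3, k=3, dilation=2, rng=new_rng(0))
    dw.bias.data[:] = rng.normal(0, 1, 3)
    got = dw.forward(x)
    # depthwise == grouped conv with a diagonal full kernel
    wfull = np.zeros((3, 3, 3, 3, 3), dtype=np.float32)
    for c in range(3):
        wfull[c, c] = dw.weight.data[c]
    want = conv3d_loops(x, wfull, dw.bias.data, dilation=2)
    np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)


# -- finite-difference gradients ----------------------------------------------

def _grad_check(layer, x_shape, rng, train=True, tol=5e-3):
    x = rng.normal(0, 1, x_shape).astype(np.float32)
    probe = rng.normal(0, 1, size=layer.forward(x.copy()).shape).astype(np.float32)
    layer.train(train)

    def loss():
        return float((layer.forward(x.copy()).astype(np.float64) * probe).sum())

    layer.forward(x.copy())
    layer.zero_grad()
    layer.forward(x.copy())
    gx = layer.backward(probe.copy())

    eps = 1e-2
    flat = x.reshape(-1)
    idx = rng.choice(flat.size, size=min(20, flat.size), replace=False)
    for i in idx:
        orig = flat[i]
        flat[i] = orig + eps
        fp = loss()
        flat[i] = orig - eps
        fm = loss()
        flat[i] = orig
        num = (fp - fm) / (2 * eps)
        assert gx.reshape(-1)[i] == pytest.approx(num, rel=tol, abs=2e-2)
    for p in layer.params():
        pflat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1)
        pidx = rng.choice(pflat.size, size=min(10, pflat.size), replace=False)
        for i in pidx:
            orig = pflat[i]
            pflat[i] = orig + eps
            fp = loss()
            pflat[i] = orig - eps
            fm = loss()
            pflat[i] = orig
            num = (fp - fm) / (2 * eps)
            assert gflat[i] == pytest.approx(num, rel=tol, abs=2e-2)


@pytest.mark.parametrize("layer_fn,x_shape", [
    (lambda: Conv3d(2, 3, k=3, rng=new_rng(0)), (2, 2, 4, 4, 4)),
    (lambda: Conv3d(3, 2, k=1, rng=new_rng(0)), (1, 3, 3, 3, 3)),
    (lambda: DepthwiseConv3d(3, k=3, dilation=2, rng=new_rng(0)), (1, 3, 5, 5, 5)),
    (lambda: BatchNorm3d(3), (2, 3, 3, 3, 3)),
    (lambda: MaxPool3d(), (1, 2, 4, 4, 4)),
    (lambda: ConvTranspose3d(2, 3, rng=new_rng(0)), (1, 2, 3, 3, 3)),
], ids=["conv3", "conv1", "depthwise", "batchnorm", "maxpool", "convT"])
def test_layer_gradients(layer_fn, x_shape, rng):
    _grad_check(layer_fn(), x_shape, rng)


def test_linear_gradient(rng):
    lin = Linear(6, 4, rng=new_rng(0))
    _grad_check(lin, (3, 6), rng)


def test_batchnorm_eval_uses_running_stats(rng):
    bn = BatchNorm3d(2)
    x = rng.normal(3, 2, (4, 2, 4, 4, 4)).astype(np.float32)
    bn.train(True)
    for _ in range(50):
        bn.forward(x)
    bn.eval()
    y = bn.forward(x)
    # after many updates running stats approach batch stats -> y ~ standard
    assert abs(float(y.mean())) < 0.05
    assert float(y.std()) == pytest.approx(1.0, abs=0.1)


def test_dropout_train_vs_eval(rng):
    d = Dropout(0.5, rng=new_rng(0))
    x = np.ones((1, 1000), dtype=np.float32)
    d.train(True)
    y = d.forward(x)
    kept = y > 0
    assert 0.3 < kept.mean() < 0.7
    np.testing.assert_allclose(y[kept], 2.0)  # inverted scaling
    d.eval()
    np.testing.assert_array_equal(d.forward(x), x)


def test_maxpool_requires_even_dims(rng):
    with pytest.raises(ValueError):
        MaxPool3d().forward(np.zeros((1, 1, 3, 4, 4), dtype=np.float32))


def test_convtranspose_doubles_and_inverts_shape(rng):
    up = ConvTranspose3d(4, 2, rng=new_rng(0))
    x = rng.normal(0, 1, (2, 4, 3, 3, 3)).astype(np.float32)
    y = up.forward(x)
    assert y.shape == (2, 2, 6, 6, 6)


# -- losses -------------------------------------------------------------------

def test_softmax_normalizes(rng):
    z = rng.normal(0, 3, (2, 5, 3, 3, 3)).astype(np.float32)
    p = softmax(z)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)


@pytest.mark.parametrize("loss_fn", [softmax_dice_loss, softmax_cross_entropy],
                         ids=["dice", "cross_entropy"])
def test_segmentation_loss_gradients(loss_fn, rng):
    logits = rng.normal(0, 1, (1, 3, 4, 4, 4)).astype(np.float32)
    labels = rng.integers(0, 3, (1, 4, 4, 4))
    _, dl = loss_fn(logits, labels)
    eps = 1e-3
    idx = rng.choice(logits.size, size=25, replace=False)
    flat = logits.reshape(-1)
    for i in idx:
        orig = flat[i]
        flat[i] = orig + eps
        lp, _ = loss_fn(logits, labels)
        flat[i] = orig - eps
        lm, _ = loss_fn(logits, labels)
        flat[i] = orig
        assert dl.reshape(-1)[i] == pytest.approx((lp - lm) / (2 * eps),
                                                  rel=2e-2, abs=1e-4)


def test_mse_loss_value_and_gradient():
    loss, grad = mse_loss(np.array([1.0, 3.0]), np.array([0.0, 1.0]))
    assert loss == pytest.approx((1 + 4) / 2)
    np.testing.assert_allclose(grad, [1.0, 2.0])


def test_adam_minimizes_quadratic():
    from neurocube.nn.core import Param
    p = Param(np.array([5.0, -3.0], dtype=np.float32))
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        p.zero_grad()
        p.grad += 2 * p.data
        opt.step()
    assert np.abs(p.data).max() < 1e-2
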