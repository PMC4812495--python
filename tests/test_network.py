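"""Network building blocks: convolution, pooling, shape laws, fusion, head."""

import numpy as np
import pytest

from mscnnseg.errors import ConfigurationError, ShapeError
from mscnnseg.network import ops
from mscnnseg.network.model import (ConvLayerSpec, Head, build_pathway,
                                    classify_head, conv_forward, fuse_features,
                                    symbolic_output)


def brute_force_conv(x, weights, bias):
    """Quadruple-loop oracle for M_s = b_s + sum_c W_sc * X_c (valid)."""
    n, c, h, w = x.shape
    s, _, kh, kw = weights.shape
    oh, ow = h - kh + 1, w - kw + 1
    out = np.zeros((n, s, oh, ow), dtype=np.float64)
    for ni in range(n):
        for si in range(s):
            for i in range(oh):
                for j in range(ow):
                    out[ni, si, i, j] = bias[si] + float(
                        (x[ni, :, i:i + kh, j:j + kw] * weights[si]).sum())
    return out


def test_conv_matches_brute_force_oracle(rng):
    x = rng.standard_normal((2, 4, 6, 6))
    w = rng.standard_normal((3, 4, 3, 3))
    b = rng.standard_normal(3)
    assert np.allclose(ops.conv2d(x, w, b), brute_force_conv(x, w, b), atol=1e-10)


def test_fft_conv_route_matches_brute_force(rng):
    """The large-input FFT evaluation computes the same sums."""
    x = rng.standard_normal((2, 4, 40, 40))
    w = rng.standard_normal((6, 4, 11, 11))
    b = rng.standard_normal(6)
    ref = ops._conv2d_direct(x, w) + b[None, :, None, None]
    got = ops._conv2d_fft(x, w) + b[None, :, None, None]
    assert np.allclose(got, ref, atol=1e-9)


def test_conv_identity_kernel():
    x = np.arange(25, dtype=np.float64).reshape(1, 1, 5, 5)
    w = np.ones((1, 1, 1, 1))
    b = np.zeros(1)
    assert np.array_equal(ops.conv2d(x, w, b), x)


def test_conv_linearity_with_zero_bias(rng):
    x = rng.standard_normal((1, 4, 10, 10))
    y = rng.standard_normal((1, 4, 10, 10))
    w = rng.standard_normal((2, 4, 3, 3))
    b = np.zeros(2)
    lhs = ops.conv2d(x + y, w, b)
    rhs = ops.conv2d(x, w, b) + ops.conv2d(y, w, b)
    assert np.allclose(lhs, rhs, atol=1e-8)


def test_conv_gradients_match_finite_differences(rng):
    x = rng.standard_normal((2, 2, 7, 7))
    w = rng.standard_normal((3, 2, 3, 3))
    b = np.zeros(3)
    dout = rng.standard_normal((2, 3, 5, 5))
    dw, db, dx = ops.conv2d_backward(x, w, dout)
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (2, 1, 2, 2), (1, 0, 1, 2)]:
        wp = w.copy(); wp[idx] += eps
        wm = w.copy(); wm[idx] -= eps
        num = ((ops.conv2d(x, wp, b) - ops.conv2d(x, wm, b)) * dout).sum() / (2 * eps)
        assert abs(num - dw[idx]) < 1e-4
    for idx in [(0, 0, 0, 0), (1, 1, 3, 4)]:
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = ((ops.conv2d(xp, w, b) - ops.conv2d(xm, w, b)) * dout).sum() / (2 * eps)
        assert abs(num - dx[idx]) < 1e-4


def test_kernel_larger_than_input_rejected(rng):
    x = rng.standard_normal((1, 1, 4, 4))
    w = rng.standard_normal((1, 1, 5, 5))
    with pytest.raises(ShapeError):
        ops.conv2d(x, w, np.zeros(1))


def test_max_pool_matches_brute_force(rng):
    x = rng.standard_normal((2, 3, 8, 8))
    out = ops.max_pool(x, (2, 2))
    for i in range(4):
        for j in range(4):
            expected = x[:, :, 2 * i:2 * i + 2, 2 * j:2 * j + 2].max(axis=(2, 3))
            assert np.array_equal(out[:, :, i, j], expected)


def test_max_pool_row_window_gives_row_maxima(rng):
    x = rng.standard_normal((1, 2, 4, 4))
    out = ops.max_pool(x, (1, 4))
    assert out.shape == (1, 2, 4, 1)
    assert np.array_equal(out[..., 0], x.max(axis=3))


def test_max_pool_constant_map_stays_constant():
    x = np.full((1, 1, 4, 4), 2.5)
    assert np.all(ops.max_pool(x, (2, 2)) == 2.5)


def test_max_pool_indivisible_rejected(rng):
    with pytest.raises(ShapeError):
        ops.max_pool(rng.standard_normal((1, 1, 5, 4)), (2, 2))


def test_48_pathway_shape_chain():
    """Symbolic chain 48 -> 38 -> 28 -> 18 -> 8 -> 4 before pooling."""
    side = 48
    for k in (11, 11, 11, 11, 5):
        side = ops.conv_out_side(side, k)
    assert side == 4
    maps, shape = symbolic_output(48, [(11, 12), (11, 32), (11, 96), (11, 256), (5, 1024)], (1, 4))
    assert (maps, shape) == (1024, (4, 1))


@pytest.mark.parametrize("scale,expected", [
    (48, (1024, (4, 1))),
    (28, (72, (4, 4))),
    (12, (16, (4, 4))),
])
def test_reference_pathway_declared_outputs(scale, expected):
    pw = build_pathway(scale, "reference")
    assert pw.output_shape == expected


def test_c1_produces_12_maps_of_38x38(rng):
    pw = build_pathway(48, "reference", seed=0)
    x = rng.standard_normal((1, 4, 48, 48)).astype(np.float32)
    c1 = ops.relu(ops.conv2d(x, pw.layers[0].weights, pw.layers[0].bias))
    assert c1.shape == (1, 12, 38, 38)


@pytest.mark.parametrize("scale,expected", [(28, (1, 72, 4, 4)), (12, (1, 16, 4, 4))])
def test_pathway_forward_output_shapes(rng, scale, expected):
    pw = build_pathway(scale, "reference", seed=1)
    x = rng.standard_normal((1, 4, scale, scale)).astype(np.float32)
    assert pw.forward(x).shape == expected


def test_symbolic_shapes_match_real_forward_on_random_stacks(rng):
    """Shape oracle: symbolic propagation equals an actual forward pass."""
    for trial in range(5):
        scale = int(rng.integers(16, 40))
        layers = []
        side = scale
        for _ in range(int(rng.integers(1, 4))):
            kmax = min(7, side - 1)
            if kmax < 2:
                break
            k = int(rng.integers(2, kmax + 1))
            layers.append((k, int(rng.integers(1, 6))))
            side = side - k + 1
        if not layers:
            continue
        pw = build_pathway(scale, layers=layers, pool=None, seed=trial)
        x = rng.standard_normal((2, 4, scale, scale)).astype(np.float32)
        maps, (h, w) = symbolic_output(scale, layers, None)
        assert pw.forward(x).shape == (2, maps, h, w)


def test_pathway_declared_output_mismatch_fails_loudly():
    with pytest.raises(ConfigurationError):
        build_pathway(48, layers=[(11, 12), (5, 7)], pool=None,
                      declared_output=(7, (4, 4)))


def test_unsupported_scale_without_layers_rejected():
    with pytest.raises(ConfigurationError):
        build_pathway(37, "reference")


def test_fused_vector_length_is_5504(rng):
    pws = {s: build_pathway(s, "reference", seed=s) for s in (48, 28, 12)}
    outs = {s: pws[s].forward(
        rng.standard_normal((1, 4, s, s)).astype(np.float32))[0] for s in pws}
    v = fuse_features(outs)
    assert v.shape == (5504,)
    assert 1024 * 4 + 72 * 16 + 16 * 16 == 5504


def test_fuse_single_map_and_multiset_identity(rng):
    single = {5: rng.standard_normal((1, 1, 1))}
    assert fuse_features(single).shape == (1,)
    outs = {48: rng.standard_normal((3, 2, 2)), 12: rng.standard_normal((2, 4, 4))}
    v = fuse_features(outs)
    assert v.shape == (3 * 4 + 2 * 16,)
    assert np.array_equal(np.sort(v), np.sort(np.concatenate(
        [outs[48].ravel(), outs[12].ravel()])))
    # largest scale comes first
    assert np.array_equal(v[:12], outs[48].ravel())


def test_head_outputs_probability_simplex(rng):
    head = Head((10, 8, 6, 5)).init_weights(rng)
    v = rng.standard_normal(10)
    p = classify_head(v, head)
    assert p.shape == (5,)
    assert abs(p.sum() - 1.0) < 1e-6
    assert np.all(p >= 0)


def test_softmax_shift_invariance_of_argmax(rng):
    logits = rng.standard_normal((4, 5))
    assert np.array_equal(np.argmax(ops.softmax(logits), axis=1),
                          np.argmax(ops.softmax(logits + 7.3), axis=1))


def test_zero_weight_head_gives_uniform_distribution():
    head = Head((6, 4, 5))
    head.weights = [np.zeros((6, 4), np.float32), np.zeros((4, 5), np.float32)]
    head.biases = [np.zeros(4, np.float32), np.zeros(5, np.float32)]
    p = classify_head(np.ones(6), head)
    assert np.allclose(p, 0.2, atol=1e-7)


def test_head_length_mismatch_rejected(rng):
    head = Head((10, 4, 5)).init_weights(rng)
    with pytest.raises(ShapeError):
        classify_head(np.ones(7), head)


def test_conv_forward_wrapper_accepts_hwc_and_chw(rng):
    w = rng.standard_normal((3, 4, 3, 3)).astype(np.float32)
    spec = ConvLayerSpec((3, 3), 3, weights=w, bias=np.zeros(3, np.float32))
    x = rng.standard_normal((10, 10, 4)).astype(np.float32)
    a = conv_forward(x, spec, activation="linear")
    b = conv_forward(x.transpose(2, 0, 1), spec, activation="linear")
    assert a.shape == (3, 8, 8)
    assert np.allclose(a, b, atol=1e-5)
    assert np.all(conv_forward(x, spec) >= 0)  # relu default
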