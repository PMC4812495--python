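"""Low-level network primitives: valid convolution, max pooling, dense layers.

All operations work on float32 batches in (N, C, H, W) layout and implement
both the forward pass and the gradients needed for mini-batch SGD.  The
convolution is the cross-correlation form used by every CNN framework,

    M_s = b_s + sum_c W_sc * X_c,

evaluated without padding ("valid"), so one layer shrinks each spatial side by
``kernel - 1`` (out = in - k + 1).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import irfft2, next_fast_len, rfft2

from ..errors import ShapeError

#: below this many multiply-adds the direct (sliding-window) kernel is used;
#: above it, convolutions go through the FFT, which maps onto batched GEMMs
_DIRECT_WORK_LIMIT = 1_500_000


def conv_out_side(in_side: int, kernel: int) -> int:
    """Shape law of valid convolution: out = in - k + 1."""
    out = in_side - kernel + 1
    if out < 1:
        raise ShapeError(f"kernel {kernel} larger than input side {in_side}")
    return out


def _conv_work(x_shape, w_shape) -> int:
    n, c, h, w = x_shape
    s, _, kh, kw = w_shape
    return n * s * c * (h - kh + 1) * (w - kw + 1) * kh * kw


def _conv2d_direct(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    kh, kw = weights.shape[2:]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N, C, oh, ow, kh, kw)
    return np.einsum("ncijhw,schw->nsij", win, weights, optimize=True)


def _freq_matmul(fa: np.ndarray, fb: np.ndarray):
    """Per-frequency contraction: (A, K, F) x (B, K, F) -> (A, B, F)."""
    a = fa.transpose(2, 0, 1)          # (F, A, K)
    b = fb.transpose(2, 1, 0)          # (F, K, B)
    return np.matmul(a, b).transpose(1, 2, 0)


def _conv2d_fft(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid correlation via circular FFT (exact because fft size >= input)."""
    n, c, h, w = x.shape
    s, _, kh, kw = weights.shape
    oh, ow = h - kh + 1, w - kw + 1
    fh, fw = next_fast_len(h), next_fast_len(w)
    fx = rfft2(x, s=(fh, fw)).reshape(n, c, -1)
    fk = rfft2(weights[:, :, ::-1, ::-1], s=(fh, fw)).reshape(s, c, -1)
    fy = _freq_matmul(fx, fk)  # (n, s, F)
    fy = fy.reshape(n, s, fh, fw // 2 + 1)
    y = irfft2(fy, s=(fh, fw))
    return np.ascontiguousarray(y[:, :, kh - 1:kh - 1 + oh, kw - 1:kw - 1 + ow])


def conv2d(x: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid 2D multi-channel cross-correlation.

    ``x`` is (N, C, H, W); ``weights`` is (S, C, kh, kw); ``bias`` is (S,).
    Returns (N, S, H-kh+1, W-kw+1).  Large inputs are evaluated through the
    FFT; both routes compute the same sums (up to float rounding).
    """
    kh, kw = weights.shape[2:]
    if x.shape[1] != weights.shape[1]:
        raise ShapeError(f"input channels {x.shape[1]} != kernel channels {weights.shape[1]}")
    conv_out_side(x.shape[2], kh)
    conv_out_side(x.shape[3], kw)
    if _conv_work(x.shape, weights.shape) <= _DIRECT_WORK_LIMIT:
        out = _conv2d_direct(x, weights)
    else:
        out = _conv2d_fft(x, weights).astype(x.dtype, copy=False)
    return out + bias[None, :, None, None]


def conv2d_backward(x: np.ndarray, weights: np.ndarray, dout: np.ndarray):
    """Gradients of :func:`conv2d` w.r.t. weights, bias and input."""
    kh, kw = weights.shape[2:]
    n, c, h, w = x.shape
    s = weights.shape[0]
    db = dout.sum(axis=(0, 2, 3))
    if _conv_work(x.shape, weights.shape) <= _DIRECT_WORK_LIMIT:
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))
        dw = np.einsum("nsij,ncijhw->schw", dout, win, optimize=True)
        pad = ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1))
        dpad = np.pad(dout, pad)
        wt = np.ascontiguousarray(weights.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dx = conv2d(dpad, wt, np.zeros(wt.shape[0], dtype=weights.dtype))
        return dw, db, dx

    fh, fw = next_fast_len(h), next_fast_len(w)
    fwr = fw // 2 + 1
    fx = rfft2(x, s=(fh, fw)).reshape(n, c, -1)
    fd = rfft2(dout, s=(fh, fw)).reshape(n, s, -1)
    # dW[s,c] = sum_n corr(x[n,c], dout[n,s]); in frequency: X . conj(D)
    fdw = _freq_matmul(np.conj(fd).transpose(1, 0, 2), fx.transpose(1, 0, 2))
    dw_full = irfft2(fdw.reshape(s, c, fh, fwr), s=(fh, fw))
    dw = np.ascontiguousarray(dw_full[:, :, :kh, :kw]).astype(x.dtype, copy=False)
    # dx[n,c] = sum_s true-convolution(dout[n,s], W[s,c]); no conjugation
    fk = rfft2(weights, s=(fh, fw)).reshape(s, c, -1)
    fdx = _freq_matmul(fd, fk.transpose(1, 0, 2))  # (n, c, F)
    dx_full = irfft2(fdx.reshape(n, c, fh, fwr), s=(fh, fw))
    dx = np.ascontiguousarray(dx_full[:, :, :h, :w]).astype(x.dtype, copy=False)
    return dw, db, dx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(x: np.ndarray, dout: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def max_pool(x: np.ndarray, window: Tuple[int, int]) -> np.ndarray:
    """Non-overlapping max pooling over (N, S, H, W); dims must divide."""
    ph, pw = window
    n, s, h, w = x.shape
    if h % ph or w % pw:
        raise ShapeError(f"map dims {(h, w)} not divisible by pool window {window}")
    r = x.reshape(n, s, h // ph, ph, w // pw, pw)
    return r.max(axis=(3, 5))


def max_pool_backward(x: np.ndarray, window: Tuple[int, int], dout: np.ndarray) -> np.ndarray:
    ph, pw = window
    n, s, h, w = x.shape
    r = x.reshape(n, s, h // ph, ph, w // pw, pw)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)
    dr = mask * (dout[:, :, :, None, :, None] / counts)
    return dr.reshape(n, s, h, w)


def dense(x: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Affine layer: (N, d_in) @ (d_in, d_out) + (d_out,)."""
    if x.shape[1] != weights.shape[0]:
        raise ShapeError(f"input dim {x.shape[1]} != weight rows {weights.shape[0]}")
    return x @ weights + bias


def dense_backward(x: np.ndarray, weights: np.ndarray, dout: np.ndarray):
    dw = x.T @ dout
    db = dout.sum(axis=0)
    dx = dout @ weights.T
    return dw, db, dx


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stable."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def he_normal(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-normal initialization, the standard choice for ReLU stacks."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
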