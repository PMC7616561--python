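"""N-dimensional convolution primitives on numpy arrays.

Plain correlation ("conv" in the deep-learning sense) for 2 or 3 spatial
dimensions, with the exact adjoint operations needed for reverse-mode
differentiation.  Transposed convolution is expressed through the data
adjoint, so a single trio of routines serves Conv2d, Conv3d and
ConvTranspose3d forwards and backwards.

Layouts: activations are ``(B, C, *spatial)``, weights ``(F, C, *kernel)``.
Stride and padding are isotropic integers; kernels are small, so the
scatter in the data adjoint loops over kernel offsets only.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["conv_out_shape", "conv_forward", "conv_bwd_data", "conv_bwd_weight"]


def conv_out_shape(spatial: tuple[int, ...], kernel: tuple[int, ...], stride: int, pad: int) -> tuple[int, ...]:
    return tuple((s + 2 * pad - k) // stride + 1 for s, k in zip(spatial, kernel))


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0), (0, 0)] + [(pad, pad)] * (x.ndim - 2)
    return np.pad(x, width)


def _windows(xp: np.ndarray, kernel: tuple[int, ...], stride: int) -> np.ndarray:
    """Strided sliding windows of ``xp`` -> (B, C, *out, *kernel) view."""
    nd = len(kernel)
    axes = tuple(range(2, 2 + nd))
    win = sliding_window_view(xp, kernel, axis=axes)
    if stride != 1:
        sl = (slice(None), slice(None)) + (slice(None, None, stride),) * nd
        win = win[sl]
    return win


def conv_forward(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Correlate ``x`` (B,C,*S) with ``w`` (F,C,*K) -> (B,F,*O)."""
    nd = w.ndim - 2
    kernel = w.shape[2:]
    out = conv_out_shape(x.shape[2:], kernel, stride, pad)
    win = _windows(_pad_spatial(x, pad), kernel, stride)
    # (B, C, *O, *K) x (F, C, *K) -> (B, F, *O)
    b = x.shape[0]
    cols = np.moveaxis(win, 1, 1 + nd)  # (B, *O, C, *K)
    cols = np.ascontiguousarray(cols).reshape(b, int(np.prod(out)), -1)
    y = cols @ w.reshape(w.shape[0], -1).T
    return np.moveaxis(y, -1, 1).reshape(b, w.shape[0], *out)


def conv_bwd_weight(x: np.ndarray, dout: np.ndarray, kernel: tuple[int, ...], stride: int = 1, pad: int = 0) -> np.ndarray:
    """Gradient of conv_forward w.r.t. the weight; returns (F, C, *K)."""
    nd = len(kernel)
    b, c = x.shape[:2]
    f = dout.shape[1]
    out = dout.shape[2:]
    win = _windows(_pad_spatial(x, pad), kernel, stride)
    cols = np.moveaxis(win, 1, 1 + nd)
    cols = np.ascontiguousarray(cols).reshape(b, int(np.prod(out)), -1)
    g = dout.reshape(b, f, -1)  # (B, F, L)
    dw = np.einsum("bfl,blm->fm", g, cols, optimize=True)
    return dw.reshape(f, c, *kernel)


def conv_bwd_data(
    dout: np.ndarray,
    w: np.ndarray,
    x_spatial: tuple[int, ...],
    stride: int = 1,
    pad: int = 0,
) -> np.ndarray:
    """Gradient of conv_forward w.r.t. the input; returns (B, C, *x_spatial).

    Also serves as the forward pass of transposed convolution, in which case
    ``x_spatial`` is the desired output size (any extra rows implied by
    output_padding are simply left untouched at zero).
    """
    nd = w.ndim - 2
    kernel = w.shape[2:]
    b, f = dout.shape[:2]
    c = w.shape[1]
    out = dout.shape[2:]
    g = np.moveaxis(dout.reshape(b, f, -1), 1, -1)  # (B, L, F)
    dcols = g @ w.reshape(f, -1)  # (B, L, C*K)
    dcols = dcols.reshape(b, *out, c, *kernel)
    dcols = np.moveaxis(dcols, 1 + nd, 1)  # (B, C, *out, *kernel)
    padded = tuple(s + 2 * pad for s in x_spatial)
    dxp = np.zeros((b, c, *padded), dtype=dout.dtype)
    for off in itertools.product(*(range(k) for k in kernel)):
        dst = tuple(
            slice(o, o + stride * n, stride) for o, n in zip(off, out)
        )
        src = (slice(None), slice(None)) + tuple(slice(None) for _ in out) + off
        dxp[(slice(None), slice(None)) + dst] += dcols[src]
    if pad:
        crop = (slice(None), slice(None)) + tuple(slice(pad, pad + s) for s in x_spatial)
        return dxp[crop]
    return dxp
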