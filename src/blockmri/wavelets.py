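"""Orthonormal periodic Daubechies wavelet transform (4-tap D4 filters).

The analysis filters have closed-form coefficients, the boundary handling
is periodic, and synthesis is the exact transpose of analysis, so the
multilevel 3D transform is an orthonormal change of basis: it preserves
the L2 norm and inverts exactly. Coefficients are packed in place
(wavedec-style: the level-l lowpass block occupies the leading
``n / 2**l`` samples along each axis).
"""

from __future__ import annotations

import numpy as np

__all__ = ["D4_LOWPASS", "D4_HIGHPASS", "dwt3", "idwt3", "max_levels"]

_S3 = np.sqrt(3.0)
D4_LOWPASS = np.array([1.0 + _S3, 3.0 + _S3, 3.0 - _S3, 1.0 - _S3]) / (4.0 * np.sqrt(2.0))
# quadrature mirror: g[n] = (-1)^n h[L-1-n]
D4_HIGHPASS = np.array([D4_LOWPASS[3], -D4_LOWPASS[2], D4_LOWPASS[1], -D4_LOWPASS[0]])


def max_levels(shape, requested: int = 3) -> int:
    """Largest level count <= requested with every axis divisible by 2^levels."""
    lv = 0
    while lv < requested and all(n % 2 ** (lv + 1) == 0 and n // 2 ** (lv + 1) >= 1
                                 for n in shape):
        lv += 1
    return lv


def _analysis_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """One periodic D4 analysis step along ``axis``: [approx | detail]."""
    x = np.moveaxis(x, axis, 0)
    L = x.shape[0]
    if L % 2:
        raise ValueError("axis length must be even")
    idx = (2 * np.arange(L // 2)[:, None] + np.arange(4)[None, :]) % L
    taps = x[idx]  # (L/2, 4, ...)
    a = np.tensordot(D4_LOWPASS, np.moveaxis(taps, 1, 0), axes=([0], [0]))
    d = np.tensordot(D4_HIGHPASS, np.moveaxis(taps, 1, 0), axes=([0], [0]))
    return np.moveaxis(np.concatenate([a, d], axis=0), 0, axis)


def _synthesis_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Exact transpose of :func:`_analysis_axis`."""
    x = np.moveaxis(x, axis, 0)
    L = x.shape[0]
    a, d = x[: L // 2], x[L // 2:]
    out = np.zeros_like(x)
    idx = (2 * np.arange(L // 2)[:, None] + np.arange(4)[None, :]) % L
    for k in range(4):
        np.add.at(out, idx[:, k], D4_LOWPASS[k] * a + D4_HIGHPASS[k] * d)
    return np.moveaxis(out, 0, axis)


def dwt3(x: np.ndarray, levels: int = 3) -> np.ndarray:
    """Multilevel separable 3D DWT; orthonormal, periodic."""
    x = np.asarray(x)
    levels = max_levels(x.shape, levels)
    out = x.copy()
    for lv in range(levels):
        sl = tuple(slice(0, n // 2**lv) for n in x.shape)
        block = out[sl]
        for axis in range(3):
            block = _analysis_axis(block, axis)
        out[sl] = block
    return out


def idwt3(c: np.ndarray, levels: int = 3) -> np.ndarray:
    """Inverse of :func:`dwt3` (exact, being the transpose)."""
    c = np.asarray(c)
    levels = max_levels(c.shape, levels)
    out = c.copy()
    for lv in reversed(range(levels)):
        sl = tuple(slice(0, n // 2**lv) for n in c.shape)
        block = out[sl]
        for axis in reversed(range(3)):
            block = _synthesis_axis(block, axis)
        out[sl] = block
    return out
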