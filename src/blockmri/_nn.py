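"""Minimal reverse-mode engine for bias-free 3D conv networks.

The regularizer is small (a handful of 3×3×3 convolutions and LeakyReLU
activations), so rather than depending on a deep-learning framework the
layers implement explicit forward/backward passes on float64 arrays in
``(channels, nx, ny, nz)`` layout. The functional cache style makes the
checkpointing contract literal: a forward pass either returns its
activation cache or it doesn't, and a discarded cache is rebuilt by
re-running the identical forward computation, so recomputed gradients are
bit-identical to stored-cache gradients.

Gradient correctness is pinned by central-difference oracles in the tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv3d", "LeakyReLU", "Sequential", "ResBlock", "ResNet2ch"]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def cache_elements(self, in_shape) -> int:
        """Element count of the activation cache a forward pass would keep."""
        return 0

    def out_shape(self, in_shape):
        return tuple(in_shape)


def _kernel_offsets(kshape):
    return [
        (i, j, k)
        for i in range(kshape[0])
        for j in range(kshape[1])
        for k in range(kshape[2])
    ]


class Conv3d(Module):
    """Zero-padded, stride-1, bias-free 3D convolution (cross-correlation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel=(3, 3, 3),
                 leaky_slope_for_init: float = 0.01, rng=None, scale: float = 1.0):
        kernel = tuple(int(k) for k in kernel)
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel sizes must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(kernel))
        gain = np.sqrt(2.0 / (1.0 + leaky_slope_for_init**2))
        std = scale * gain / np.sqrt(fan_in)
        self.weight = Param(rng.standard_normal((out_channels, in_channels) + kernel) * std)
        self.kernel = kernel
        self.pad = tuple((k - 1) // 2 for k in kernel)

    @property
    def receptive_radius(self):
        return self.pad

    def params(self):
        return [self.weight]

    def _padded(self, x):
        p = self.pad
        return np.pad(x, ((0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))

    def forward(self, x: np.ndarray, want_cache: bool = True):
        W = self.weight.value
        xp = self._padded(x)
        X, Y, Z = x.shape[1:]
        out = np.zeros((W.shape[0], X, Y, Z), dtype=x.dtype)
        for (i, j, k) in _kernel_offsets(self.kernel):
            out += np.tensordot(W[:, :, i, j, k], xp[:, i:i + X, j:j + Y, k:k + Z],
                                axes=([1], [0]))
        return out, (x if want_cache else None)

    def backward(self, grad_out: np.ndarray, cache):
        x = cache
        W = self.weight.value
        xp = self._padded(x)
        X, Y, Z = x.shape[1:]
        p = self.pad
        gxp = np.zeros_like(xp)
        for (i, j, k) in _kernel_offsets(self.kernel):
            self.weight.grad[:, :, i, j, k] += np.real(
                np.tensordot(grad_out, xp[:, i:i + X, j:j + Y, k:k + Z].conj(),
                             axes=([1, 2, 3], [1, 2, 3]))
            )
            gxp[:, i:i + X, j:j + Y, k:k + Z] += np.tensordot(
                W[:, :, i, j, k].T, grad_out, axes=([1], [0])
            )
        return gxp[:, p[0]:p[0] + X, p[1]:p[1] + Y, p[2]:p[2] + Z]

    def cache_elements(self, in_shape) -> int:
        return int(np.prod(in_shape))

    def out_shape(self, in_shape):
        return (self.weight.value.shape[0],) + tuple(in_shape[1:])


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = float(slope)

    receptive_radius = (0, 0, 0)

    def forward(self, x: np.ndarray, want_cache: bool = True):
        pos = x >= 0
        out = np.where(pos, x, self.slope * x)
        return out, (pos if want_cache else None)

    def backward(self, grad_out: np.ndarray, cache):
        pos = cache
        return np.where(pos, grad_out, self.slope * grad_out)

    def cache_elements(self, in_shape) -> int:
        # boolean mask stored per activation element
        return int(np.prod(in_shape))


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def receptive_radius(self):
        r = np.zeros(3, dtype=int)
        for layer in self.layers:
            r += np.asarray(getattr(layer, "receptive_radius", (0, 0, 0)))
        return tuple(int(v) for v in r)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, want_cache: bool = True):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, want_cache=want_cache)
            caches.append(c)
        return x, (caches if want_cache else None)

    def backward(self, grad_out, cache):
        for layer, c in zip(reversed(self.layers), reversed(cache)):
            grad_out = layer.backward(grad_out, c)
        return grad_out

    def cache_elements(self, in_shape) -> int:
        shape = tuple(in_shape)
        total = 0
        for layer in self.layers:
            total += layer.cache_elements(shape)
            shape = layer.out_shape(shape)
        return total

    def out_shape(self, in_shape):
        shape = tuple(in_shape)
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape


class ResBlock(Module):
    """conv – LeakyReLU – conv with an identity skip connection."""

    def __init__(self, channels: int, kernel=(3, 3, 3), slope: float = 0.01,
                 rng=None):
        self.body = Sequential(
            Conv3d(channels, channels, kernel, slope, rng),
            LeakyReLU(slope),
            Conv3d(channels, channels, kernel, slope, rng),
        )

    @property
    def receptive_radius(self):
        return self.body.receptive_radius

    def params(self):
        return self.body.params()

    def forward(self, x, want_cache: bool = True):
        y, c = self.body.forward(x, want_cache=want_cache)
        return x + y, c

    def backward(self, grad_out, cache):
        return grad_out + self.body.backward(grad_out, cache)

    def cache_elements(self, in_shape) -> int:
        return self.body.cache_elements(in_shape)


class ResNet2ch(Module):
    """Bias-free residual CNN on 2-channel (real/imag) fields.

    Structure: input conv (2 → channels), ``n_res_blocks`` residual blocks,
    output conv (channels → 2). No global residual here — that lives at the
    complex level in the regularizer wrapper. With all-zero weights the
    output is identically zero.
    """

    def __init__(self, channels: int = 32, kernel=(3, 3, 3),
                 n_res_blocks: int = 2, slope: float = 0.01, seed: int = 0):
        rng = np.random.default_rng(seed)
        layers = [Conv3d(2, channels, kernel, slope, rng)]
        layers += [ResBlock(channels, kernel, slope, rng) for _ in range(n_res_blocks)]
        # small output-conv init keeps the initial model near the identity
        layers += [Conv3d(channels, 2, kernel, slope, rng, scale=0.1)]
        self.net = Sequential(*layers)
        self.channels = channels
        self.n_res_blocks = n_res_blocks
        self.slope = slope

    @property
    def receptive_radius(self):
        return self.net.receptive_radius

    @property
    def n_convs(self) -> int:
        return 2 + 2 * self.n_res_blocks

    def params(self):
        return self.net.params()

    def forward(self, x, want_cache: bool = True):
        return self.net.forward(x, want_cache=want_cache)

    def backward(self, grad_out, cache):
        return self.net.backward(grad_out, cache)

    def cache_elements(self, in_shape) -> int:
        return self.net.cache_elements((2,) + tuple(in_shape[-3:]))
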