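"""Unrolled reconstruction model.

Each unroll applies the CNN regularizer block-by-block (patch extraction,
per-patch checkpointed forward, core recomposition) and then a gradient
data-consistency step with a learnable, softplus-positive step size,
accumulated one k-space channel at a time.

Complex volumes cross the CNN as 2-channel real/imaginary fields. The
global residual connection is applied at the complex level, so a
zero-weight network is exactly the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import Param, ResNet2ch
from .blockwise import BlockScheme, BlockwiseModule, MemoryLedger
from .forward_model import EncodingOperator
from .types import KSpaceData, as_array

__all__ = [
    "RegularizerConfig",
    "complex_to_channels",
    "channels_to_complex",
    "ComplexRegularizer",
    "regularize",
    "dc_step",
    "UnrolledModel",
    "unrolled_reconstruct",
]


def complex_to_channels(x) -> np.ndarray:
    """Complex volume -> (2, nx, ny, nz) real field; exact round trip."""
    xa = as_array(x)
    return np.stack([xa.real, xa.imag]).astype(np.float64)


def channels_to_complex(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c)
    if c.shape[0] != 2:
        raise ValueError("expected a 2-channel field")
    return c[0] + 1j * c[1]


@dataclass
class RegularizerConfig:
    """Residual-network regularizer hyperparameters.

    ``bias`` must stay False: the bias-free network maps zero to zero and,
    with the global residual, zero weights give the identity.
    """

    channels: int = 32
    kernel: tuple[int, int, int] = (3, 3, 3)
    n_res_blocks: int = 2
    bias: bool = False
    leaky_slope: float = 0.01
    init_seed: int = 0

    def __post_init__(self):
        if self.bias:
            raise ValueError("only bias-free networks are supported")
        self.kernel = tuple(int(k) for k in self.kernel)

    @property
    def n_convs(self) -> int:
        return 2 + 2 * self.n_res_blocks

    @property
    def receptive_radius(self) -> tuple[int, int, int]:
        per_conv = tuple((k - 1) // 2 for k in self.kernel)
        return tuple(self.n_convs * r for r in per_conv)

    def build(self) -> "ComplexRegularizer":
        return ComplexRegularizer(self)

    def to_dict(self) -> dict:
        return {
            "channels": self.channels,
            "kernel": list(self.kernel),
            "n_res_blocks": self.n_res_blocks,
            "bias": self.bias,
            "leaky_slope": self.leaky_slope,
            "init_seed": self.init_seed,
        }


class ComplexRegularizer:
    """The residual CNN lifted to complex patches.

    forward: convert to 2 channels, run the bias-free resnet, convert back,
    add the input (global residual).
    """

    def __init__(self, config: RegularizerConfig):
        self.config = config
        self.net = ResNet2ch(
            channels=config.channels,
            kernel=config.kernel,
            n_res_blocks=config.n_res_blocks,
            slope=config.leaky_slope,
            seed=config.init_seed,
        )

    @property
    def receptive_radius(self):
        return self.net.receptive_radius

    def params(self):
        return self.net.params()

    def zero_grad(self):
        self.net.zero_grad()

    def forward(self, x: np.ndarray, want_cache: bool = True):
        x2 = complex_to_channels(x)
        y2, cache = self.net.forward(x2, want_cache=want_cache)
        return x + channels_to_complex(y2), cache

    def backward(self, grad_out: np.ndarray, cache):
        g2 = complex_to_channels(grad_out)
        gx2 = self.net.backward(g2, cache)
        return grad_out + channels_to_complex(gx2)

    def cache_elements(self, in_shape) -> int:
        # the regularizer sees 2-channel real fields of the patch's shape
        return self.net.cache_elements(tuple(in_shape[-3:]))


def regularize(x, reg: ComplexRegularizer, scheme: BlockScheme,
               checkpointed: bool = True,
               allow_halo_violation: bool = False) -> np.ndarray:
    """Apply the regularizer patch-by-patch (inference path)."""
    mod = BlockwiseModule(reg, scheme, checkpointed=checkpointed,
                          allow_halo_violation=allow_halo_violation)
    out, _ = mod.forward(as_array(x), train=False)
    return out


def _dc_gradient(x: np.ndarray, y: KSpaceData, op: EncodingOperator) -> np.ndarray:
    """E^H(Ex - y), accumulated channel by channel in channel-index order."""
    samples = y.samples if isinstance(y, KSpaceData) else np.atleast_2d(y)
    if samples.shape[0] != op.n_channels:
        raise ValueError("k-space channel count does not match operator")
    grad = np.zeros(op.shape, dtype=np.complex128)
    for c in range(op.n_channels):
        resid_c = op.encode_channel(x, c) - samples[c]
        grad += op.encode_adjoint_channel(resid_c, c)
    return grad


def dc_step(x, y: KSpaceData, op: EncodingOperator, t: float,
            checkpointed: bool = True) -> np.ndarray:
    """One data-consistency gradient step: x - t · E^H(Ex - y).

    The ``checkpointed`` flag mirrors the training contract (each channel's
    forward+adjoint pass is recomputed rather than cached during gradient
    propagation); the numerical result is identical in both modes.
    """
    xa = as_array(x)
    if xa.shape != op.shape:
        raise ValueError(f"volume shape {xa.shape} != operator grid {op.shape}")
    return xa - t * _dc_gradient(xa, y, op)


def _softplus(v: float) -> float:
    return float(np.log1p(np.exp(-abs(v))) + max(v, 0.0))


def _softplus_inv(s: float) -> float:
    return float(np.log(np.expm1(s)))


def _sigmoid(v: float) -> float:
    return float(1.0 / (1.0 + np.exp(-v)))


class UnrolledModel:
    """N unrolls of (block-wise CNN regularizer, DC gradient step).

    Regularizer weights are unshared across unrolls unless
    ``share_weights=True``. Step sizes are one learnable scalar per unroll,
    softplus-parameterized positive, initialized to 1. ``n_unrolls = 0``
    is the identity; ``network_only=True`` instead builds the no-DC arm
    (a single regularizer pass).
    """

    def __init__(self, n_unrolls: int, config: RegularizerConfig,
                 scheme: BlockScheme, share_weights: bool = False,
                 network_only: bool = False, step_init: float = 1.0):
        if n_unrolls < 0:
            raise ValueError("n_unrolls must be >= 0")
        if network_only and n_unrolls != 0:
            raise ValueError("network_only implies n_unrolls = 0")
        self.n_unrolls = int(n_unrolls)
        self.config = config
        self.scheme = scheme
        self.share_weights = bool(share_weights)
        self.network_only = bool(network_only)
        n_regs = 1 if (network_only or share_weights) else n_unrolls
        self.regularizers = []
        for k in range(n_regs):
            cfg_k = RegularizerConfig(**{**config.to_dict(),
                                         "init_seed": config.init_seed + k})
            self.regularizers.append(cfg_k.build())
        self.raw_steps = [
            Param(np.array(_softplus_inv(step_init))) for _ in range(n_unrolls)
        ]

    # -- parameter plumbing -------------------------------------------------
    def _reg(self, k: int) -> ComplexRegularizer:
        return self.regularizers[0 if (self.share_weights or self.network_only)
                                 else k]

    @property
    def step_sizes(self) -> list[float]:
        return [_softplus(float(p.value)) for p in self.raw_steps]

    def params(self) -> list[Param]:
        out = []
        for reg in self.regularizers:
            out.extend(reg.params())
        out.extend(self.raw_steps)
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- execution ----------------------------------------------------------
    def forward(self, x0, y: KSpaceData, op: EncodingOperator,
                checkpointed: bool = True,
                ledger: MemoryLedger | None = None) -> np.ndarray:
        x = as_array(x0)
        if self.network_only:
            mod = BlockwiseModule(self._reg(0), self.scheme,
                                  checkpointed=checkpointed, ledger=ledger)
            out, _ = mod.forward(x, train=False)
            return out
        for k in range(self.n_unrolls):
            mod = BlockwiseModule(self._reg(k), self.scheme,
                                  checkpointed=checkpointed, ledger=ledger)
            z, _ = mod.forward(x, train=False)
            x = dc_step(z, y, op, self.step_sizes[k], checkpointed=checkpointed)
        return x

    def forward_train(self, x0, y: KSpaceData, op: EncodingOperator,
                      checkpointed: bool = True,
                      ledger: MemoryLedger | None = None):
        """Forward pass retaining per-unroll inputs (the (N+1)·Mem_x state).

        Returns ``(output, ctx)``; pass ``ctx`` to :meth:`backward`.
        """
        x = as_array(x0)
        if self.network_only:
            mod = BlockwiseModule(self._reg(0), self.scheme,
                                  checkpointed=checkpointed, ledger=ledger)
            out, bctx = mod.forward(x, train=True)
            return out, {"mode": "network_only", "bctx": bctx, "mod": mod}
        xs = [x]  # unroll-level checkpoints
        bctxs = []
        for k in range(self.n_unrolls):
            mod = BlockwiseModule(self._reg(k), self.scheme,
                                  checkpointed=checkpointed, ledger=ledger)
            z, bctx = mod.forward(x, train=True)
            x = dc_step(z, y, op, self.step_sizes[k], checkpointed=checkpointed)
            xs.append(x)
            bctxs.append((mod, bctx))
        return x, {"mode": "unrolled", "xs": xs, "bctxs": bctxs,
                   "y": y, "op": op, "checkpointed": checkpointed}

    def backward(self, grad_out: np.ndarray, ctx) -> np.ndarray:
        """Accumulate parameter gradients; returns gradient w.r.t. x0."""
        if ctx["mode"] == "network_only":
            return ctx["mod"].backward(grad_out, ctx["bctx"])
        y, op = ctx["y"], ctx["op"]
        g = np.asarray(grad_out, dtype=np.complex128)
        for k in reversed(range(self.n_unrolls)):
            mod, bctx = ctx["bctxs"][k]
            t_k = self.step_sizes[k]
            # recompute z_k = regularizer(x_{k-1}) for the step-size gradient
            z, _ = mod.forward(ctx["xs"][k], train=False)
            dc_grad = _dc_gradient(z, y, op)
            # d/dt: out = z - t * E^H(Ez - y)
            gt = -float(np.real(np.vdot(g, dc_grad)))
            self.raw_steps[k].grad += gt * _sigmoid(float(self.raw_steps[k].value))
            # d/dz: (I - t E^H E) applied to g (self-adjoint linear part)
            gz = g - t_k * op.normal(g)
            g = mod.backward(gz, bctx)
        return g

    # -- serialization ------------------------------------------------------
    def config_dict(self) -> dict:
        return {
            "n_unrolls": self.n_unrolls,
            "regularizer": self.config.to_dict(),
            "scheme": json.loads(self.scheme.to_json()),
            "share_weights": self.share_weights,
            "network_only": self.network_only,
        }

    def save(self, path: str) -> None:
        arrays = {
            f"param_{i}": p.value for i, p in enumerate(self.params())
        }
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "UnrolledModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
            model = cls(
                n_unrolls=cfg["n_unrolls"],
                config=RegularizerConfig(**{**cfg["regularizer"],
                                            "kernel": tuple(cfg["regularizer"]["kernel"])}),
                scheme=BlockScheme(
                    tuple(cfg["scheme"]["volume_shape"]),
                    tuple(cfg["scheme"]["splits"]),
                    tuple(cfg["scheme"]["halo"]),
                ),
                share_weights=cfg["share_weights"],
                network_only=cfg["network_only"],
            )
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
        return model


def unrolled_reconstruct(x0, y: KSpaceData, op: EncodingOperator,
                         model: UnrolledModel,
                         checkpointed: bool = True) -> np.ndarray:
    """Run the unrolled model from an initial image (usually the gridded
    reconstruction). With ``n_unrolls = 0`` (and not network-only) this
    returns ``x0`` unchanged."""
    return model.forward(x0, y, op, checkpointed=checkpointed)
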