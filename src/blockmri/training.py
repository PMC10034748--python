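"""Supervised end-to-end training with per-iteration spoke resampling.

Every training iteration draws a fresh random spoke subset from a dense
"ground truth" acquisition, rebuilds the density compensation and the
normalized encoding operator for that subset, reconstructs the gridded
input, runs the unrolled model under block-wise checkpointing, and takes
one Adam step on the 2-channel MSE loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import (
    EncodingOperator,
    gridded_recon,
    normalize_operator,
    rescale_kspace,
)
from .model import UnrolledModel
from .synthetic import subsample_spokes
from .types import CoilSensitivities, KSpaceData, Trajectory, as_array

__all__ = [
    "TrainConfig",
    "TrainingCase",
    "make_training_example",
    "mse_loss",
    "mse_loss_grad",
    "Adam",
    "TrainingDiverged",
    "train",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    n_iterations: int = 4000
    optimizer: str = "adam"
    spokes_per_example: int = 5000
    seed: int = 0
    checkpointed: bool = True
    power_iters: int = 20
    power_tol: float = 1e-4

    def __post_init__(self):
        if self.n_iterations < 1 or self.spokes_per_example < 1:
            raise ValueError("counts must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainingCase:
    """A dense acquisition plus its fixed supervision target."""

    gt_kspace: KSpaceData
    traj: Trajectory
    maps: CoilSensitivities
    target: np.ndarray  # complex volume

    def __post_init__(self):
        self.target = as_array(self.target)


@dataclass
class OperatorConfig:
    """How to build the per-subset encoding operator."""

    oversamp: float = 1.5
    width: int = 6
    power_iters: int = 20
    power_tol: float = 1e-4


def make_training_example(gt_kspace: KSpaceData, traj: Trajectory,
                          maps: CoilSensitivities, target, n_spokes: int,
                          seed=0, op_config: OperatorConfig | None = None):
    """Draw a random spoke subset and build its normalized operator.

    Returns ``(input_volume, target, subset_operator, subset_kspace)`` where
    the input is the gridded (adjoint) reconstruction of the subset and the
    subset k-space has the operator's normalization factor applied.
    ``seed`` may be a Generator so successive calls draw fresh subsets.
    """
    cfg = op_config or OperatorConfig()
    y_sub, traj_sub, dcf_sub = subsample_spokes(gt_kspace, traj, n_spokes, seed)
    op = EncodingOperator.from_components(maps, traj_sub, dcf_sub,
                                          oversamp=cfg.oversamp, width=cfg.width)
    op = normalize_operator(op, n_iter=cfg.power_iters, tol=cfg.power_tol)
    y_sub = rescale_kspace(op, y_sub)
    x_in = gridded_recon(op, y_sub)
    return x_in, as_array(target), op, y_sub


def mse_loss(pred, target) -> float:
    """Mean squared difference over all voxels and both real/imag channels."""
    p, t = as_array(pred), as_array(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    d = p - t
    return float(np.sum(d.real**2 + d.imag**2) / (2 * d.size))


def mse_loss_grad(pred, target) -> np.ndarray:
    """Gradient of :func:`mse_loss` w.r.t. pred, packed as a complex array."""
    p, t = as_array(pred), as_array(target)
    return (p - t) / p.size


class Adam:
    """Standard Adam over a list of :class:`blockmri._nn.Param`."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TrainingDiverged(RuntimeError):
    def __init__(self, iteration: int, loss: float):
        super().__init__(f"non-finite loss {loss} at iteration {iteration}")
        self.iteration = iteration
        self.loss = loss


def train(model: UnrolledModel, dataset: list[TrainingCase],
          cfg: TrainConfig) -> tuple[UnrolledModel, list[float]]:
    """Train in place; returns the model and the per-iteration loss trace.

    One volume per iteration (batch size 1). Fully deterministic for a
    fixed ``cfg.seed`` and fixed regularizer init seeds.
    """
    if len(dataset) < 1:
        raise ValueError("need at least one training case")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    op_cfg = OperatorConfig(power_iters=cfg.power_iters, power_tol=cfg.power_tol)
    trace: list[float] = []
    for it in range(cfg.n_iterations):
        case = dataset[int(rng.integers(len(dataset)))]
        x_in, target, op, y_sub = make_training_example(
            case.gt_kspace, case.traj, case.maps, case.target,
            cfg.spokes_per_example, seed=rng, op_config=op_cfg,
        )
        pred, ctx = model.forward_train(x_in, y_sub, op,
                                        checkpointed=cfg.checkpointed)
        loss = mse_loss(pred, target)
        if not np.isfinite(loss):
            raise TrainingDiverged(it, loss)
        trace.append(loss)
        model.zero_grad()
        model.backward(mse_loss_grad(pred, target), ctx)
        opt.step()
    return model, trace
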