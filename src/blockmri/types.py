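"""Core data containers shared across the package.

All heavy numerics operate on plain :class:`numpy.ndarray`; these containers
carry the arrays together with the minimal metadata needed to keep shapes,
channel counts and sampling geometry consistent, and they validate their
invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "CoilSensitivities",
    "Trajectory",
    "DensityCompensation",
    "KSpaceData",
    "as_array",
]


def as_array(x) -> np.ndarray:
    """Unwrap an :class:`ImageVolume` (or pass an ndarray through)."""
    if isinstance(x, ImageVolume):
        return x.data
    return np.asarray(x)


@dataclass
class ImageVolume:
    """A complex 3D image volume.

    Parameters
    ----------
    data:
        Complex scalar field over an ``(nx, ny, nz)`` voxel grid.
    voxel_size:
        Edge length per voxel in mm. Metadata only; never enters numerics.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(n < 8 for n in self.data.shape):
            raise ValueError(f"all dimensions must be >= 8, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CoilSensitivities:
    """Per-channel complex sensitivity maps over the image grid."""

    maps: np.ndarray  # (n_channels, nx, ny, nz)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 4:
            raise ValueError("maps must be (n_channels, nx, ny, nz)")
        if self.normalized:
            sos = np.sum(np.abs(self.maps) ** 2, axis=0)
            if not np.allclose(sos, 1.0, atol=1e-6):
                raise ValueError("normalized maps must satisfy sum |S_c|^2 = 1")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


@dataclass
class Trajectory:
    """3D radial sampling trajectory in units of cycles/FOV.

    ``coords`` has layout ``(n_spokes, n_readout, 3)`` with every spoke
    starting at k = 0 (center-out). ``ordering`` records the acquisition-order
    permutation applied to the underlying spoke directions.
    """

    coords: np.ndarray
    ordering: np.ndarray = None
    grid_n: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("coords must be (n_spokes, n_readout, 3)")
        if self.ordering is None:
            self.ordering = np.arange(self.coords.shape[0])
        self.ordering = np.asarray(self.ordering, dtype=np.int64)
        if self.ordering.shape != (self.coords.shape[0],):
            raise ValueError("ordering must have one entry per spoke")
        if not np.allclose(self.coords[:, 0, :], 0.0, atol=1e-9):
            raise ValueError("every spoke must start at k = 0 (center-out radial)")

    @property
    def n_spokes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_readout(self) -> int:
        return self.coords.shape[1]

    @property
    def n_samples(self) -> int:
        return self.n_spokes * self.n_readout

    @property
    def points(self) -> np.ndarray:
        """All samples flattened to ``(n_samples, 3)`` in spoke-major order."""
        return self.coords.reshape(-1, 3)


@dataclass
class DensityCompensation:
    """Non-negative per-sample density compensation weights."""

    weights: np.ndarray  # (n_samples,)
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("dcf weights must be finite and >= 0")
        if not np.isfinite(self.scale):
            raise ValueError("dcf scale must be finite")


@dataclass
class KSpaceData:
    """Multi-channel k-space samples paired with their trajectory."""

    samples: np.ndarray  # (n_channels, n_samples)
    traj: Trajectory = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_channels, n_samples)")
        if self.traj is not None and self.samples.shape[1] != self.traj.n_samples:
            raise ValueError(
                f"sample count {self.samples.shape[1]} does not match "
                f"trajectory ({self.traj.n_samples})"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]
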