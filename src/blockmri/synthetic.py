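"""Synthetic acquisition generator.

Produces phantoms, smooth coil maps, center-out 3D radial ("kooshball")
trajectories with a bit-reversed acquisition ordering, analytic radial
density compensation, and simulated multi-coil k-space — everything needed
to exercise the reconstruction stack without scanner data.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CoilSensitivities,
    DensityCompensation,
    ImageVolume,
    KSpaceData,
    Trajectory,
    as_array,
)

__all__ = [
    "ellipsoid_mask",
    "make_phantom",
    "make_coil_maps",
    "make_trajectory",
    "bit_reversed_order",
    "make_dcf",
    "simulate_acquisition",
    "subsample_spokes",
    "pca_coil_compress",
]

_GOLDEN_FRAC = (np.sqrt(5.0) - 1.0) / 2.0


def _centered_grid(shape):
    return np.meshgrid(
        *[np.arange(n, dtype=np.float64) - n // 2 for n in shape], indexing="ij"
    )


def ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    """Boolean mask of voxels with x²/a² + y²/b² + z²/c² <= 1.

    ``center`` is given in centered voxel coordinates (0 = grid center voxel
    ``n // 2``).
    """
    gx, gy, gz = _centered_grid(shape)
    cx, cy, cz = center
    a, b, c = semiaxes
    return ((gx - cx) / a) ** 2 + ((gy - cy) / b) ** 2 + ((gz - cz) / c) ** 2 <= 1.0


def _quadratic_bezier(p0, p1, p2, t):
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _rasterize_tube(shape, p0, p1, p2, radius, out, amplitude):
    """Add a curved tube (quadratic Bezier centerline) to ``out``."""
    n_pts = int(4 * max(shape))
    pts = _quadratic_bezier(np.asarray(p0), np.asarray(p1), np.asarray(p2),
                            np.linspace(0.0, 1.0, n_pts))
    r = int(np.ceil(radius))
    offs = np.stack(
        np.meshgrid(*[np.arange(-r, r + 1)] * 3, indexing="ij"), -1
    ).reshape(-1, 3)
    ball = offs[np.linalg.norm(offs, axis=1) <= radius]
    centers = np.rint(pts).astype(int)
    vox = (centers[:, None, :] + ball[None, :, :]).reshape(-1, 3)
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox = vox[ok]
    out[vox[:, 0], vox[:, 1], vox[:, 2]] = np.maximum(
        out[vox[:, 0], vox[:, 1], vox[:, 2]], amplitude
    )


def make_phantom(shape, n_ellipsoids: int = 4, n_tubes: int = 3,
                 seed: int = 0, voxel_size=(1.0, 1.0, 1.0)) -> ImageVolume:
    """Random ellipsoid + curved-tube phantom with a smooth complex phase.

    Magnitude lies in [0, 1]; with zero counts the volume is identically
    zero. Deterministic for a fixed seed.
    """
    shape = tuple(int(n) for n in shape)
    if any(n <= 0 for n in shape):
        raise ValueError(f"non-positive dimensions: {shape}")
    if any(n < 8 for n in shape):
        raise ValueError(f"all dimensions must be >= 8, got {shape}")
    rng = np.random.default_rng(seed)
    mag = np.zeros(shape, dtype=np.float64)
    N = np.array(shape, dtype=float)

    for _ in range(int(n_ellipsoids)):
        center = rng.uniform(-0.3, 0.3, size=3) * N
        semi = rng.uniform(0.08, 0.28, size=3) * N
        amp = rng.uniform(0.3, 1.0)
        m = ellipsoid_mask(shape, center, semi)
        mag[m] = np.maximum(mag[m], amp)

    for _ in range(int(n_tubes)):
        # control points in voxel-index space, radius 1-3 voxels
        p = rng.uniform(0.15, 0.85, size=(3, 3)) * N
        radius = rng.uniform(1.0, 3.0)
        amp = rng.uniform(0.5, 1.0)
        _rasterize_tube(shape, p[0], p[1], p[2], radius, mag, amp)

    mag = np.clip(mag, 0.0, 1.0)
    # smooth low-order polynomial phase over the unit cube
    gx, gy, gz = [g / max(n, 1) for g, n in zip(_centered_grid(shape), shape)]
    coef = rng.uniform(-1.0, 1.0, size=6)
    phase = (coef[0] * gx + coef[1] * gy + coef[2] * gz
             + coef[3] * gx * gy + coef[4] * gy * gz + coef[5] * gx * gz)
    return ImageVolume(mag * np.exp(1j * np.pi * phase), voxel_size=voxel_size)


def make_coil_maps(shape, n_channels: int, seed: int = 0, *,
                   normalized: bool = True, uniform: bool = False) -> CoilSensitivities:
    """Smooth band-limited complex coil sensitivity maps.

    Each channel is a broad Gaussian profile centered outside the FOV edge
    with a slowly varying phase. ``normalized=True`` rescales so the
    per-voxel sum of squared magnitudes is exactly 1. ``uniform=True`` with
    one channel yields the identity (all-ones) coil.
    """
    shape = tuple(int(n) for n in shape)
    n_channels = int(n_channels)
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if uniform:
        maps = np.ones((n_channels,) + shape, dtype=np.complex128)
        maps /= np.sqrt(n_channels) if normalized else 1.0
        return CoilSensitivities(maps, normalized=normalized)

    rng = np.random.default_rng(seed)
    gx, gy, gz = _centered_grid(shape)
    N = np.array(shape, dtype=float)
    maps = np.empty((n_channels,) + shape, dtype=np.complex128)
    for c in range(n_channels):
        # coil center on a sphere of radius ~0.7 FOV
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        center = 0.7 * u * N / 2
        width = rng.uniform(0.6, 1.0) * N
        prof = np.exp(
            -(((gx - center[0]) / width[0]) ** 2
              + ((gy - center[1]) / width[1]) ** 2
              + ((gz - center[2]) / width[2]) ** 2)
        )
        pc = rng.uniform(-1.0, 1.0, size=3)
        phase = np.pi * (pc[0] * gx / N[0] + pc[1] * gy / N[1] + pc[2] * gz / N[2])
        maps[c] = prof * np.exp(1j * phase)
    if normalized:
        sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        maps /= sos[None]
    return CoilSensitivities(maps, normalized=normalized)


def bit_reversed_order(n: int) -> np.ndarray:
    """Bit-reversal permutation of 0..n-1 (indices >= n are skipped)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    nbits = max(1, int(np.ceil(np.log2(n))))
    j = np.arange(2**nbits, dtype=np.uint64)
    rev = np.zeros_like(j)
    for b in range(nbits):
        rev |= ((j >> np.uint64(b)) & np.uint64(1)) << np.uint64(nbits - 1 - b)
    return rev[rev < n].astype(np.int64)


def _sphere_spiral_directions(n: int) -> np.ndarray:
    """Near-uniform spoke directions via a golden-means spherical spiral."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * _GOLDEN_FRAC * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def make_trajectory(n_spokes: int, n_readout: int, grid_n: int,
                    ordering_mode: str = "bit_reversed") -> Trajectory:
    """Center-out 3D radial trajectory covering |k| in [0, grid_n / 2].

    Spoke directions come from a golden-means spherical spiral; the
    acquisition order is either ``sequential`` (spiral order) or
    ``bit_reversed`` (bit-reversal permutation of the spiral index, a
    pseudorandom interleaving so any contiguous subset covers the sphere).
    """
    n_spokes, n_readout = int(n_spokes), int(n_readout)
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    if n_readout < 2:
        raise ValueError("n_readout must be >= 2")
    if ordering_mode not in ("sequential", "bit_reversed"):
        raise ValueError(f"unknown ordering_mode {ordering_mode!r}")
    dirs = _sphere_spiral_directions(n_spokes)
    if ordering_mode == "bit_reversed":
        order = bit_reversed_order(n_spokes)
    else:
        order = np.arange(n_spokes)
    dirs = dirs[order]
    radii = np.linspace(0.0, grid_n / 2.0, n_readout)
    coords = dirs[:, None, :] * radii[None, :, None]
    return Trajectory(coords=coords, ordering=order, grid_n=int(grid_n))


def make_dcf(traj: Trajectory) -> DensityCompensation:
    """Analytic 3D-radial density compensation: w = max(|k|², floor).

    The floor is the |k|² of the first readout point past the spoke center,
    keeping the k = 0 sample at a small positive weight.
    """
    pts = traj.points
    r2 = np.sum(pts**2, axis=1)
    nonzero = r2[r2 > 0]
    floor = float(nonzero.min()) if nonzero.size else 1.0
    return DensityCompensation(np.maximum(r2, floor), scale=1.0)


def simulate_acquisition(x, S: CoilSensitivities, traj: Trajectory,
                         noise_sigma: float = 0.0, seed: int = 0) -> KSpaceData:
    """Forward-simulate multi-coil k-space: NUFFT(S_c ⊙ x) + complex noise.

    Uses the unitary NUFFT convention (DFT sum divided by sqrt(n_voxels)).
    With ``noise_sigma = 0`` the result is deterministic regardless of seed.
    """
    from .forward_model import NufftPlan  # local import avoids cycle at import time

    xa = as_array(x)
    if xa.shape != S.grid_shape:
        raise ValueError(f"phantom shape {xa.shape} != map grid {S.grid_shape}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    plan = NufftPlan(traj.points, xa.shape)
    samples = np.stack([plan.forward(S.maps[c] * xa) for c in range(S.n_channels)])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        samples = samples + noise_sigma * noise / np.sqrt(2.0)
    return KSpaceData(samples=samples, traj=traj)


def subsample_spokes(y: KSpaceData, traj: Trajectory, n_keep: int, seed=0):
    """Uniform random spoke subset without replacement, relative order kept.

    ``seed`` may be an int or a ``numpy.random.Generator`` (so callers can
    draw a fresh subset per training iteration from one stream). Returns the
    subset k-space, trajectory, and a freshly computed DCF.
    """
    n_keep = int(n_keep)
    if n_keep > traj.n_spokes:
        raise ValueError(f"n_keep={n_keep} > n_spokes={traj.n_spokes}")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(traj.n_spokes, size=n_keep, replace=False))
    sub_coords = traj.coords[idx]
    sub_order = np.argsort(np.argsort(traj.ordering[idx]))
    sub_traj = Trajectory(coords=sub_coords, ordering=sub_order, grid_n=traj.grid_n)
    samp = y.samples.reshape(y.n_channels, traj.n_spokes, traj.n_readout)[:, idx]
    sub_y = KSpaceData(samples=samp.reshape(y.n_channels, -1), traj=sub_traj)
    return sub_y, sub_traj, make_dcf(sub_traj)


def pca_coil_compress(y: KSpaceData, n_out: int) -> KSpaceData:
    """Project channels onto the top principal components of the channel
    covariance estimated from the samples. Total energy is non-increasing."""
    n_out = int(n_out)
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    if n_out > y.n_channels:
        raise ValueError(f"n_out={n_out} > n_channels={y.n_channels}")
    cov = (y.samples @ y.samples.conj().T) / y.n_samples
    vals, vecs = np.linalg.eigh(cov)
    top = vecs[:, np.argsort(vals)[::-1][:n_out]]  # (C, n_out)
    return KSpaceData(samples=top.conj().T @ y.samples, traj=y.traj)
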