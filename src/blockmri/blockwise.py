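"""Patch decomposition / recomposition with halo-based edge correction.

A volume is tiled by disjoint block cores. Each extracted patch carries an
extra halo of neighboring-volume voxels, clipped at the volume boundary.
Clipping (rather than zero-filling the exterior) matters: a zero-padded
convolution stack re-pads at every layer, so the only way a patch
reproduces the full-volume computation bit-for-bit is for its boundary to
coincide with the volume boundary wherever the halo would exit it. With
halo >= the operator's receptive radius, each patch core then equals the
full-volume result exactly. Recomposition keeps only each patch's core —
that crop is the internal-edge correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .types import as_array

__all__ = [
    "BlockScheme",
    "plan_blocks",
    "extract_patches",
    "recompose",
    "blockwise_apply",
    "memory_footprint",
    "MemoryLedger",
]


def _as_triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a scalar or 3-tuple, got {v!r}")
    return t


class MemoryLedger:
    """Element-count accounting for live working sets (not hardware bytes)."""

    def __init__(self) -> None:
        self.current = 0
        self.peak = 0

    def alloc(self, n: int) -> None:
        self.current += int(n)
        self.peak = max(self.peak, self.current)

    def free(self, n: int) -> None:
        self.current -= int(n)


@dataclass
class BlockScheme:
    """A P_x × P_y × P_z tiling of a volume with per-axis halo widths.

    Cores are disjoint, tile the volume exactly, and differ by at most one
    voxel per axis (earlier blocks take the remainder). Blocks are ordered
    lexicographically by block index.
    """

    volume_shape: tuple[int, int, int]
    splits: tuple[int, int, int]
    halo: tuple[int, int, int]
    axis_bounds: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.volume_shape = _as_triple(self.volume_shape)
        self.splits = _as_triple(self.splits)
        self.halo = _as_triple(self.halo)
        if any(p < 1 for p in self.splits):
            raise ValueError("splits must be >= 1 per axis")
        if any(h < 0 for h in self.halo):
            raise ValueError("halo must be >= 0")
        if any(p > n for p, n in zip(self.splits, self.volume_shape)):
            raise ValueError(
                f"splits {self.splits} exceed volume shape {self.volume_shape}"
            )
        if not self.axis_bounds:
            self.axis_bounds = []
            for n, p in zip(self.volume_shape, self.splits):
                base, extra = divmod(n, p)
                sizes = [base + (1 if i < extra else 0) for i in range(p)]
                starts = np.concatenate([[0], np.cumsum(sizes)])
                self.axis_bounds.append(
                    [(int(starts[i]), int(starts[i + 1])) for i in range(p)]
                )

    @property
    def n_blocks(self) -> int:
        return int(np.prod(self.splits))

    @property
    def n_internal_faces(self) -> int:
        """Block-adjacency faces needing edge correction:
        sum over axes of (splits_a - 1) * prod(other splits)."""
        p = self.splits
        return ((p[0] - 1) * p[1] * p[2]
                + p[0] * (p[1] - 1) * p[2]
                + p[0] * p[1] * (p[2] - 1))

    def block_indices(self):
        for i in range(self.splits[0]):
            for j in range(self.splits[1]):
                for k in range(self.splits[2]):
                    yield (i, j, k)

    def core_range(self, idx) -> list[tuple[int, int]]:
        return [self.axis_bounds[a][idx[a]] for a in range(3)]

    def extended_range(self, idx) -> list[tuple[int, int]]:
        """Halo-extended half-open ranges, clipped at the volume boundary."""
        return [
            (max(c0 - self.halo[a], 0), min(c1 + self.halo[a], self.volume_shape[a]))
            for a, (c0, c1) in enumerate(self.core_range(idx))
        ]

    def extended_shape(self, idx) -> tuple[int, int, int]:
        return tuple(e1 - e0 for e0, e1 in self.extended_range(idx))

    def core_in_extended(self, idx) -> tuple[slice, slice, slice]:
        """Slices locating the block core inside its extended patch."""
        return tuple(
            slice(c0 - e0, c1 - e0)
            for (c0, c1), (e0, e1) in zip(self.core_range(idx),
                                          self.extended_range(idx))
        )

    def core_slices(self, idx) -> tuple[slice, slice, slice]:
        return tuple(slice(c0, c1) for c0, c1 in self.core_range(idx))

    def extended_slices(self, idx) -> tuple[slice, slice, slice]:
        return tuple(slice(e0, e1) for e0, e1 in self.extended_range(idx))

    @property
    def max_extended_voxels(self) -> int:
        return max(
            int(np.prod(self.extended_shape(idx))) for idx in self.block_indices()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "volume_shape": list(self.volume_shape),
                "splits": list(self.splits),
                "halo": list(self.halo),
                "core_ranges": [
                    [list(map(int, r)) for r in self.core_range(idx)]
                    for idx in self.block_indices()
                ],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "BlockScheme":
        d = json.loads(s)
        return cls(tuple(d["volume_shape"]), tuple(d["splits"]), tuple(d["halo"]))


def plan_blocks(volume_shape, splits, halo=0) -> BlockScheme:
    """Plan a block decomposition; see :class:`BlockScheme`."""
    return BlockScheme(volume_shape, splits, halo)


def extract_patches(x, scheme: BlockScheme) -> list[np.ndarray]:
    """Halo-extended (boundary-clipped) patches in lexicographic block order."""
    xa = as_array(x)
    if xa.shape != scheme.volume_shape:
        raise ValueError(f"volume shape {xa.shape} != scheme {scheme.volume_shape}")
    return [
        xa[tuple(slice(e0, e1) for e0, e1 in scheme.extended_range(idx))].copy()
        for idx in scheme.block_indices()
    ]


def recompose(patches, scheme: BlockScheme) -> np.ndarray:
    """Reassemble the full volume from patches, keeping only each core.

    Cropping the halo is the internal-edge correction: halo voxels were
    computed from (possibly zero-padded) neighbor data and are discarded.
    """
    patches = list(patches)
    if len(patches) != scheme.n_blocks:
        raise ValueError(f"got {len(patches)} patches, expected {scheme.n_blocks}")
    out = None
    for patch, idx in zip(patches, scheme.block_indices()):
        patch = np.asarray(patch)
        if patch.shape != scheme.extended_shape(idx):
            raise ValueError(
                f"patch shape {patch.shape} != expected "
                f"{scheme.extended_shape(idx)} for block {idx}"
            )
        if out is None:
            out = np.zeros(scheme.volume_shape, dtype=patch.dtype)
        out[scheme.core_slices(idx)] = patch[scheme.core_in_extended(idx)]
    return out


def _check_halo(scheme: BlockScheme, f, allow_halo_violation: bool) -> None:
    radius = getattr(f, "receptive_radius", None)
    if radius is None:
        return
    radius = _as_triple(radius)
    if any(h < r for h, r in zip(scheme.halo, radius)) and not allow_halo_violation:
        raise ValueError(
            f"halo {scheme.halo} < receptive radius {radius}; pass "
            "allow_halo_violation=True to run the (approximate) computation anyway"
        )


def blockwise_apply(x, f, scheme: BlockScheme, checkpointed: bool = False,
                    allow_halo_violation: bool = False,
                    ledger: MemoryLedger | None = None) -> np.ndarray:
    """Apply an image-space operator patch-by-patch, sequentially.

    ``f`` is either a plain callable ``patch -> patch`` or a module exposing
    ``forward(patch, want_cache)`` (see :mod:`blockmri._nn`). When the
    scheme's halo covers ``f``'s receptive radius, the result equals the
    full-volume application of ``f``. At most one patch's working set is
    live at a time; with ``checkpointed=True`` any forward cache is dropped
    immediately after each patch (gradient recomputation happens in
    :class:`BlockwiseModule`).
    """
    xa = as_array(x)
    _check_halo(scheme, f, allow_halo_violation)
    out = np.zeros(scheme.volume_shape, dtype=np.result_type(xa.dtype, np.float64))
    has_module_api = hasattr(f, "forward")
    for idx, patch in zip(scheme.block_indices(), _iter_patches(xa, scheme)):
        if has_module_api:
            yp, _ = f.forward(patch, want_cache=False)
            if ledger is not None and hasattr(f, "cache_elements"):
                n = f.cache_elements(patch.shape)
                ledger.alloc(n)
                ledger.free(n)
        else:
            yp = f(patch)
            if ledger is not None:
                ledger.alloc(yp.size)
                ledger.free(yp.size)
        yp = np.asarray(yp)
        if yp.shape != patch.shape:
            raise ValueError("operator changed patch shape")
        out[scheme.core_slices(idx)] = yp[scheme.core_in_extended(idx)]
    return out.astype(xa.dtype) if np.iscomplexobj(xa) else out


def _iter_patches(xa: np.ndarray, scheme: BlockScheme):
    """Generator form of :func:`extract_patches` (one patch live at a time)."""
    for idx in scheme.block_indices():
        yield xa[scheme.extended_slices(idx)].copy()


def _cache_elements(cache) -> int:
    if cache is None:
        return 0
    if isinstance(cache, np.ndarray):
        return cache.size
    if isinstance(cache, (list, tuple)):
        return sum(_cache_elements(c) for c in cache)
    if isinstance(cache, dict):
        return sum(_cache_elements(c) for c in cache.values())
    return 0


class BlockwiseModule:
    """Differentiable patch-wise application of a network module.

    ``forward`` runs the module sequentially over halo-extended patches and
    recomposes cores. With ``checkpointed=True`` per-patch activation caches
    are discarded after each patch's forward pass and recomputed during
    ``backward``; gradients are identical either way (up to floating-point
    round-off of the recomputation, which is exact here since the recompute
    repeats the same operations on the same inputs).
    """

    def __init__(self, net, scheme: BlockScheme, checkpointed: bool = True,
                 allow_halo_violation: bool = False,
                 ledger: MemoryLedger | None = None):
        _check_halo(scheme, net, allow_halo_violation)
        self.net = net
        self.scheme = scheme
        self.checkpointed = checkpointed
        self.ledger = ledger

    @property
    def receptive_radius(self):
        return getattr(self.net, "receptive_radius", (0, 0, 0))

    def forward(self, x: np.ndarray, train: bool = False):
        scheme = self.scheme
        out = np.zeros(scheme.volume_shape, dtype=np.complex128)
        keep_caches = train and not self.checkpointed
        caches = [] if keep_caches else None
        if self.ledger is not None:
            self.ledger.alloc(x.size + out.size)  # input + accumulator
        for idx, patch in zip(scheme.block_indices(), _iter_patches(x, scheme)):
            yp, cache = self.net.forward(patch, want_cache=keep_caches)
            if self.ledger is not None:
                # the forward pass materializes this patch's activations
                # transiently even when the cache is discarded afterwards
                n = _cache_elements(cache) if cache is not None else (
                    self.net.cache_elements(patch.shape)
                    if hasattr(self.net, "cache_elements") else 0
                )
                self.ledger.alloc(n)
                if not keep_caches:
                    self.ledger.free(n)
            if caches is not None:
                caches.append(cache)
            out[scheme.core_slices(idx)] = yp[scheme.core_in_extended(idx)]
        ctx = {"x": x, "caches": caches} if train else None
        if self.ledger is not None:
            self.ledger.free(x.size + out.size)
        return out, ctx

    def backward(self, grad_out: np.ndarray, ctx) -> np.ndarray:
        """Propagate a volume gradient; accumulates the net's parameter
        gradients and returns the gradient w.r.t. the input volume."""
        scheme = self.scheme
        x = ctx["x"]
        caches = ctx["caches"]
        grad_x = np.zeros(scheme.volume_shape, dtype=np.complex128)
        for b, idx in enumerate(scheme.block_indices()):
            gp = np.zeros(scheme.extended_shape(idx), dtype=np.complex128)
            gp[scheme.core_in_extended(idx)] = grad_out[scheme.core_slices(idx)]
            if caches is not None:
                cache = caches[b]
            else:  # checkpointed: recompute this patch's activations
                patch = x[scheme.extended_slices(idx)].copy()
                _, cache = self.net.forward(patch, want_cache=True)
            gin = self.net.backward(gp, cache)
            grad_x[scheme.extended_slices(idx)] += gin
        return grad_x


def memory_footprint(volume_shape, scheme: BlockScheme, n_unrolls: int,
                     activations_per_voxel: int) -> dict:
    """Element-count memory model of block-wise unrolled training.

    Returns, in stored-element units:

    - ``forward_volume_elements``: (N+1) · Mem_x with Mem_x = prod(shape);
    - ``backward_total_elements``: (N+1) · Mem_x + Σ_k I_k where
      I_k = activations_per_voxel × extended-patch-k voxels;
    - ``peak_intermediate_elements``: max_k I_k (the transiently live CNN
      intermediate between checkpointed patches);
    - ``reduction_factor``: full-volume voxels / largest extended patch
      voxels (the CNN-intermediate memory reduction).
    """
    volume_shape = _as_triple(volume_shape)
    if n_unrolls < 0:
        raise ValueError("n_unrolls must be >= 0")
    if activations_per_voxel < 1:
        raise ValueError("activations_per_voxel must be >= 1")
    if tuple(scheme.volume_shape) != volume_shape:
        raise ValueError("scheme volume_shape does not match volume_shape")
    mem_x = int(np.prod(volume_shape))
    patch_voxels = [
        int(np.prod(scheme.extended_shape(idx))) for idx in scheme.block_indices()
    ]
    intermediates = [activations_per_voxel * v for v in patch_voxels]
    return {
        "mem_x": mem_x,
        "forward_volume_elements": (n_unrolls + 1) * mem_x,
        "backward_total_elements": (n_unrolls + 1) * mem_x + sum(intermediates),
        "peak_intermediate_elements": max(intermediates),
        "largest_patch_voxels": max(patch_voxels),
        "reduction_factor": mem_x / max(patch_voxels),
    }
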