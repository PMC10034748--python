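"""HDF5 acquisition container and complex-volume NIfTI round trip."""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np

from .types import (
    CoilSensitivities,
    DensityCompensation,
    ImageVolume,
    KSpaceData,
    Trajectory,
)

__all__ = [
    "save_acquisition",
    "load_acquisition",
    "write_nifti_complex",
    "read_nifti_complex",
]


def save_acquisition(path, kspace: KSpaceData, traj: Trajectory,
                     dcf: DensityCompensation, maps: CoilSensitivities,
                     target=None, voxel_size=(1.0, 1.0, 1.0),
                     seed: int | None = None) -> None:
    """Write /kspace, /coords, /dcf, /maps (and optionally /target)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.samples)
        f.create_dataset("coords", data=traj.points)
        f.create_dataset("dcf", data=dcf.weights)
        f.create_dataset("maps", data=maps.maps)
        f.create_dataset("spoke_ordering", data=traj.ordering)
        if target is not None:
            f.create_dataset("target", data=np.asarray(target, np.complex128))
        f.attrs["grid_shape"] = np.asarray(maps.grid_shape)
        f.attrs["voxel_size"] = np.asarray(voxel_size, float)
        f.attrs["n_spokes"] = traj.n_spokes
        f.attrs["n_readout"] = traj.n_readout
        f.attrs["dcf_scale"] = dcf.scale
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_acquisition(path) -> dict:
    """Load a container written by :func:`save_acquisition`."""
    with h5py.File(path, "r") as f:
        n_spokes = int(f.attrs["n_spokes"])
        n_readout = int(f.attrs["n_readout"])
        coords = f["coords"][...].reshape(n_spokes, n_readout, 3)
        traj = Trajectory(coords=coords, ordering=f["spoke_ordering"][...])
        out = {
            "kspace": KSpaceData(samples=f["kspace"][...], traj=traj),
            "traj": traj,
            "dcf": DensityCompensation(f["dcf"][...],
                                       scale=float(f.attrs["dcf_scale"])),
            "maps": CoilSensitivities(f["maps"][...]),
            "grid_shape": tuple(int(n) for n in f.attrs["grid_shape"]),
            "voxel_size": tuple(float(v) for v in f.attrs["voxel_size"]),
            "seed": int(f.attrs["seed"]) if "seed" in f.attrs else None,
        }
        if "target" in f:
            out["target"] = f["target"][...]
    return out


def write_nifti_complex(path, volume, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Store a complex volume as a 4D NIfTI with real/imag on the 4th axis."""
    vol = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    if isinstance(volume, ImageVolume):
        voxel_size = volume.voxel_size
    data = np.stack([vol.real, vol.imag], axis=-1).astype(np.float64)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti_complex(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[-1] == 2:
        vol = data[..., 0] + 1j * data[..., 1]
    elif data.ndim == 3:
        vol = data.astype(np.complex128)
    else:
        raise ValueError(f"unsupported NIfTI shape {data.shape}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(vol, voxel_size=voxel_size)
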