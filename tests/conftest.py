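import numpy as np
import pytest

from blockmri.forward_model import EncodingOperator, normalize_operator
from blockmri.synthetic import (
    make_coil_maps,
    make_dcf,
    make_phantom,
    make_trajectory,
    simulate_acquisition,
)


def direct_dft(x, coords):
    """Brute-force non-uniform Fourier sum (unitary convention).

    Independent oracle for the NUFFT: sum_r x(r) exp(-2pi i k.r/N) / sqrt(V)
    over centered integer voxel coordinates r.
    """
    x = np.asarray(x, complex)
    N = np.array(x.shape)
    grids = [np.arange(n) - n // 2 for n in x.shape]
    R = np.stack(np.meshgrid(*grids, indexing="ij"), -1).reshape(-1, 3)
    phase = np.exp(-2j * np.pi * (np.asarray(coords) @ (R / N).T))
    return (phase @ x.ravel()) / np.sqrt(np.prod(N))


def direct_dft_adjoint(s, coords, shape):
    """Brute-force adjoint of :func:`direct_dft`."""
    N = np.array(shape)
    grids = [np.arange(n) - n // 2 for n in shape]
    R = np.stack(np.meshgrid(*grids, indexing="ij"), -1).reshape(-1, 3)
    phase = np.exp(2j * np.pi * (R / N) @ np.asarray(coords).T)
    return (phase @ np.asarray(s, complex)) .reshape(shape) / np.sqrt(np.prod(N))


def rel_err(a, b):
    return np.linalg.norm(np.ravel(a) - np.ravel(b)) / max(
        np.linalg.norm(np.ravel(b)), 1e-300
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_problem():
    """A 16^3, 2-coil, 300-spoke problem with a normalized operator."""
    shape = (16, 16, 16)
    phantom = make_phantom(shape, seed=11)
    maps = make_coil_maps(shape, 2, seed=12)
    traj = make_trajectory(300, 16, grid_n=16)
    y = simulate_acquisition(phantom, maps, traj, noise_sigma=0.0)
    op = EncodingOperator.from_components(maps, traj, make_dcf(traj))
    op = normalize_operator(op, n_iter=40, tol=1e-6)
    from blockmri.forward_model import rescale_kspace

    return {
        "shape": shape,
        "phantom": phantom,
        "maps": maps,
        "traj": traj,
        "y": rescale_kspace(op, y),
        "op": op,
    }


@pytest.fixture(scope="session")
def tiny_operator():
    """An 8^3, 2-coil operator small enough for dense-matrix oracles."""
    shape = (8, 8, 8)
    rng = np.random.default_rng(7)
    maps = make_coil_maps(shape, 2, seed=21)
    traj = make_trajectory(75, 8, grid_n=8)  # 600 samples
    op = EncodingOperator.from_components(maps, traj, make_dcf(traj))
    x_true = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return {"shape": shape, "maps": maps, "traj": traj, "op": op,
            "x_true": x_true}
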