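import numpy as np
import pytest

from blockmri.synthetic import (
    bit_reversed_order,
    ellipsoid_mask,
    make_coil_maps,
    make_dcf,
    make_phantom,
    make_trajectory,
    pca_coil_compress,
    simulate_acquisition,
    subsample_spokes,
)
from blockmri.types import ImageVolume, KSpaceData

from conftest import direct_dft, rel_err


class TestMakePhantom:
    def test_empty_scene_is_zero(self):
        vol = make_phantom((16, 16, 16), n_ellipsoids=0, n_tubes=0, seed=0)
        assert np.all(vol.data == 0)

    def test_centered_ellipsoid_matches_bruteforce(self):
        # voxel-wise oracle: count interior voxels by a direct triple loop
        shape = (32, 32, 32)
        mask = ellipsoid_mask(shape, (0, 0, 0), (8, 8, 8))
        count = 0
        for i in range(32):
            for j in range(32):
                for k in range(32):
                    x, y, z = i - 16, j - 16, k - 16
                    if x**2 / 64 + y**2 / 64 + z**2 / 64 <= 1:
                        count += 1
        assert int(mask.sum()) == count

    def test_deterministic(self):
        a = make_phantom((16, 16, 16), seed=5)
        b = make_phantom((16, 16, 16), seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_magnitude_range_and_nonempty(self):
        vol = make_phantom((24, 24, 24), n_ellipsoids=3, n_tubes=2, seed=3)
        mag = np.abs(vol.data)
        assert mag.max() <= 1 + 1e-12
        assert mag.max() > 0

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            make_phantom((0, 16, 16))
        with pytest.raises(ValueError):
            make_phantom((4, 16, 16))


class TestMakeCoilMaps:
    def test_uniform_single_coil_is_ones(self):
        maps = make_coil_maps((8, 8, 8), 1, uniform=True)
        np.testing.assert_allclose(maps.maps, 1.0)

    def test_normalized_sum_of_squares(self, rng):
        maps = make_coil_maps((12, 12, 12), 6, seed=9, normalized=True)
        sos = np.sum(np.abs(maps.maps) ** 2, axis=0)
        np.testing.assert_allclose(sos, 1.0, atol=1e-6)

    def test_deterministic(self):
        a = make_coil_maps((8, 8, 8), 3, seed=2)
        b = make_coil_maps((8, 8, 8), 3, seed=2)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_rejects_zero_channels(self):
        with pytest.raises(ValueError):
            make_coil_maps((8, 8, 8), 0)


class TestMakeTrajectory:
    def test_paper_spoke_count(self):
        traj = make_trajectory(94957, 2, grid_n=8)
        assert traj.n_spokes == 94957

    def test_components_within_bounds(self):
        traj = make_trajectory(500, 16, grid_n=16)
        assert np.all(np.abs(traj.coords) <= 8 + 1e-12)

    def test_directions_near_uniform_on_sphere(self):
        # Monte-Carlo oracle: mean of uniform unit vectors ~ O(1/sqrt(n))
        traj = make_trajectory(4096, 4, grid_n=16)
        tips = traj.coords[:, -1, :]
        dirs = tips / np.linalg.norm(tips, axis=1, keepdims=True)
        assert np.linalg.norm(dirs.mean(axis=0)) < 0.05

    def test_center_out(self):
        traj = make_trajectory(10, 8, grid_n=16)
        np.testing.assert_allclose(traj.coords[:, 0, :], 0.0)

    def test_bit_reversed_is_permutation(self):
        for n in (1, 2, 7, 16, 33):
            order = bit_reversed_order(n)
            assert sorted(order) == list(range(n))

    def test_ordering_modes_differ(self):
        seq = make_trajectory(64, 4, grid_n=8, ordering_mode="sequential")
        rev = make_trajectory(64, 4, grid_n=8, ordering_mode="bit_reversed")
        assert not np.array_equal(seq.coords, rev.coords)
        # same set of spokes, different order
        assert np.allclose(
            np.sort(seq.coords[:, -1, 2]), np.sort(rev.coords[:, -1, 2])
        )

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            make_trajectory(0, 8, grid_n=8)
        with pytest.raises(ValueError):
            make_trajectory(8, 1, grid_n=8)


class TestMakeDcf:
    def test_nonnegative(self):
        dcf = make_dcf(make_trajectory(50, 8, grid_n=16))
        assert np.all(dcf.weights >= 0)

    def test_radius_squared_ratio(self):
        # closed form: weights scale as |k|^2 above the floor
        traj = make_trajectory(20, 9, grid_n=16)
        dcf = make_dcf(traj)
        w = dcf.weights.reshape(20, 9)
        # readout index 4 has radius exactly twice index 2
        np.testing.assert_allclose(w[:, 4] / w[:, 2], 4.0, atol=1e-9)

    def test_center_sample_floor(self):
        traj = make_trajectory(20, 9, grid_n=16)
        dcf = make_dcf(traj)
        w = dcf.weights.reshape(20, 9)
        assert np.all(w[:, 0] > 0)
        np.testing.assert_allclose(w[:, 0], w[:, 1])


class TestSimulateAcquisition:
    def test_zero_phantom_zero_kspace(self):
        shape = (8, 8, 8)
        vol = ImageVolume(np.zeros(shape))
        maps = make_coil_maps(shape, 2, seed=1)
        traj = make_trajectory(20, 8, grid_n=8)
        y = simulate_acquisition(vol, maps, traj, noise_sigma=0.0)
        np.testing.assert_array_equal(y.samples, 0)

    def test_impulse_constant_magnitude(self):
        # direct DFT oracle: impulse at the center voxel gives flat spectrum
        # of magnitude amplitude/sqrt(V) under the unitary convention
        shape = (8, 8, 8)
        data = np.zeros(shape, complex)
        data[4, 4, 4] = 1.0
        vol = ImageVolume(data)
        maps = make_coil_maps(shape, 1, uniform=True, normalized=False)
        traj = make_trajectory(25, 8, grid_n=8)
        y = simulate_acquisition(vol, maps, traj, noise_sigma=0.0)
        expected = 1.0 / np.sqrt(8**3)
        np.testing.assert_allclose(np.abs(y.samples), expected, rtol=1e-3)
        oracle = direct_dft(data, traj.points)
        assert rel_err(y.samples[0], oracle) < 1e-3

    def test_noiseless_deterministic_across_seeds(self):
        shape = (8, 8, 8)
        vol = make_phantom(shape, seed=0)
        maps = make_coil_maps(shape, 2, seed=1)
        traj = make_trajectory(20, 8, grid_n=8)
        a = simulate_acquisition(vol, maps, traj, noise_sigma=0.0, seed=1)
        b = simulate_acquisition(vol, maps, traj, noise_sigma=0.0, seed=2)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_noise_scale(self, rng):
        shape = (8, 8, 8)
        vol = ImageVolume(np.zeros(shape))
        maps = make_coil_maps(shape, 1, uniform=True)
        traj = make_trajectory(400, 8, grid_n=8)
        y = simulate_acquisition(vol, maps, traj, noise_sigma=0.5, seed=3)
        assert np.std(y.samples) == pytest.approx(0.5, rel=0.1)

    def test_shape_mismatch_rejected(self):
        vol = make_phantom((8, 8, 8), seed=0)
        maps = make_coil_maps((12, 12, 12), 2, seed=1)
        traj = make_trajectory(20, 8, grid_n=8)
        with pytest.raises(ValueError):
            simulate_acquisition(vol, maps, traj)

    def test_linearity(self, rng):
        shape = (8, 8, 8)
        maps = make_coil_maps(shape, 2, seed=4)
        traj = make_trajectory(30, 8, grid_n=8)
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        z = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        a, b = 1.7 - 0.3j, -0.6 + 2.1j

        def sim(v):
            return simulate_acquisition(ImageVolume(v), maps, traj).samples

        combo = sim(a * x + b * z)
        assert rel_err(combo, a * sim(x) + b * sim(z)) < 1e-6


class TestSubsampleSpokes:
    def _acq(self, n_spokes=50000, n_readout=2):
        traj = make_trajectory(n_spokes, n_readout, grid_n=8)
        samples = (np.arange(2 * traj.n_samples, dtype=float)
                   .reshape(2, -1) + 0j)
        return KSpaceData(samples=samples, traj=traj), traj

    def test_paper_subset_count(self):
        y, traj = self._acq()
        y_sub, traj_sub, dcf_sub = subsample_spokes(y, traj, 5000, seed=0)
        assert traj_sub.n_spokes == 5000
        assert y_sub.n_samples == 5000 * traj.n_readout
        assert dcf_sub.weights.shape[0] == y_sub.n_samples

    def test_identity_subset(self):
        y, traj = self._acq(100)
        y_sub, traj_sub, _ = subsample_spokes(y, traj, 100, seed=0)
        np.testing.assert_array_equal(y_sub.samples, y.samples)
        np.testing.assert_array_equal(traj_sub.coords, traj.coords)

    def test_deterministic(self):
        y, traj = self._acq(1000)
        a = subsample_spokes(y, traj, 100, seed=9)[0]
        b = subsample_spokes(y, traj, 100, seed=9)[0]
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_rejects_oversized(self):
        y, traj = self._acq(100)
        with pytest.raises(ValueError):
            subsample_spokes(y, traj, 101, seed=0)

    def test_commutes_with_simulation(self, rng):
        # subsample(simulate(x)) == simulate(x) on the subset trajectory
        shape = (8, 8, 8)
        maps = make_coil_maps(shape, 2, seed=5)
        traj = make_trajectory(60, 8, grid_n=8)
        vol = make_phantom(shape, seed=6)
        y = simulate_acquisition(vol, maps, traj)
        y_sub, traj_sub, _ = subsample_spokes(y, traj, 25, seed=1)
        y_direct = simulate_acquisition(vol, maps, traj_sub)
        np.testing.assert_allclose(y_sub.samples, y_direct.samples,
                                   rtol=0, atol=1e-12)


class TestPcaCoilCompress:
    def _kspace(self, rng, n_channels=32, n_samples=500):
        traj = make_trajectory(n_samples // 2, 2, grid_n=8)
        samples = rng.standard_normal((n_channels, traj.n_samples)) + \
            1j * rng.standard_normal((n_channels, traj.n_samples))
        return KSpaceData(samples=samples, traj=traj)

    def test_paper_channel_count(self, rng):
        y = self._kspace(rng, n_channels=32)
        assert pca_coil_compress(y, 20).n_channels == 20

    def test_full_rank_preserves_energy(self, rng):
        y = self._kspace(rng, n_channels=8)
        out = pca_coil_compress(y, 8)
        e_in = np.sum(np.abs(y.samples) ** 2)
        e_out = np.sum(np.abs(out.samples) ** 2)
        assert abs(e_out - e_in) / e_in < 1e-6

    def test_energy_nonincreasing(self, rng):
        y = self._kspace(rng, n_channels=12)
        out = pca_coil_compress(y, 4)
        assert np.sum(np.abs(out.samples) ** 2) <= \
            np.sum(np.abs(y.samples) ** 2) * (1 + 1e-12)

    def test_rank_one_retains_energy(self, rng):
        # SVD oracle: channels are scalar multiples of one signal
        traj = make_trajectory(100, 2, grid_n=8)
        base = rng.standard_normal(traj.n_samples) + \
            1j * rng.standard_normal(traj.n_samples)
        gains = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        y = KSpaceData(samples=np.outer(gains, base), traj=traj)
        sv = np.linalg.svd(y.samples, compute_uv=False)
        assert sv[1] / sv[0] < 1e-12  # rank-1 by construction
        out = pca_coil_compress(y, 1)
        e_ratio = np.sum(np.abs(out.samples) ** 2) / np.sum(np.abs(y.samples) ** 2)
        assert e_ratio >= 0.9999

    def test_rejects_bad_counts(self, rng):
        y = self._kspace(rng, n_channels=4)
        with pytest.raises(ValueError):
            pca_coil_compress(y, 0)
        with pytest.raises(ValueError):
            pca_coil_compress(y, 5)
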