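import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blockmri._nn import Conv3d, LeakyReLU, Sequential
from blockmri.blockwise import (
    BlockScheme,
    BlockwiseModule,
    MemoryLedger,
    blockwise_apply,
    extract_patches,
    memory_footprint,
    plan_blocks,
    recompose,
)

from conftest import rel_err


class TestPlanBlocks:
    def test_eight_blocks(self):
        assert plan_blocks((32, 32, 32), (2, 2, 2)).n_blocks == 8
        assert plan_blocks((17, 9, 30), (2, 2, 2)).n_blocks == 8

    def test_twelve_internal_faces(self):
        assert plan_blocks((32, 32, 32), (2, 2, 2)).n_internal_faces == 12

    def test_degenerate_split(self):
        scheme = plan_blocks((16, 16, 16), (1, 1, 1), halo=3)
        assert scheme.n_blocks == 1
        assert scheme.n_internal_faces == 0
        assert scheme.extended_range((0, 0, 0)) == [(0, 16)] * 3

    def test_face_count_formula(self):
        scheme = plan_blocks((30, 30, 30), (3, 2, 1))
        # sum over axes of (p_a - 1) * prod(others)
        assert scheme.n_internal_faces == 2 * 2 * 1 + 3 * 1 * 1 + 0

    def test_core_sizes_balanced(self):
        scheme = plan_blocks((17, 9, 8), (3, 2, 2))
        for bounds in scheme.axis_bounds:
            sizes = [b1 - b0 for b0, b1 in bounds]
            assert max(sizes) - min(sizes) <= 1

    def test_rejects_oversplit(self):
        with pytest.raises(ValueError):
            plan_blocks((4, 8, 8), (5, 1, 1))

    def test_json_round_trip(self):
        scheme = plan_blocks((16, 12, 10), (2, 3, 1), halo=(1, 2, 0))
        restored = BlockScheme.from_json(scheme.to_json())
        assert restored.volume_shape == scheme.volume_shape
        assert restored.splits == scheme.splits
        assert restored.halo == scheme.halo


class TestExtractRecompose:
    def test_halo_zero_partition(self, rng):
        x = rng.standard_normal((16, 16, 16))
        scheme = plan_blocks((16, 16, 16), (2, 2, 2), halo=0)
        patches = extract_patches(x, scheme)
        assert all(p.shape == (8, 8, 8) for p in patches)
        np.testing.assert_array_equal(recompose(patches, scheme), x)

    def test_corner_patch_against_bruteforce_index_map(self, rng):
        x = rng.standard_normal((16, 16, 16))
        scheme = plan_blocks((16, 16, 16), (2, 2, 2), halo=2)
        patches = extract_patches(x, scheme)
        # first (corner) block: core 0..8, halo clips at the volume edge
        assert patches[0].shape == (10, 10, 10)
        np.testing.assert_array_equal(patches[0], x[:10, :10, :10])
        # last (opposite corner) block
        np.testing.assert_array_equal(patches[-1], x[6:, 6:, 6:])

    def test_zero_volume_zero_patches(self):
        scheme = plan_blocks((8, 8, 8), (2, 2, 2), halo=1)
        for p in extract_patches(np.zeros((8, 8, 8)), scheme):
            np.testing.assert_array_equal(p, 0)

    def test_block_index_label_map(self):
        scheme = plan_blocks((12, 12, 12), (2, 2, 2), halo=3)
        patches = [np.full(scheme.extended_shape(idx), float(b))
                   for b, idx in enumerate(scheme.block_indices())]
        out = recompose(patches, scheme)
        expected = np.zeros((12, 12, 12))
        for b, idx in enumerate(scheme.block_indices()):
            expected[scheme.core_slices(idx)] = b
        np.testing.assert_array_equal(out, expected)

    def test_single_block_identity(self, rng):
        x = rng.standard_normal((10, 10, 10)) + 1j * rng.standard_normal((10, 10, 10))
        scheme = plan_blocks((10, 10, 10), (1, 1, 1), halo=4)
        np.testing.assert_array_equal(
            recompose(extract_patches(x, scheme), scheme), x)

    def test_mismatched_patches_rejected(self, rng):
        scheme = plan_blocks((8, 8, 8), (2, 2, 2))
        with pytest.raises(ValueError):
            recompose([np.zeros((4, 4, 4))] * 7, scheme)
        with pytest.raises(ValueError):
            extract_patches(np.zeros((9, 8, 8)), scheme)

    @settings(max_examples=30, deadline=None)
    @given(
        shape=st.tuples(*[st.integers(8, 24)] * 3),
        splits=st.tuples(*[st.integers(1, 3)] * 3),
        halo=st.integers(0, 4),
        data=st.randoms(use_true_random=False),
    )
    def test_round_trip_property(self, shape, splits, halo, data):
        rng = np.random.default_rng(data.randint(0, 2**31))
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        scheme = plan_blocks(shape, splits, halo=halo)
        np.testing.assert_array_equal(
            recompose(extract_patches(x, scheme), scheme), x)


def random_conv_net(rng, radius, channels=2):
    """Composition of zero-padded convs + LeakyReLU, total radius `radius`,
    acting on 1-channel real patches via a small adapter."""
    layers = []
    in_ch = 1
    for i in range(radius):
        out_ch = 1 if i == radius - 1 else channels
        layers.append(Conv3d(in_ch, out_ch, (3, 3, 3),
                             rng=np.random.default_rng(rng.integers(2**31))))
        if i < radius - 1:
            layers.append(LeakyReLU(0.1))
        in_ch = out_ch
    return Sequential(*layers)


class NetAdapter:
    """Presents a (C=1) conv net as a plain 3D patch operator."""

    def __init__(self, net):
        self.net = net
        self.receptive_radius = net.receptive_radius

    def __call__(self, patch):
        out, _ = self.net.forward(patch[None].real, want_cache=False)
        return out[0]


class TestBlockwiseApply:
    def test_identity_operator(self, rng):
        x = rng.standard_normal((12, 12, 12))
        scheme = plan_blocks((12, 12, 12), (2, 2, 2), halo=2)
        np.testing.assert_array_equal(
            blockwise_apply(x, lambda p: p, scheme), x)

    def test_single_conv_matches_full_volume(self, rng):
        x = rng.standard_normal((16, 16, 16))
        f = NetAdapter(random_conv_net(rng, radius=1))
        scheme = plan_blocks((16, 16, 16), (2, 2, 2), halo=1)
        full = f(x)
        assert rel_err(blockwise_apply(x, f, scheme), full) < 1e-6

    def test_halo_zero_errors_confined_to_faces(self, rng):
        # negative control: with halo 0 the mismatch sits within distance 1
        # of an internal block face
        x = rng.standard_normal((16, 16, 16))
        f = NetAdapter(random_conv_net(rng, radius=1))
        scheme = plan_blocks((16, 16, 16), (2, 2, 2), halo=0)
        out = blockwise_apply(x, f, scheme, allow_halo_violation=True)
        diff = np.abs(out - f(x)) > 1e-12
        face_zone = np.zeros((16, 16, 16), bool)
        for axis in range(3):
            sl = [slice(None)] * 3
            sl[axis] = slice(7, 9)  # within distance 1 of the cut at 8
            face_zone[tuple(sl)] = True
        assert diff.any()  # the control must actually exercise the mismatch
        assert not (diff & ~face_zone).any()

    def test_halo_violation_requires_override(self, rng):
        f = NetAdapter(random_conv_net(rng, radius=2))
        scheme = plan_blocks((16, 16, 16), (2, 2, 2), halo=1)
        with pytest.raises(ValueError):
            blockwise_apply(np.zeros((16, 16, 16)), f, scheme)

    @pytest.mark.parametrize("trial", range(5))
    def test_equivalence_random_configs(self, trial):
        rng = np.random.default_rng(100 + trial)
        shape = tuple(int(v) for v in rng.integers(10, 22, size=3))
        splits = tuple(int(v) for v in rng.integers(1, 3, size=3))
        radius = int(rng.integers(1, 4))
        f = NetAdapter(random_conv_net(rng, radius))
        scheme = plan_blocks(shape, splits, halo=radius)
        x = rng.standard_normal(shape)
        assert rel_err(blockwise_apply(x, f, scheme), f(x)) < 1e-5


class Tiny2LayerNet:
    """2-layer real conv net with the module forward/backward protocol."""

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.net = Sequential(
            Conv3d(1, 3, (3, 3, 3), rng=rng),
            LeakyReLU(0.05),
            Conv3d(3, 1, (3, 3, 3), rng=rng),
        )
        self.receptive_radius = self.net.receptive_radius

    def params(self):
        return self.net.params()

    def forward(self, patch, want_cache=True):
        out, cache = self.net.forward(patch[None].real, want_cache=want_cache)
        return out[0] + 0j, cache

    def backward(self, grad_out, cache):
        g = self.net.backward(grad_out.real[None], cache)
        return g[0] + 0j

    def cache_elements(self, in_shape):
        return self.net.cache_elements((1,) + tuple(in_shape))


class TestBlockwiseGradients:
    def _grads(self, checkpointed):
        rng = np.random.default_rng(5)
        net = Tiny2LayerNet(seed=3)
        scheme = plan_blocks((12, 12, 12), (2, 2, 2), halo=2)
        mod = BlockwiseModule(net, scheme, checkpointed=checkpointed)
        x = rng.standard_normal((12, 12, 12)) + 0j
        g = rng.standard_normal((12, 12, 12)) + 0j
        out, ctx = mod.forward(x, train=True)
        for p in net.params():
            p.zero_grad()
        gx = mod.backward(g, ctx)
        return out, gx, [p.grad.copy() for p in net.params()]

    def test_checkpointed_matches_stored(self):
        out1, gx1, grads1 = self._grads(True)
        out2, gx2, grads2 = self._grads(False)
        np.testing.assert_array_equal(out1, out2)
        assert rel_err(gx1, gx2) < 1e-6
        for a, b in zip(grads1, grads2):
            assert rel_err(a, b) < 1e-6

    def test_input_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(6)
        net = Tiny2LayerNet(seed=4)
        scheme = plan_blocks((10, 10, 10), (2, 1, 2), halo=2)
        mod = BlockwiseModule(net, scheme, checkpointed=True)
        x = rng.standard_normal((10, 10, 10)) + 0j
        g = rng.standard_normal((10, 10, 10)) + 0j
        _, ctx = mod.forward(x, train=True)
        gx = mod.backward(g, ctx)
        eps = 1e-6
        for _ in range(3):
            idx = tuple(rng.integers(10, size=3))
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fp = np.real(np.vdot(g, mod.forward(xp)[0]))
            fm = np.real(np.vdot(g, mod.forward(xm)[0]))
            num = (fp - fm) / (2 * eps)
            assert num == pytest.approx(np.real(gx[idx]), rel=1e-5, abs=1e-9)

    def test_peak_working_set_bound(self):
        net = Tiny2LayerNet(seed=1)
        shape = (16, 16, 16)
        scheme = plan_blocks(shape, (2, 2, 2), halo=2)
        ledger = MemoryLedger()
        mod = BlockwiseModule(net, scheme, checkpointed=True, ledger=ledger)
        x = np.random.default_rng(0).standard_normal(shape) + 0j
        mod.forward(x, train=True)
        vol = int(np.prod(shape))
        max_cache = max(net.cache_elements(scheme.extended_shape(idx))
                        for idx in scheme.block_indices())
        assert ledger.peak <= 2 * vol + max_cache


class TestMemoryFootprint:
    def test_forward_storage_formula(self):
        # (N+1) * Mem_x; the printed case N=5 gives 6 volumes
        scheme = plan_blocks((300, 300, 300), (2, 2, 2), halo=0)
        rep = memory_footprint((300, 300, 300), scheme, n_unrolls=5,
                               activations_per_voxel=32)
        assert rep["forward_volume_elements"] == 6 * 300**3

    def test_reduction_factor_eight(self):
        scheme = plan_blocks((300, 300, 300), (2, 2, 2), halo=0)
        rep = memory_footprint((300, 300, 300), scheme, n_unrolls=5,
                               activations_per_voxel=32)
        assert rep["reduction_factor"] == pytest.approx(8.0)

    def test_zero_unrolls_single_volume(self):
        scheme = plan_blocks((32, 32, 32), (2, 2, 2), halo=0)
        rep = memory_footprint((32, 32, 32), scheme, n_unrolls=0,
                               activations_per_voxel=1)
        assert rep["forward_volume_elements"] == 32**3

    def test_backward_total(self):
        shape = (16, 16, 16)
        scheme = plan_blocks(shape, (2, 2, 2), halo=0)
        rep = memory_footprint(shape, scheme, n_unrolls=2,
                               activations_per_voxel=3)
        assert rep["backward_total_elements"] == 3 * 16**3 + 3 * 16**3
        assert rep["peak_intermediate_elements"] == 3 * 8**3

    def test_halo_shrinks_reduction_factor(self):
        shape = (32, 32, 32)
        rep0 = memory_footprint(shape, plan_blocks(shape, (2, 2, 2), halo=0),
                                1, 1)
        rep4 = memory_footprint(shape, plan_blocks(shape, (2, 2, 2), halo=4),
                                1, 1)
        assert rep4["reduction_factor"] < rep0["reduction_factor"]
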