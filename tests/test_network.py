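"""KR-block, SRDN and conjoint-restorer contracts: identity maps with zero
weights, shape preservation, parameter counts, gradient-descent behavior."""

import numpy as np
import pytest

import stirnet as sn
from stirnet.errors import ConfigurationError, InvalidInputError
from stirnet.network import KRBlock, _Adam
from stirnet.patches import PatchPair


def tiny_spec() -> sn.SRDNSpec:
    return sn.SRDNSpec(n_features=8, kr_blocks=1, kr=sn.KRBlockSpec(width=8, reduce=4))


class TestKRBlock:
    def test_zero_weights_is_identity(self, rng):
        block = KRBlock(sn.KRBlockSpec(width=8, reduce=4), init="zeros")
        x = rng.random((12, 12, 8)).astype(np.float32)
        np.testing.assert_array_equal(sn.kr_block_forward(x, block), x)

    def test_shape_preserved(self, rng):
        block = KRBlock(sn.KRBlockSpec(width=16, reduce=8),
                        rng=np.random.default_rng(0))
        x = rng.random((41, 41, 16)).astype(np.float32)
        assert sn.kr_block_forward(x, block).shape == (41, 41, 16)

    def test_conv_parameter_count_closed_form(self):
        # sum of f^2*c_in*n + n over the four convolutions:
        # 1x1: 8*4+4=36, 7x7: 49*4*8+8=1576, 3x3: 9*8*8+8=584, 1x1: 8*8+8=72
        assert sn.KRBlockSpec(width=8, reduce=4).conv_param_count == 2268
        block = KRBlock(sn.KRBlockSpec(width=8, reduce=4))
        assert block.conv_param_count == 2268

    def test_channel_mismatch_rejected(self, rng):
        block = KRBlock(sn.KRBlockSpec(width=8, reduce=4))
        with pytest.raises(InvalidInputError):
            sn.kr_block_forward(rng.random((10, 10, 4)).astype(np.float32), block)


class TestSRDNForward:
    def test_zero_weights_with_shortcut_is_identity(self, rng):
        model = sn.SRDN(tiny_spec(), init="zeros")
        img = rng.random((20, 20)).astype(np.float32)
        np.testing.assert_array_equal(sn.srdn_forward(img, model), img)

    @pytest.mark.parametrize("shape", [(41, 41), (50, 23), (7, 64)])
    def test_fully_convolutional_shapes(self, rng, shape):
        model = sn.SRDN(tiny_spec(), seed=1)
        img = rng.random(shape).astype(np.float32)
        assert sn.srdn_forward(img, model).shape == shape

    def test_layer_plan_channel_flow(self):
        plan = sn.SRDNSpec().layer_plan()
        assert (plan[0].f, plan[0].n, plan[0].c) == (7, 128, 1)
        assert (plan[1].f, plan[1].n) == (7, 128)
        assert (plan[-2].f, plan[-2].n) == (3, 128)
        assert (plan[-1].f, plan[-1].n) == (3, 1)
        # output channels of each layer feed the next layer's input channels
        for prev, nxt in zip(plan, plan[1:]):
            assert nxt.c == prev.n


class TestConjointMerge:
    def test_identical_volumes_unchanged(self, inwindow_volume):
        out = sn.conjoint_merge(inwindow_volume, inwindow_volume, inwindow_volume)
        np.testing.assert_array_equal(out.data, inwindow_volume.data)

    def test_constant_volumes(self):
        def const(v):
            return sn.CTPVolume(np.full((4, 4, 2), v, dtype=np.float32), dt=1.0)
        out = sn.conjoint_merge(const(1.0), const(2.0), const(3.0))
        np.testing.assert_array_equal(out.data, 2.0)

    def test_matches_elementwise_oracle(self, rng):
        vols = [sn.CTPVolume(rng.random((8, 8, 4)).astype(np.float32), dt=1.0)
                for _ in range(3)]
        out = sn.conjoint_merge(*vols)
        expected = np.empty((8, 8, 4), dtype=np.float32)
        for i in range(8):
            for j in range(8):
                for t in range(4):
                    expected[i, j, t] = np.float32(
                        (float(vols[0].data[i, j, t]) + float(vols[1].data[i, j, t])
                         + float(vols[2].data[i, j, t])) / 3.0)
        np.testing.assert_array_equal(out.data, expected)

    def test_shape_mismatch_rejected(self):
        a = sn.CTPVolume(np.zeros((4, 4, 2), dtype=np.float32), dt=1.0)
        b = sn.CTPVolume(np.zeros((4, 4, 3), dtype=np.float32), dt=1.0)
        with pytest.raises(InvalidInputError):
            sn.conjoint_merge(a, a, b)


class TestTraining:
    def make_pair(self, rng, size=16, noise=0.1):
        label = rng.random((size, size)).astype(np.float32)
        inp = np.clip(label + noise * rng.standard_normal((size, size)), 0, 1)
        return PatchPair(inp.astype(np.float32), label, 0, 0, 0)

    def test_zero_iterations_returns_initial_weights(self, rng):
        pair = self.make_pair(rng)
        model, trace = sn.train_srdn([pair], tiny_spec(),
                                     sn.TrainConfig(iterations=0, seed=3))
        reference = sn.SRDN(tiny_spec(), seed=3)
        assert trace.size == 0
        for (w, _), (v, _) in zip(model.parameters(), reference.parameters()):
            np.testing.assert_array_equal(w, v)

    def test_empty_training_set_rejected(self):
        with pytest.raises(InvalidInputError):
            sn.train_srdn([], tiny_spec(), sn.TrainConfig(iterations=1))

    def test_deterministic_loss_traces(self, rng):
        pairs = [self.make_pair(rng) for _ in range(4)]
        cfg = sn.TrainConfig(learning_rate=1e-3, batch_size=2, iterations=25, seed=7)
        _, t1 = sn.train_srdn(pairs, tiny_spec(), cfg)
        _, t2 = sn.train_srdn(pairs, tiny_spec(), cfg)
        np.testing.assert_array_equal(t1, t2)

    def test_single_patch_overfit(self, rng):
        # a single repeated sample must be driven to near-zero loss
        pair = self.make_pair(rng)
        cfg = sn.TrainConfig(learning_rate=3e-3, batch_size=1,
                             iterations=800, seed=0)
        _, trace = sn.train_srdn([pair], tiny_spec(), cfg)
        assert trace[-1] < 1e-4 * trace[0]
        running_min = np.minimum.accumulate(trace)
        assert np.all(np.diff(running_min) <= 0.0)

    def test_descent_on_phantom_patches(self, quick_phantom):
        _, vol, _ = quick_phantom
        degraded = sn.add_correlated_noise(vol, sn.DoseParams(I=40.0, seed=2))
        pairs = sn.extract_patch_pairs(
            sn.extract_cross_sections(vol, "xy"),
            sn.extract_cross_sections(degraded, "xy"), "xy", 16, 8)
        cfg = sn.TrainConfig(learning_rate=1e-3, batch_size=8, iterations=60, seed=1)
        _, trace = sn.train_srdn(pairs, tiny_spec(), cfg)
        assert trace[-10:].mean() < trace[:10].mean()


class TestRestoreVolume:
    def test_identity_weights_restore_inwindow_volume(self, inwindow_volume):
        model = sn.STIRModel.from_spec(
            sn.STIRSpec(xy=tiny_spec(), xt=tiny_spec(), yt=tiny_spec()), init="zeros")
        conjoint, branches = sn.restore_volume(inwindow_volume, model)
        np.testing.assert_allclose(conjoint.data, inwindow_volume.data, atol=1e-4)
        for vol in branches.values():
            np.testing.assert_allclose(vol.data, inwindow_volume.data, atol=1e-4)

    def test_conjoint_equals_mean_of_branches(self, inwindow_volume):
        model = sn.STIRModel.from_spec(
            sn.STIRSpec(xy=tiny_spec(), xt=tiny_spec(), yt=tiny_spec()), seed=4)
        conjoint, branches = sn.restore_volume(inwindow_volume, model)
        mean = (branches["xy"].data.astype(np.float64) + branches["xt"].data
                + branches["yt"].data) / 3.0
        np.testing.assert_array_equal(conjoint.data, mean.astype(np.float32))

    def test_missing_branch_rejected(self, inwindow_volume):
        model = sn.STIRModel({"xy": sn.SRDN(tiny_spec())})
        with pytest.raises(ConfigurationError):
            sn.restore_volume(inwindow_volume, model)

    def test_save_load_roundtrip(self, tmp_path, inwindow_volume):
        model = sn.STIRModel.from_spec(
            sn.STIRSpec(xy=tiny_spec(), xt=tiny_spec(), yt=tiny_spec()), seed=9)
        before, _ = sn.restore_volume(inwindow_volume, model)
        sn.save_model(model, tmp_path / "model")
        loaded = sn.load_model(tmp_path / "model")
        after, _ = sn.restore_volume(inwindow_volume, loaded)
        np.testing.assert_array_equal(before.data, after.data)


class TestAdam:
    def test_converges_on_quadratic(self):
        # minimize (w - 3)^2 — sanity of the optimizer update rule
        w = np.zeros(1, dtype=np.float32)
        g = np.zeros(1, dtype=np.float32)
        opt = _Adam([(w, g)], lr=0.1)
        for _ in range(500):
            g[...] = 2.0 * (w - 3.0)
            opt.step()
        assert w[0] == pytest.approx(3.0, abs=1e-2)
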