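"""Dose-reduction simulation: the tube-current noise model, grid-wise
down-sampling, and bicubic re-interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stirnet as sn
from stirnet.errors import InvalidInputError


def flat_volume(value: float, nx: int = 64, ny: int = 64, nt: int = 3,
                dt: float = 1.0) -> sn.CTPVolume:
    return sn.CTPVolume(np.full((nx, ny, nt), value, dtype=np.float32), dt=dt)


class TestNoiseSigma:
    def test_zero_at_reference_current(self):
        assert sn.noise_sigma(sn.DoseParams(I=190.0, I0=190.0)) == 0.0

    @pytest.mark.parametrize("current, expected", [
        (20.0, 21.804654120526415),   # K*sqrt(1/20 - 1/190)
        (80.0, 8.769828251784038), ])  # K*sqrt(1/80 - 1/190)
    def test_matches_closed_form(self, current, expected):
        got = sn.noise_sigma(sn.DoseParams(I=current))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_matches_arbitrary_precision_oracle(self):
        sympy = pytest.importorskip("sympy")
        for current in (20, 40, 60, 80, 190):
            exact = sympy.Float("103.09", 30) * sympy.sqrt(
                sympy.Rational(1, current) - sympy.Rational(1, 190))
            got = sn.noise_sigma(sn.DoseParams(I=float(current)))
            assert got == pytest.approx(float(exact), rel=1e-12)

    @given(st.floats(min_value=1.0, max_value=189.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_current(self, current):
        lower = sn.noise_sigma(sn.DoseParams(I=current))
        higher = sn.noise_sigma(sn.DoseParams(I=current + 1.0))
        assert lower > higher >= 0.0

    def test_invalid_currents_rejected(self):
        with pytest.raises(InvalidInputError):
            sn.DoseParams(I=0.0)
        with pytest.raises(InvalidInputError):
            sn.DoseParams(I=200.0, I0=190.0)


class TestCorrelatedNoise:
    def test_identity_at_reference_current(self):
        vol = flat_volume(50.0)
        out = sn.add_correlated_noise(vol, sn.DoseParams(I=190.0, seed=1))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_empirical_std_matches_target(self):
        vol = flat_volume(50.0, nx=256, ny=256, nt=1)
        params = sn.DoseParams(I=20.0, seed=2)
        out = sn.add_correlated_noise(vol, params)
        noise = (out.data - vol.data)[:, :, 0]
        assert noise.std() == pytest.approx(sn.noise_sigma(params), rel=0.02)

    def test_noise_mean_near_zero(self):
        vol = flat_volume(0.0, nx=256, ny=256, nt=1)
        params = sn.DoseParams(I=20.0, seed=3)
        noise = sn.add_correlated_noise(vol, params).data[:, :, 0]
        sigma = sn.noise_sigma(params)
        assert abs(noise.mean()) < 3.0 * sigma / np.sqrt(256 * 256)

    def test_deterministic_given_seed(self):
        vol = flat_volume(10.0, nx=32, ny=32, nt=4)
        a = sn.add_correlated_noise(vol, sn.DoseParams(I=40.0, seed=9))
        b = sn.add_correlated_noise(vol, sn.DoseParams(I=40.0, seed=9))
        np.testing.assert_array_equal(a.data, b.data)

    def test_frames_get_independent_noise(self):
        vol = flat_volume(0.0, nx=64, ny=64, nt=2)
        out = sn.add_correlated_noise(vol, sn.DoseParams(I=20.0, seed=4))
        r = np.corrcoef(out.data[:, :, 0].ravel(), out.data[:, :, 1].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_spatial_autocorrelation(self):
        vol = flat_volume(0.0, nx=256, ny=256, nt=1)
        corr = sn.add_correlated_noise(vol, sn.DoseParams(I=20.0, corr_sigma=1.5,
                                                          seed=5)).data[:, :, 0]
        white = sn.add_correlated_noise(vol, sn.DoseParams(I=20.0, corr_sigma=0.0,
                                                           seed=5)).data[:, :, 0]

        def lag1(f):
            return np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1]

        assert lag1(corr) > 0.3
        assert abs(lag1(white)) < 0.05


class TestDownsampling:
    @pytest.mark.parametrize("scale, expected_nt", [(1, 119), (2, 60), (3, 40)])
    def test_temporal_frame_counts(self, scale, expected_nt):
        vol = flat_volume(1.0, nx=4, ny=4, nt=119)
        out = sn.downsample_temporal(vol, scale)
        assert out.nt == expected_nt
        assert out.dt == pytest.approx(vol.dt * scale)

    def test_temporal_keeps_stride_frames(self):
        data = np.arange(12, dtype=np.float32).reshape(1, 1, 12)
        vol = sn.CTPVolume(data, dt=1.0)
        out = sn.downsample_temporal(vol, 3)
        np.testing.assert_array_equal(out.data[0, 0], [0, 3, 6, 9])

    @pytest.mark.parametrize("scale, expected", [(1, 512), (2, 256), (3, 171)])
    def test_spatial_sizes(self, scale, expected):
        vol = flat_volume(2.0, nx=512, ny=512, nt=1)
        out = sn.downsample_spatial(vol, scale)
        assert out.nx == out.ny == expected

    def test_spatial_constant_preserved(self):
        out = sn.downsample_spatial(flat_volume(7.5, nx=32, ny=32), 2)
        assert np.all(out.data == np.float32(7.5))

    def test_empty_temporal_result_rejected(self):
        vol = flat_volume(0.0, nx=2, ny=2, nt=2)
        with pytest.raises(InvalidInputError):
            sn.downsample_temporal(vol, 3)


class TestUpsampleBicubic:
    def test_constant_maps_to_constant(self):
        vol = flat_volume(7.0, nx=256, ny=256, nt=1)
        out = sn.upsample_bicubic(vol, (512, 512, 1))
        np.testing.assert_allclose(out.data, 7.0, atol=1e-6)

    def test_roundtrip_restores_shape(self):
        vol = flat_volume(1.0, nx=50, ny=60, nt=13)
        down = sn.downsample_spatial(sn.downsample_temporal(vol, 2), 2)
        up = sn.upsample_bicubic(down, vol.shape)
        assert up.shape == vol.shape

    def test_linear_ramp_recovered(self):
        ramp = np.tile(np.arange(128, dtype=np.float32)[:, None, None], (1, 128, 1))
        vol = sn.CTPVolume(ramp, dt=1.0)
        up = sn.upsample_bicubic(sn.downsample_spatial(vol, 2), vol.shape)
        interior = (slice(8, 120), slice(8, 120), 0)
        err = np.abs(up.data[interior] - ramp[interior]) / 127.0
        assert err.max() < 0.01

    def test_target_smaller_than_input_rejected(self):
        vol = flat_volume(1.0, nx=16, ny=16, nt=4)
        with pytest.raises(InvalidInputError):
            sn.upsample_bicubic(vol, (8, 16, 4))


class TestSimulateLowDose:
    def test_identity_at_full_dose_scale1(self, quick_phantom):
        _, vol, _ = quick_phantom
        out = sn.simulate_low_dose(vol, sn.DoseParams(I=190.0),
                                   sn.SamplingSpec(scale=1))
        np.testing.assert_array_equal(out.data, vol.data)

    @pytest.mark.parametrize("scale", [1, 2, 3])
    @pytest.mark.parametrize("axes", ["t", "xy", "xyt"])
    def test_shape_and_metadata_preserved(self, quick_phantom, scale, axes):
        _, vol, _ = quick_phantom
        out = sn.simulate_low_dose(
            vol, sn.DoseParams(I=40.0, seed=1),
            sn.SamplingSpec(scale=scale, axis_set=frozenset(axes)))
        assert out.shape == vol.shape
        assert out.dt == pytest.approx(vol.dt)
        assert out.pixel_size == vol.pixel_size

    def test_temporal_s2_interpolates_odd_frames(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 100, (6, 6, 10)).astype(np.float32)
        vol = sn.CTPVolume(data, dt=1.0)
        out = sn.simulate_low_dose(vol, sn.DoseParams(I=190.0),
                                   sn.SamplingSpec(scale=2, axis_set=frozenset("t")))
        # even frames are the kept samples (spline interpolates them exactly)
        np.testing.assert_allclose(out.data[:, :, 0], vol.data[:, :, 0], atol=1e-3)
        assert not np.allclose(out.data[:, :, 1], vol.data[:, :, 1], atol=1e-3)

    def test_lower_current_lowers_psnr(self, quick_phantom):
        _, vol, _ = quick_phantom
        sampling = sn.SamplingSpec(scale=2, axis_set=frozenset("xy"))
        psnrs = {}
        for current in (20.0, 80.0):
            out = sn.simulate_low_dose(vol, sn.DoseParams(I=current, seed=7), sampling)
            a = np.clip(vol.data, 0, 255)
            b = np.clip(out.data, 0, 255)
            psnrs[current] = sn.psnr(a[:, :, 0], b[:, :, 0])
        assert psnrs[20.0] < psnrs[80.0]
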