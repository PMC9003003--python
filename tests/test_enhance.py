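import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stocta.enhance import (
    G3Kernel,
    PipelineConfig,
    STEP_NAMES,
    build_g3_bank,
    enhance_slice,
    enhance_stack,
    estimate_background_rms,
    fft_bandpass,
    median_suppress,
    ridge_enhance,
    rollingball_subtract,
    smooth,
    subtract_offset,
)
from stocta.volume import EnFaceStack


class TestPipelineConfig:
    def test_defaults_match_reference_system(self):
        cfg = PipelineConfig()
        assert cfg.rms_offset == 20.0
        assert (cfg.bandpass_large, cfg.bandpass_small) == (40.0, 3.0)
        assert cfg.gaussian_sigma == 2.0
        assert cfg.n_orientations == 9
        assert cfg.median_3d_window == (5, 5, 3)

    def test_rejects_inverted_bandpass(self):
        with pytest.raises(ValueError, match="bandpass_large"):
            PipelineConfig(bandpass_large=3, bandpass_small=40)

    def test_round_trips_through_dict(self):
        cfg = PipelineConfig(gaussian_sigma=3.0, n_orientations=5)
        assert PipelineConfig.from_dict(cfg.to_dict()) == cfg

    def test_rejects_unknown_fields(self):
        with pytest.raises(ValueError, match="unknown config"):
            PipelineConfig.from_dict({"sigma": 2})


class TestBackgroundRms:
    def test_constant_region(self):
        img = np.full((10, 10), 20.0)
        assert estimate_background_rms(img, np.ones((10, 10), bool)) == pytest.approx(20.0)

    def test_closed_form(self):
        img = np.array([[3.0, 4.0]])
        # sqrt((9 + 16) / 2) = sqrt(12.5)
        assert estimate_background_rms(img, np.ones((1, 2), bool)) == pytest.approx(
            math.sqrt(12.5)
        )

    def test_all_zero(self):
        assert estimate_background_rms(np.zeros((5, 5))) == 0.0

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background_rms(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestSubtractOffset:
    def test_reference_background_value(self):
        out = subtract_offset(np.full((4, 4), 20.0), 20.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_zero_offset_identity(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        np.testing.assert_array_equal(subtract_offset(img, 0.0), img)

    def test_clamps_at_zero(self):
        assert subtract_offset(np.array([[5.0]]), 8.0)[0, 0] == 0.0


class TestFftBandpass:
    def test_horizontal_stripe_suppressed(self):
        # banding: constant along x, sinusoidal along z with period 16
        n = 128
        stripe = 50.0 + 10.0 * np.sin(2 * np.pi * np.arange(n) / 16)[None, :] * np.ones((n, 1))
        out = fft_bandpass(stripe, 40, 3, "horizontal")
        f_in = np.abs(np.fft.fft2(stripe))[0, n // 16]
        f_out = np.abs(np.fft.fft2(out))[0, n // 16]
        assert f_out < 0.05 * f_in

    def test_constant_image_preserved(self):
        img = np.full((32, 32), 7.0)
        np.testing.assert_allclose(fft_bandpass(img), img, atol=1e-10)

    def test_mean_restored(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        out = fft_bandpass(img)
        assert out.mean() == pytest.approx(img.mean())

    def test_in_band_blob_mostly_passes(self):
        n = 128
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        blob = 100 * np.exp(-(((ii - 64) ** 2 + (jj - 64) ** 2) / (2 * 1.7 ** 2)))
        out = fft_bandpass(blob, 40, 3, "horizontal")
        assert out.max() > 0.7 * blob.max()

    def test_rejects_inverted_scales(self):
        with pytest.raises(ValueError, match="large"):
            fft_bandpass(np.zeros((8, 8)), large=3, small=40)

    def test_rejects_tiny_slice(self):
        with pytest.raises(ValueError, match=">= 4"):
            fft_bandpass(np.zeros((2, 2)))


class TestSmooth:
    def test_impulse_response_center(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = smooth(img, PipelineConfig(gaussian_sigma=2.0))
        assert out[16, 16] == pytest.approx(1.0 / (2 * np.pi * 4.0), rel=5e-3)

    def test_constant_unchanged_both_modes(self):
        img = np.full((16, 16), 3.5)
        for mode in ("gaussian_2d", "median_3d"):
            out = smooth(img, PipelineConfig(smoothing_mode=mode))
            np.testing.assert_allclose(out, img, atol=1e-12)

    def test_hot_voxel_removed_by_3d_median(self):
        stack = np.zeros((16, 16, 8))
        stack[8, 8, 4] = 100.0
        out = smooth(stack, PipelineConfig(smoothing_mode="median_3d"))
        assert out[8, 8, 4] == 0.0

    def test_gaussian_mode_on_stack_is_per_slice(self, rng):
        stack = rng.uniform(0, 10, (12, 12, 4))
        cfg = PipelineConfig()
        out = smooth(stack, cfg)
        for j in range(4):
            np.testing.assert_allclose(out[:, :, j], smooth(stack[:, :, j], cfg))


class TestG3Bank:
    def test_default_bank_has_9_kernels_at_20_degrees(self):
        bank = build_g3_bank(PipelineConfig())
        assert len(bank) == 9
        angles = [k.orientation for k in bank]
        np.testing.assert_allclose(np.diff(angles), np.pi / 9)

    def test_zero_sum_within_tolerance(self):
        for k in build_g3_bank(PipelineConfig()):
            assert abs(k.weights.sum()) <= 1e-6 * np.abs(k.weights).max()

    def test_0deg_is_90deg_transposed(self):
        bank = build_g3_bank(PipelineConfig(n_orientations=2))
        np.testing.assert_allclose(bank[0].weights, bank[1].weights.T, atol=1e-12)

    def test_kernel_validates_zero_sum(self):
        with pytest.raises(ValueError, match="zero"):
            G3Kernel(weights=np.ones((3, 3)), orientation=0.0, sigma=2.0)

    def test_central_notch_is_zero(self):
        bank = build_g3_bank(PipelineConfig(n_orientations=1))
        w = bank[0].weights
        center = w.shape[0] // 2
        np.testing.assert_array_equal(w[:, center], 0.0)


def render_tube(theta, n=128, diameter=4.0, intensity=100.0, noise_rms=1.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.abs(rng.normal(0, noise_rms, (n, n)))
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    across = -(ii - n / 2) * math.sin(theta) + (jj - n / 2) * math.cos(theta)
    img[np.abs(across) <= diameter / 2] += intensity
    return img, across


class TestRidgeEnhance:
    def test_constant_slice_maps_to_exact_zero(self):
        bank = build_g3_bank(PipelineConfig())
        out = ridge_enhance(np.full((32, 32), 123.0), bank)
        np.testing.assert_array_equal(out, 0.0)

    def test_detects_4voxel_tube_at_all_orientations(self):
        bank = build_g3_bank(PipelineConfig())
        for kern in bank:
            img, across = render_tube(kern.orientation)
            resp = ridge_enhance(img, bank)
            centerline = resp[np.abs(across) <= 0.5].mean()
            background = np.quantile(resp[np.abs(across) > 10], 0.99)
            assert centerline > background, f"missed at {kern.orientation:.2f} rad"

    def test_rotation_consistency_20deg_vs_0deg(self):
        bank = build_g3_bank(PipelineConfig())
        responses = []
        for theta in (0.0, math.radians(20)):
            img, across = render_tube(theta, noise_rms=0.0)
            resp = ridge_enhance(img, bank)
            responses.append(resp[np.abs(across) <= 0.5].mean())
        assert abs(responses[1] - responses[0]) < 0.25 * responses[0]

    def test_output_non_negative(self, rng):
        bank = build_g3_bank(PipelineConfig())
        out = ridge_enhance(rng.uniform(0, 255, (48, 48)), bank)
        assert out.min() >= 0.0


class TestMedianSuppress:
    def test_salt_noise_removed(self, rng):
        img = np.zeros((32, 32))
        idx = rng.choice(32 * 32, size=20, replace=False)
        img.ravel()[idx] = 100.0
        # isolated spikes only: drop any that landed adjacent to another
        out = median_suppress(img, radius=1)
        assert out.max() == 0.0 or (out > 0).sum() < (img > 0).sum() // 2

    def test_constant_unchanged(self):
        img = np.full((16, 16), 9.0)
        np.testing.assert_array_equal(median_suppress(img, 2), img)

    def test_4voxel_ridge_survives(self):
        img = np.zeros((32, 32))
        img[:, 14:18] = 50.0
        out = median_suppress(img, radius=2)
        assert out[:, 15:17].min() > 0.0

    def test_rejects_zero_radius(self):
        with pytest.raises(ValueError):
            median_suppress(np.zeros((8, 8)), 0)


def ball_opening_oracle(img, radius):
    """Brute-force rolling-ball background: erosion then dilation with a
    spherical structuring element, via explicit shifted-plane min/max."""
    r = int(np.ceil(radius))
    offsets = []
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            d2 = di * di + dj * dj
            if d2 <= radius * radius:
                offsets.append((di, dj, np.sqrt(radius * radius - d2) - radius))
    pad = np.pad(img, r, mode="reflect")
    n0, n1 = img.shape
    ero = np.full_like(img, np.inf)
    for di, dj, h in offsets:
        ero = np.minimum(ero, pad[r + di:r + di + n0, r + dj:r + dj + n1] - h)
    pad_e = np.pad(ero, r, mode="reflect")
    dil = np.full_like(img, -np.inf)
    for di, dj, h in offsets:
        dil = np.maximum(dil, pad_e[r + di:r + di + n0, r + dj:r + dj + n1] + h)
    return dil


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        out = rollingball_subtract(np.full((32, 32), 9.0), 10)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_ramp_removed_ridge_preserved(self):
        ramp = np.linspace(0, 60, 128)[None, :] * np.ones((128, 1))
        ridge = np.zeros((128, 128))
        ridge[:, 60:64] = 40.0
        out = rollingball_subtract(ramp + ridge, 25)
        assert abs(out[:, 60:64].mean() - 40.0) < 0.2 * 40.0
        assert out[:, :40].max() < 2.0

    def test_narrow_ridge_on_zero_background_unchanged(self):
        img = np.zeros((64, 64))
        img[:, 30:33] = 25.0
        out = rollingball_subtract(img, 25)
        # the ball dips ~r - sqrt(r^2 - (w/2)^2) under a ridge of width w
        np.testing.assert_allclose(out, img, atol=0.1)

    def test_matches_ball_opening_oracle(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        for radius in (5, 10):
            background = img - rollingball_subtract(img, radius)
            oracle = ball_opening_oracle(img, radius)
            # subtraction clamps at zero; compare where it did not engage
            np.testing.assert_allclose(
                np.minimum(background, img), np.minimum(oracle, img), atol=1e-6
            )


class TestEnhance:
    def test_zero_slice_stays_zero(self):
        out = enhance_slice(np.zeros((48, 48)), PipelineConfig())
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_deterministic(self, rng):
        img = rng.uniform(0, 255, (48, 48))
        cfg = PipelineConfig()
        np.testing.assert_array_equal(enhance_slice(img, cfg), enhance_slice(img, cfg))

    def test_output_non_negative(self, rng):
        out = enhance_slice(rng.uniform(0, 255, (48, 48)), PipelineConfig())
        assert out.min() >= 0.0

    def test_stack_identical_slices_give_identical_outputs(self, rng):
        sl = rng.uniform(0, 255, (32, 32))
        stack = EnFaceStack(np.repeat(sl[:, :, None], 3, axis=2))
        out = enhance_stack(stack, PipelineConfig())
        np.testing.assert_array_equal(out.data[:, :, 0], out.data[:, :, 1])
        np.testing.assert_array_equal(out.data[:, :, 0], out.data[:, :, 2])

    def test_stack_preserves_extents(self, rng):
        stack = EnFaceStack(rng.uniform(0, 255, (24, 20, 5)))
        out = enhance_stack(stack, PipelineConfig())
        assert out.data.shape == (24, 20, 5)

    def test_seven_checkpoints_exported(self, rng):
        stack = EnFaceStack(rng.uniform(0, 255, (24, 20, 3)))
        steps = enhance_stack(stack, PipelineConfig(), return_steps=True)
        assert tuple(steps) == STEP_NAMES
        assert len(steps) == 7
        np.testing.assert_array_equal(steps["input"].data, stack.data)

    def test_stack_matches_slice_pipeline_in_gaussian_mode(self, rng):
        stack = EnFaceStack(rng.uniform(0, 255, (32, 32, 2)))
        cfg = PipelineConfig()
        out = enhance_stack(stack, cfg)
        for j in range(2):
            np.testing.assert_allclose(
                out.data[:, :, j], enhance_slice(stack.data[:, :, j], cfg), atol=1e-9
            )

    def test_median_3d_mode_runs(self, rng):
        stack = EnFaceStack(rng.uniform(0, 255, (24, 24, 4)))
        out = enhance_stack(stack, PipelineConfig(smoothing_mode="median_3d"))
        assert out.data.shape == (24, 24, 4)
        assert out.data.min() >= 0.0


@given(value=st.floats(min_value=0.0, max_value=255.0))
@settings(max_examples=20, deadline=None)
def test_ridge_response_to_any_constant_is_zero(value):
    bank = build_g3_bank(PipelineConfig(n_orientations=3))
    out = ridge_enhance(np.full((16, 16), value), bank)
    assert np.array_equal(out, np.zeros((16, 16)))
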