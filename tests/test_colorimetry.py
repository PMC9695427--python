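import numpy as np
import pytest

from dissolvekit import colorimetry as col
from dissolvekit.colorimetry import (
    ColorimetryConfig,
    FrameStack,
    NoDynamicsError,
    RoiSpec,
    ThresholdMap,
    analyze_stack,
    classify_mixed,
    crop_roi,
    discoloration_time,
    first_mixed_map,
    load_frames,
    mixing_curve,
    threshold_map,
    threshold_map_from_stack,
    to_grayscale,
)

from _oracles import bruteforce_mixing_percent


# ---------------------------------------------------------------------------
# FrameStack / config invariants


class TestFrameStack:
    def test_requires_two_frames(self):
        with pytest.raises(ValueError, match="at least 2"):
            FrameStack(frames=np.zeros((1, 4, 4)), fps=60)

    def test_rejects_bad_fps(self):
        with pytest.raises(ValueError, match="fps"):
            FrameStack(frames=np.zeros((3, 4, 4)), fps=0)

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError, match=r"\[0, 255\]"):
            FrameStack(frames=np.full((3, 4, 4), 300.0), fps=60)

    def test_frame_times(self):
        s = FrameStack(frames=np.zeros((4, 2, 2)), fps=60, t0_offset=1.0)
        np.testing.assert_allclose(s.times, 1.0 + np.arange(4) / 60)

    def test_mask_shape_checked(self):
        with pytest.raises(ValueError, match="mask"):
            FrameStack(frames=np.zeros((3, 4, 4)), fps=60, mask=np.ones((5, 5), bool))


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"mixing_coefficient": -0.1},
        {"mixing_coefficient": 1.5},
        {"mixed_level": 0},
        {"mixed_level": 120},
        {"static_epsilon": -1},
        {"reference_last_n": 0},
        {"grayscale_weights": (0.5, 0.5, 0.5)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ColorimetryConfig(**kwargs)


# ---------------------------------------------------------------------------
# load_frames


class TestLoadFrames:
    def test_directory_of_pngs(self, tmp_path):
        import imageio.v3 as iio

        img = np.full((6, 5), 100, dtype=np.uint8)
        for k in range(3):
            iio.imwrite(tmp_path / f"f{k:03d}.png", img)
        stack = load_frames(tmp_path, fps=60)
        assert stack.n_frames == 3
        assert stack.fps == 60
        assert stack.shape == (6, 5)
        np.testing.assert_array_equal(stack.frames[0], img)

    def test_missing_source(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_frames(tmp_path / "nope", fps=60)

    def test_mismatched_shapes(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "a.png", np.zeros((4, 4), np.uint8))
        iio.imwrite(tmp_path / "b.png", np.zeros((5, 5), np.uint8))
        with pytest.raises(ValueError, match="inconsistent frame shapes"):
            load_frames(tmp_path, fps=60)

    def test_16bit_rescaled_with_warning(self, tmp_path):
        import imageio.v3 as iio

        img = np.full((4, 4), 65535, dtype=np.uint16)
        iio.imwrite(tmp_path / "a.tif", img)
        iio.imwrite(tmp_path / "b.tif", img)
        with pytest.warns(UserWarning, match="rescaling"):
            stack = load_frames(tmp_path, fps=60)
        assert stack.frames.max() == 255

    def test_fps_unresolvable(self, tmp_path):
        import imageio.v3 as iio

        for k in range(2):
            iio.imwrite(tmp_path / f"f{k}.png", np.zeros((4, 4), np.uint8))
        with pytest.raises(ValueError, match="frame rate"):
            load_frames(tmp_path)


# ---------------------------------------------------------------------------
# to_grayscale


class TestToGrayscale:
    def test_gray_rgb_maps_to_same_value(self):
        frames = np.full((2, 3, 3, 3), 200, dtype=np.uint8)
        out = to_grayscale(FrameStack(frames=frames, fps=60))
        assert out.frames.shape == (2, 3, 3)
        assert (out.frames == 200).all()

    def test_pure_blue_itu601(self):
        # oracle: round(0.114 * 255) = 29
        frames = np.zeros((2, 1, 1, 3), dtype=np.uint8)
        frames[..., 2] = 255
        out = to_grayscale(FrameStack(frames=frames, fps=60))
        assert out.frames[0, 0, 0] == 29

    def test_already_grayscale_identity(self, ramp_stack):
        assert to_grayscale(ramp_stack) is ramp_stack

    def test_bad_weights(self):
        frames = np.zeros((2, 2, 2, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="sum to 1"):
            to_grayscale(FrameStack(frames=frames, fps=60), weights=(1, 1, 1))

    def test_rounding_half_up(self):
        # 0.299*1 + 0.587*0 + 0.114*3 = 0.641 -> 1; 0.299*1 = 0.299 -> 0
        frames = np.zeros((2, 1, 2, 3), dtype=np.uint8)
        frames[:, 0, 0] = (1, 0, 3)
        frames[:, 0, 1] = (1, 0, 0)
        out = to_grayscale(FrameStack(frames=frames, fps=60))
        assert out.frames[0, 0, 0] == 1
        assert out.frames[0, 0, 1] == 0


# ---------------------------------------------------------------------------
# crop_roi


class TestCropRoi:
    def test_full_frame_identity(self, random_uint8_stack):
        roi = RoiSpec.rectangle(0, 0, *random_uint8_stack.shape)
        out = crop_roi(random_uint8_stack, roi)
        np.testing.assert_array_equal(out.frames, random_uint8_stack.frames)

    def test_rectangle_crop(self, rng):
        stack = FrameStack(frames=rng.integers(0, 256, (3, 100, 100), dtype=np.uint8), fps=60)
        out = crop_roi(stack, RoiSpec.rectangle(5, 7, 10, 10))
        assert out.shape == (10, 10)
        np.testing.assert_array_equal(out.frames, stack.frames[:, 5:15, 7:17])

    def test_out_of_bounds(self, random_uint8_stack):
        with pytest.raises(ValueError, match="exceeds"):
            crop_roi(random_uint8_stack, RoiSpec.rectangle(0, 0, 9, 9))

    def test_circular_mask_limits_n_valid(self):
        T, H, W = 5, 20, 20
        frames = np.zeros((T, H, W))
        frames[-1] = 200  # every pixel dynamic
        rr, cc = np.ogrid[:H, :W]
        mask = (rr - 10) ** 2 + (cc - 10) ** 2 <= 36
        stack = FrameStack(frames=frames, fps=60)
        out = crop_roi(stack, RoiSpec.from_mask(mask))
        tmap = threshold_map_from_stack(out)
        assert tmap.n_valid == mask.sum()
        assert tmap.n_valid < H * W

    def test_roi_spec_requires_exactly_one(self):
        with pytest.raises(ValueError):
            RoiSpec()
        with pytest.raises(ValueError):
            RoiSpec(rect=(0, 0, 2, 2), mask=np.ones((2, 2), bool))


# ---------------------------------------------------------------------------
# threshold_map / classify_mixed


class TestThresholdMap:
    def test_midpoint(self):
        first = np.full((2, 2), 40.0)
        last = np.full((2, 2), 240.0)
        tmap = threshold_map(first, last)
        assert (tmap.beta == 140.0).all()
        assert tmap.valid.all()

    def test_x_zero_gives_r0(self):
        first = np.full((2, 2), 40.0)
        last = np.full((2, 2), 240.0)
        tmap = threshold_map(first, last, ColorimetryConfig(mixing_coefficient=0.0))
        assert (tmap.beta == 40.0).all()

    def test_static_pixel_invalid(self):
        first = np.array([[100.0, 40.0]])
        last = np.array([[100.0, 240.0]])
        tmap = threshold_map(first, last)
        assert not tmap.valid[0, 0]
        assert tmap.valid[0, 1]

    def test_all_static_raises(self):
        first = last = np.full((3, 3), 100.0)
        with pytest.raises(NoDynamicsError):
            threshold_map(first, last)

    def test_beta_between_anchors(self, rng):
        first = rng.uniform(0, 255, (10, 10))
        last = rng.uniform(0, 255, (10, 10))
        tmap = threshold_map(first, last, ColorimetryConfig(static_epsilon=0))
        lo = np.minimum(first, last)
        hi = np.maximum(first, last)
        assert (tmap.beta >= lo).all() and (tmap.beta <= hi).all()

    def test_reference_last_n_mean(self):
        frames = np.zeros((5, 1, 1))
        frames[:, 0, 0] = [10, 50, 100, 200, 240]
        stack = FrameStack(frames=frames, fps=60)
        tmap = threshold_map_from_stack(stack, ColorimetryConfig(reference_last_n=2))
        assert tmap.beta[0, 0] == 10 + 0.5 * ((200 + 240) / 2 - 10)


class TestClassifyMixed:
    def _tmap(self):
        return ThresholdMap(beta=np.full((1, 1), 140.0), valid=np.ones((1, 1), bool))

    def _stack(self, v):
        frames = np.zeros((2, 1, 1))
        frames[:, 0, 0] = [0, v]
        return FrameStack(frames=frames, fps=60)

    def test_above_threshold_is_mixed(self):
        assert classify_mixed(self._stack(141), self._tmap())[1, 0, 0]

    def test_tie_is_unmixed_when_strict(self):
        assert not classify_mixed(self._stack(140), self._tmap())[1, 0, 0]

    def test_tie_is_mixed_when_non_strict(self):
        assert classify_mixed(self._stack(140), self._tmap(), strict=False)[1, 0, 0]

    def test_invalid_pixel_never_mixed(self):
        tmap = ThresholdMap(beta=np.full((1, 1), 140.0), valid=np.zeros((1, 1), bool))
        assert not classify_mixed(self._stack(255), tmap).any()

    def test_shape_mismatch(self):
        tmap = ThresholdMap(beta=np.zeros((3, 3)), valid=np.ones((3, 3), bool))
        with pytest.raises(ValueError, match="shape"):
            classify_mixed(self._stack(100), tmap)


# ---------------------------------------------------------------------------
# mixing_curve / discoloration_time / first_mixed_map


class TestMixingCurve:
    def test_ratio_of_valid_pixels(self):
        tmap = ThresholdMap(beta=np.zeros((100, 100)), valid=np.ones((100, 100), bool))
        binary = np.zeros((1, 100, 100), bool)
        binary[0].flat[:9000] = True
        curve = mixing_curve(binary, tmap, fps=60)
        assert curve.M[0] == 90.0
        assert curve.n_valid == 10000

    def test_bounds(self):
        tmap = ThresholdMap(beta=np.zeros((2, 2)), valid=np.ones((2, 2), bool))
        binary = np.zeros((2, 2, 2), bool)
        binary[1] = True
        curve = mixing_curve(binary, tmap, fps=60)
        assert curve.M[0] == 0.0 and curve.M[1] == 100.0

    def test_single_valid_pixel(self):
        valid = np.zeros((2, 2), bool)
        valid[0, 0] = True
        tmap = ThresholdMap(beta=np.zeros((2, 2)), valid=valid)
        binary = np.ones((1, 2, 2), bool)
        assert mixing_curve(binary, tmap, fps=60).M[0] == 100.0

    def test_zero_valid_pixels(self):
        tmap = ThresholdMap(beta=np.zeros((2, 2)), valid=np.zeros((2, 2), bool))
        with pytest.raises(NoDynamicsError):
            mixing_curve(np.zeros((1, 2, 2), bool), tmap, fps=60)


class TestDiscolorationTime:
    def _curve(self, M, fps=60.0):
        from dissolvekit.colorimetry import MixingCurve

        M = np.asarray(M, float)
        return MixingCurve(times=np.arange(len(M)) / fps, M=M, n_valid=100)

    def test_first_frame_at_level(self):
        M = np.zeros(200)
        M[120:] = 95.0
        res = discoloration_time(self._curve(M))
        assert res.t90 == pytest.approx(2.0)
        assert not res.censored

    def test_censored_at_video_end(self):
        M = np.full(600, 50.0)  # 10 s at 60 fps, never reaches 90
        res = discoloration_time(self._curve(M))
        assert res.censored
        assert res.t90 == pytest.approx(599 / 60)

    def test_crossing_is_first_not_any(self):
        M = np.array([0, 95, 0, 95, 95], float)
        res = discoloration_time(self._curve(M, fps=1.0))
        assert res.t90 == 1.0

    def test_interpolation_flag(self):
        M = np.array([0.0, 80.0, 100.0])
        cfg = ColorimetryConfig(interpolate=True)
        res = discoloration_time(self._curve(M, fps=1.0), cfg)
        assert res.t90 == pytest.approx(1.5)


class TestFirstMixedMap:
    def test_mixed_from_frame_zero(self):
        binary = np.ones((3, 1, 1), bool)
        fmap = first_mixed_map(binary, fps=60)
        assert fmap.times[0, 0] == 0.0

    def test_flicker_ignored(self):
        binary = np.array([0, 0, 1, 0, 1], bool)[:, None, None]
        fmap = first_mixed_map(binary, fps=60)
        assert fmap.times[0, 0] == pytest.approx(2 / 60)

    def test_never_mixed_is_nan(self):
        binary = np.zeros((5, 2, 2), bool)
        assert np.isnan(first_mixed_map(binary, fps=60).times).all()


# ---------------------------------------------------------------------------
# properties


class TestProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_bruteforce_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 256, size=(20, 8, 8), dtype=np.uint8)
        stack = FrameStack(frames=frames, fps=60)
        tmap = threshold_map_from_stack(stack)
        binary = classify_mixed(stack, tmap)
        curve = mixing_curve(binary, tmap, stack.fps)
        M_oracle, n_valid = bruteforce_mixing_percent(frames)
        assert curve.n_valid == n_valid
        np.testing.assert_array_equal(curve.M, M_oracle)

    def test_monotone_inputs_give_monotone_M(self, rng):
        # non-decreasing per-pixel traces with random increments
        T, H, W = 40, 6, 6
        incr = rng.uniform(0, 6, size=(T - 1, H, W))
        frames = np.concatenate([np.zeros((1, H, W)), np.cumsum(incr, axis=0)])
        frames = np.clip(frames, 0, 255)
        stack = FrameStack(frames=frames, fps=60)
        tmap = threshold_map_from_stack(stack, ColorimetryConfig(static_epsilon=1.0))
        curve = mixing_curve(classify_mixed(stack, tmap), tmap, stack.fps)
        assert (np.diff(curve.M) >= 0).all()

    def test_x_monotonicity_of_t90(self, rng):
        T, H, W = 60, 8, 8
        incr = rng.uniform(0, 5, size=(T - 1, H, W))
        frames = np.clip(np.concatenate([np.zeros((1, H, W)), np.cumsum(incr, axis=0)]), 0, 255)
        stack = FrameStack(frames=frames, fps=60)
        t90s = []
        for x in (0.25, 0.5, 0.75):
            cfg = ColorimetryConfig(mixing_coefficient=x, static_epsilon=1.0)
            res, _ = analyze_stack(stack, cfg)
            t90s.append(res.t90)
        assert t90s[0] <= t90s[1] <= t90s[2]

    def test_gray_shift_invariance(self, rng):
        frames = rng.integers(30, 200, size=(25, 8, 8))
        s1 = FrameStack(frames=frames.astype(float), fps=60)
        s2 = FrameStack(frames=frames.astype(float) + 17.0, fps=60)
        r1, _ = analyze_stack(s1)
        r2, _ = analyze_stack(s2)
        np.testing.assert_array_equal(r1.curve.M, r2.curve.M)
        assert r1.t90 == r2.t90 and r1.censored == r2.censored
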