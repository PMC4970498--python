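import numpy as np
import pytest
from hypothesis import given, strategies as st

from sfxprep import (
    CalibrationSet,
    apply_correction,
    detect_bad_pixels,
    load_calibration,
    save_calibration,
    split_maps,
    stack_maps,
    train,
    update,
)
from sfxprep.darkcal import save_calibration_series, subtract_common_mode_rows
from sfxprep.synthetic import gen_dark_run

from reference_impls import list_based_rejection_train


class TestTrain:
    def test_identical_frames_give_exact_offset_zero_noise(self):
        frames = np.full((100, 8, 8), 120.0)
        cal = train(frames)
        assert np.all(cal.offset == 120.0)
        assert np.all(cal.noise == 0.0)
        assert np.all(cal.counts == 100)

    def test_gaussian_parameter_recovery_within_sampling_error(self):
        frames, truth = gen_dark_run(shape=(32, 32), n_frames=200,
                                     outlier_fraction=0.0, seed=7)
        cal = train(frames)
        tol = 4 * truth.sigma / np.sqrt(200)
        frac_offset = np.mean(np.abs(cal.offset - truth.mu) <= tol)
        frac_noise = np.mean(np.abs(cal.noise / truth.sigma - 1) <= 0.15)
        assert frac_offset >= 0.99
        assert frac_noise >= 0.99

    def test_single_spike_rejected_matches_list_oracle(self):
        frames = np.full((51, 4, 4), 100.0)
        frames += np.random.default_rng(0).normal(0, 1, frames.shape)
        frames[50, 2, 2] = 10000.0
        cal = train(frames, n_outlier=3)
        mean, std, count = list_based_rejection_train(frames[:, 2, 2], 3)
        assert cal.counts[2, 2] == count == 50
        assert cal.offset[2, 2] == pytest.approx(mean)
        assert cal.noise[2, 2] == pytest.approx(std)

    def test_training_on_survivors_is_idempotent(self):
        frames, _ = gen_dark_run(shape=(8, 8), n_frames=60,
                                 outlier_fraction=0.01, seed=3)
        cal = train(frames)
        # keep only values within the final acceptance band and retrain
        keep = np.abs(frames - cal.offset) <= cal.n_outlier * np.maximum(cal.noise, 1e-6)
        pix = (4, 4)
        surviving = frames[:, pix[0], pix[1]][keep[:, pix[0], pix[1]]]
        mean, std, _ = list_based_rejection_train(surviving, 4)
        assert mean == pytest.approx(cal.offset[pix])
        assert std == pytest.approx(cal.noise[pix])

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            train(np.zeros((1, 4, 4)))

    def test_non_uniform_shapes_rejected(self):
        with pytest.raises(ValueError):
            train([np.zeros((4, 4)), np.zeros((5, 5))])


class TestUpdate:
    def test_cumulative_update_with_offset_values_keeps_offset(self):
        cal = train(np.full((10, 4, 4), 50.0))
        out = update(cal, np.full((4, 4), 50.0), scheme="cumulative")
        assert np.all(out.offset == 50.0)
        assert np.all(out.counts == 11)

    def test_exponential_converges_geometrically_to_constant(self):
        cal = train(np.full((10, 4, 4), 100.0))
        alpha = 0.1
        out = cal
        errs = []
        for _ in range(30):
            out = update(out, np.full((4, 4), 200.0), scheme="exponential",
                         alpha=alpha, n_outlier=1e9)
        # after k updates: offset = 200 - (1-alpha)^k * 100
        expected = 200.0 - (1 - alpha) ** 30 * 100.0
        assert out.offset[0, 0] == pytest.approx(expected)

    def test_cumulative_updates_equal_larger_training_on_clean_data(self):
        frames, _ = gen_dark_run(shape=(8, 8), n_frames=200,
                                 outlier_fraction=0.0, seed=11)
        cal = train(frames[:100], n_outlier=1e9)
        for f in frames[100:]:
            cal = update(cal, f, scheme="cumulative", n_outlier=1e9)
        full = train(frames, n_outlier=1e9)
        np.testing.assert_allclose(cal.offset, full.offset, rtol=1e-10)
        np.testing.assert_allclose(cal.noise, full.noise, rtol=1e-8)
        assert np.all(cal.counts == full.counts)

    def test_outlying_pixel_skipped(self):
        frames, _ = gen_dark_run(shape=(4, 4), n_frames=50,
                                 outlier_fraction=0.0, seed=2)
        cal = train(frames)
        spike = cal.offset.copy()
        spike[1, 1] += 1000.0
        out = update(cal, spike, scheme="cumulative")
        assert out.counts[1, 1] == cal.counts[1, 1]
        assert out.offset[1, 1] == cal.offset[1, 1]

    def test_invalid_alpha_rejected(self):
        cal = train(np.full((5, 2, 2), 1.0))
        with pytest.raises(ValueError, match="alpha"):
            update(cal, np.ones((2, 2)), scheme="exponential", alpha=1.5)


class TestBadPixels:
    def test_uniform_maps_mask_nothing(self):
        cal = train(np.full((10, 8, 8), 42.0))
        out = detect_bad_pixels(cal, "auto", n=4)
        assert out.mask.sum() == 0

    def test_single_10x_offset_pixel_flagged_by_auto_bounds(self):
        frames, truth = gen_dark_run(shape=(16, 16), n_frames=100,
                                     outlier_fraction=0.0, seed=5)
        cal = train(frames)
        cal.offset[3, 9] *= 10
        out = detect_bad_pixels(cal, "auto", n=4)
        expected = np.zeros((16, 16), dtype=bool)
        expected[3, 9] = True
        np.testing.assert_array_equal(out.mask.astype(bool), expected)

    def test_explicit_offset_bounds(self):
        offset = np.full((4, 4), 100.0)
        offset[0, :2] = 120.0
        cal = CalibrationSet(offset=offset, noise=np.ones((4, 4)),
                             counts=np.full((4, 4), 10), mask=np.zeros((4, 4), np.uint8),
                             train_size=10)
        out = detect_bad_pixels(cal, {"offset": (90, 110)})
        assert out.mask.sum() == 2
        assert out.mask[0, 0] == 1 and out.mask[0, 1] == 1

    def test_mask_stable_under_rerun_with_same_bounds(self):
        frames, _ = gen_dark_run(shape=(16, 16), n_frames=80, bad_fraction=0.02, seed=9)
        cal = detect_bad_pixels(train(frames), "auto", n=4)
        again = detect_bad_pixels(cal, cal.bounds)
        np.testing.assert_array_equal(cal.mask, again.mask)


class TestApplyCorrection:
    def test_crystfel_dialect_zeroes_frame_equal_to_offset(self):
        frames, _ = gen_dark_run(shape=(8, 8), n_frames=20, outlier_fraction=0.0, seed=1)
        cal = train(frames)
        out = apply_correction(cal.offset.copy(), cal, dialect="crystfel")
        np.testing.assert_allclose(out, 0.0)

    def test_nxds_dialect_leaves_unmasked_pixels_bit_identical(self):
        cal = train(np.full((5, 6, 6), 90.0))
        cal.mask[2, 2] = 1
        raw = np.arange(36, dtype=np.int32).reshape(6, 6)
        out = apply_correction(raw, cal, dialect="nxds")
        good = cal.mask == 0
        assert out.dtype == raw.dtype
        np.testing.assert_array_equal(out[good], raw[good])
        assert out[2, 2] == -1

    def test_masked_value_honoured_regardless_of_input(self):
        cal = train(np.full((5, 4, 4), 10.0))
        cal.mask[1, 3] = 1
        out = apply_correction(np.full((4, 4), 77.0), cal, dialect="crystfel",
                               masked_value=-5.0)
        assert out[1, 3] == -5.0


class TestStackSplit:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_stack_split_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        cal = CalibrationSet(
            offset=rng.normal(100, 10, (8, 8)),
            noise=np.abs(rng.normal(2, 0.5, (8, 8))),
            counts=rng.integers(0, 100, (8, 8)),
            mask=rng.integers(0, 2, (8, 8)).astype(np.uint8),
            train_size=100,
        )
        back = split_maps(stack_maps(cal), train_size=100)
        np.testing.assert_array_equal(back.offset, cal.offset)
        np.testing.assert_array_equal(back.noise, cal.noise)
        np.testing.assert_array_equal(back.counts, cal.counts)
        np.testing.assert_array_equal(back.mask, cal.mask)

    def test_stack_shape_and_block_order(self):
        cal = train(np.full((4, 64, 64), 5.0))
        stacked = stack_maps(cal)
        assert stacked.shape == (256, 64)
        np.testing.assert_array_equal(stacked[128:192], cal.counts)

    def test_bad_height_rejected(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            split_maps(np.zeros((10, 4)))


class TestPersistence:
    def test_save_load_roundtrip_bitexact(self, tmp_path):
        frames, _ = gen_dark_run(shape=(16, 16), n_frames=50, seed=4)
        cal = detect_bad_pixels(train(frames))
        path = save_calibration(cal, tmp_path / "cal.h5")
        back = load_calibration(path)
        np.testing.assert_array_equal(back.offset, cal.offset)
        np.testing.assert_array_equal(back.noise, cal.noise)
        np.testing.assert_array_equal(back.counts, cal.counts)
        np.testing.assert_array_equal(back.mask, cal.mask)
        assert back.train_size == cal.train_size

    def test_offset_noise_only_file_gets_synthetic_counts_and_mask(self, tmp_path):
        import h5py

        frames, _ = gen_dark_run(shape=(16, 16), n_frames=60, bad_fraction=0.02, seed=8)
        cal = train(frames)
        path = tmp_path / "partial.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("offset", data=cal.offset)
            f.create_dataset("noise", data=cal.noise)
            f.attrs["train_size"] = 60
        back = load_calibration(path)
        assert np.all(back.counts == 60)
        expected = detect_bad_pixels(cal, "auto", n=4)
        np.testing.assert_array_equal(back.mask, expected.mask)

    def test_missing_required_datasets_error_lists_found(self, tmp_path):
        import h5py

        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("offset", data=np.zeros((4, 4)))
        with pytest.raises(ValueError, match="noise"):
            load_calibration(path)

    def test_series_saves_distinct_files_and_latest_alias(self, tmp_path):
        cal = train(np.full((5, 4, 4), 3.0))
        p1, alias1 = save_calibration_series(cal, tmp_path, base="dark")
        p2, alias2 = save_calibration_series(cal, tmp_path, base="dark")
        assert p1 != p2
        assert alias1 == alias2
        latest = load_calibration(alias2)
        np.testing.assert_array_equal(latest.offset, cal.offset)


def test_common_mode_row_median_subtraction():
    frame = np.outer(np.array([10.0, -5.0, 0.0]), np.ones(7))
    frame[:, 0] += 1.0  # one odd pixel per row does not move the median
    out = subtract_common_mode_rows(frame)
    np.testing.assert_allclose(out[:, 1:], 0.0)
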