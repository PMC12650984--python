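import numpy as np
import pytest

from brixnet.preprocess import (
    FruitPatchDataset,
    NoRoiFoundError,
    ReflectanceCube,
    RoiMask,
    augment,
    calibrate_cube,
    calibrate_reflectance,
    compute_ratio_mask,
    crop_to,
    extract_mean_spectrum,
    extract_patch_pairs,
    normalize_cube,
    rotate_cube,
)
from brixnet.synthetic_data import generate_cube


def _cube(data):
    data = np.asarray(data, dtype=float)
    wl = np.linspace(400, 1000, data.shape[2])
    return ReflectanceCube(data, wl)


class TestCalibration:
    def test_identities(self, rng):
        white = rng.uniform(100, 200, (4, 4, 3))
        black = rng.uniform(0, 50, (4, 4, 3))
        assert np.array_equal(calibrate_reflectance(white, white, black), np.ones((4, 4, 3)))
        assert np.array_equal(calibrate_reflectance(black, white, black), np.zeros((4, 4, 3)))

    def test_midpoint_arithmetic(self):
        out = calibrate_reflectance(
            np.full((1, 1, 1), 60.0), np.full((1, 1, 1), 110.0), np.full((1, 1, 1), 10.0)
        )
        assert out[0, 0, 0] == 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            calibrate_reflectance(np.zeros((2, 2, 2)), np.ones((2, 2, 3)), np.zeros((2, 2, 2)))

    def test_zero_denominator_pixels_warned_and_zeroed(self):
        raw = np.ones((2, 2, 1))
        white = np.ones((2, 2, 1))
        black = np.ones((2, 2, 1))
        white[0, 0, 0] = 2.0
        with pytest.warns(RuntimeWarning, match="white == black"):
            out = calibrate_reflectance(raw, white, black)
        assert out[0, 1, 0] == 0.0 and out[0, 0, 0] == 0.0


class TestRatioMask:
    def test_threshold_rule_inclusive(self):
        data = np.ones((2, 2, 16))
        wl = np.linspace(400, 1000, 16)
        num_band = np.argmin(abs(wl - 715.16))
        den_band = np.argmin(abs(wl - 525.54))
        data[0, 0, num_band] = 2.0      # ratio 2.0 -> in
        data[0, 1, num_band] = 1.6      # ratio exactly 1.6 -> in (minimum threshold)
        data[1, :, num_band] = 1.0      # ratio 1.0 -> out
        mask = compute_ratio_mask(ReflectanceCube(data, wl)).mask
        assert mask[0, 0] and mask[0, 1]
        assert not mask[1].any()

    def test_uniform_cube_raises_no_roi(self):
        cube = _cube(np.ones((4, 4, 16)))
        with pytest.raises(NoRoiFoundError):
            compute_ratio_mask(cube)

    def test_largest_component_kept(self):
        wl = np.linspace(400, 1000, 16)
        num_band = np.argmin(abs(wl - 715.16))
        data = np.ones((8, 8, 16))
        data[0:4, 0:4, num_band] = 3.0   # 16-pixel blob
        data[7, 7, num_band] = 3.0       # stray pixel
        mask = compute_ratio_mask(ReflectanceCube(data, wl)).mask
        assert mask[0:4, 0:4].all() and not mask[7, 7]

    def test_matches_truth_exactly_on_noiseless_scene(self, small_cube):
        cal = calibrate_cube(small_cube)
        mask = compute_ratio_mask(cal).mask
        assert np.array_equal(mask, small_cube.truth_mask)


class TestMeanSpectrum:
    def test_single_pixel_mask(self, rng):
        cube = _cube(rng.uniform(size=(5, 5, 4)))
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        assert np.array_equal(extract_mean_spectrum(cube, mask), cube.data[2, 3])

    def test_matches_explicit_loop(self, rng):
        cube = _cube(rng.uniform(size=(5, 5, 4)))
        mask = rng.uniform(size=(5, 5)) > 0.5
        mask[0, 0] = True
        expected = np.zeros(4)
        count = 0
        for i in range(5):
            for j in range(5):
                if mask[i, j]:
                    expected += cube.data[i, j]
                    count += 1
        assert np.allclose(extract_mean_spectrum(cube, mask), expected / count, atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_mean_spectrum(_cube(np.ones((3, 3, 2))), np.zeros((3, 3), bool))


class TestAugmentation:
    def test_exactly_five_images_first_is_original(self, rng):
        cube = _cube(rng.uniform(size=(16, 16, 4)))
        out = augment(cube, seed=0)
        assert len(out) == 5
        assert np.array_equal(out[0].data, cube.data)
        for o in out:
            assert o.data.shape == cube.data.shape

    def test_mirror_is_involution(self, rng):
        cube = _cube(rng.uniform(size=(8, 8, 3)))
        mirrored = augment(cube, seed=0)[4]
        assert np.array_equal(mirrored.data[:, ::-1, :], cube.data)

    def test_half_turn_preserves_symmetric_disk(self):
        # a centred disk is invariant under a 180-degree rotation
        yy, xx = np.mgrid[0:33, 0:33]
        disk = (((yy - 16) ** 2 + (xx - 16) ** 2) <= 100).astype(float)
        cube = _cube(np.repeat(disk[:, :, None], 2, axis=2))
        rot = rotate_cube(cube, 180.0)
        assert np.allclose(rot.data, cube.data, atol=1e-7)

    def test_rotation_angles_in_specified_ranges(self):
        from brixnet.preprocess import _augment_angles

        for seed in range(20):
            a, b, c = _augment_angles(seed)
            assert 0 <= a <= 30 and 150 <= b <= 180 and 180 <= c <= 210


class TestNormalize:
    def test_full_range_after_scaling(self, rng):
        cube = _cube(0.2 + 0.5 * rng.uniform(size=(4, 4, 3)))
        out = normalize_cube(cube)
        assert out.data.min() == 0.0 and out.data.max() == 1.0

    def test_already_scaled_cube_unchanged(self, rng):
        data = rng.uniform(size=(4, 4, 3))
        data.flat[0], data.flat[-1] = 0.0, 1.0
        out = normalize_cube(_cube(data))
        assert np.allclose(out.data, data, atol=1e-15)

    def test_constant_cube_maps_to_zeros_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant cube"):
            out = normalize_cube(_cube(np.full((3, 3, 2), 0.7)))
        assert not out.data.any()

    def test_nonfinite_rejected(self):
        data = np.ones((2, 2, 2))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            normalize_cube(_cube(data))


class TestCrop:
    def test_large_cube_cropped_to_size(self, rng):
        data = rng.uniform(size=(300, 300, 3)) * 0.1
        mask = np.zeros((300, 300), bool)
        mask[100:160, 120:180] = True
        cube, m = crop_to(_cube(data), RoiMask(mask), size=224)
        assert cube.data.shape == (224, 224, 3) and m.mask.shape == (224, 224)

    def test_same_size_is_identity(self, rng):
        data = rng.uniform(size=(64, 64, 3))
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        cube, m = crop_to(_cube(data), RoiMask(mask), size=64)
        assert np.array_equal(cube.data, data) and np.array_equal(m.mask, mask)

    def test_centroid_lands_at_window_centre(self, rng):
        data = rng.uniform(size=(200, 200, 2))
        mask = np.zeros((200, 200), bool)
        mask[80:120, 90:130] = True
        _, m = crop_to(_cube(data), RoiMask(mask), size=64)
        rows, cols = np.nonzero(m.mask)
        assert abs(rows.mean() - 31.5) <= 1.0 and abs(cols.mean() - 31.5) <= 1.0

    def test_small_cube_reflect_padded(self, rng):
        data = rng.uniform(size=(20, 20, 2))
        mask = np.ones((20, 20), bool)
        cube, m = crop_to(_cube(data), RoiMask(mask), size=31)
        assert cube.data.shape == (31, 31, 2)
        assert m.mask.sum() == 400  # padding never invents fruit pixels

    def test_too_small_size_rejected(self, rng):
        with pytest.raises(ValueError):
            crop_to(_cube(np.ones((40, 40, 2))), RoiMask(np.ones((40, 40), bool)), size=16)


class TestPatchPairs:
    def test_shapes_and_center_value(self, rng):
        data = rng.uniform(size=(64, 64, 5))
        mask = np.zeros((64, 64), bool)
        mask[10:50, 10:50] = True
        pairs = extract_patch_pairs(_cube(data), mask, k_centers=4, seed=0)
        assert len(pairs) == 4
        for p in pairs:
            assert p.spectral_patch.shape == (3, 3, 5)
            assert p.spatial_patch.shape == (31, 31, 5)
            r, c = p.center
            assert mask[r, c]
            assert np.array_equal(p.spectral_patch[1, 1], data[r, c])
            assert np.array_equal(p.spatial_patch[15, 15], data[r, c])

    def test_corner_patch_matches_reflect_pad_oracle(self, rng):
        data = rng.uniform(size=(5, 5, 2))
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        (pair,) = extract_patch_pairs(
            _cube(data), mask, k_centers=1, seed=0, spectral_size=3, spatial_size=5
        )
        padded = np.pad(data, [(2, 2), (2, 2), (0, 0)], mode="reflect")
        assert np.array_equal(pair.spatial_patch, padded[0:5, 0:5])
        assert np.array_equal(pair.spectral_patch, padded[1:4, 1:4])

    def test_all_mask_pixels_when_k_exceeds_roi(self, rng):
        data = rng.uniform(size=(40, 40, 3))
        mask = np.zeros((40, 40), bool)
        mask[5, 5] = mask[6, 6] = True
        pairs = extract_patch_pairs(_cube(data), mask, k_centers=10, seed=0)
        assert len(pairs) == 2

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patch_pairs(_cube(np.ones((8, 8, 2))), np.ones((8, 8), bool), 0, 0)


class TestFruitPatchDataset:
    def test_augmented_training_never_touches_validation_ids(self, noisy_params):
        from brixnet.synthetic_data import generate_dataset

        cubes, _ = generate_dataset(noisy_params, 6, seed=0)
        ds = FruitPatchDataset.from_labeled_cubes(cubes, k_centers=2)
        train_ids, val_ids = ds.sample_ids[:4], ds.sample_ids[4:]
        _, _, _, train_pids = ds.patch_arrays(train_ids, seed=0, augment_data=True)
        _, _, _, val_pids = ds.patch_arrays(val_ids, seed=1, augment_data=False)
        assert set(train_pids) == set(train_ids)
        assert set(val_pids) == set(val_ids)
        assert not set(train_pids) & set(val_pids)

    def test_augmentation_multiplies_patches_five_fold(self, noisy_params):
        cube = generate_cube(noisy_params, 12.0, seed=0)
        cube.sample_id = "s0"
        ds = FruitPatchDataset.from_labeled_cubes([cube], k_centers=3)
        _, _, y_plain, _ = ds.patch_arrays(["s0"], seed=0)
        _, _, y_aug, _ = ds.patch_arrays(["s0"], seed=0, augment_data=True)
        assert len(y_aug) == 5 * len(y_plain)
        assert np.allclose(y_aug, y_plain[0])  # every view keeps the fruit's label
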