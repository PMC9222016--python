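"""Descriptor triplet: stain normalization, RAW/HOG/LBP, augmentation."""

import numpy as np
import pytest
from skimage.color import hed2rgb, rgb2hed
from skimage.feature import local_binary_pattern

from wsifuse.descriptors import (AugmentSample, AugmentationParams, HogParams,
                                 LbpParams, NoStainWarning, apply_augmentation,
                                 augment, compute_hog, compute_lbp,
                                 compute_raw, featurize_store, read_features,
                                 stain_normalize, stain_profile,
                                 write_features)

from ._oracles import hog_bruteforce, lbp_uniform_oracle


class TestStainNormalize:
    def test_self_profile_is_near_identity(self, small_patch_store):
        patch = small_patch_store.patches[0]
        out = stain_normalize(patch, stain_profile(patch))
        diff = np.abs(out.astype(float) - patch.astype(float)).mean()
        assert diff < 2.0  # < 2/255 per-channel mean absolute difference

    def test_pure_white_patch_returned_unchanged_with_warning(self):
        white = np.full((224, 224, 3), 255, np.uint8)
        with pytest.warns(NoStainWarning):
            out = stain_normalize(white)
        assert np.array_equal(out, white)

    def test_understained_copy_converges_to_reference(self, small_patch_store):
        patch = small_patch_store.patches[0]
        # render the same tissue with optical density scaled by 0.7
        weak = np.clip(np.round(hed2rgb(
            rgb2hed(patch.astype(float) / 255.0) * 0.7) * 255), 0, 255
        ).astype(np.uint8)
        before = np.abs(patch.astype(float) - weak.astype(float)).mean()
        a = stain_normalize(patch)
        b = stain_normalize(weak)
        after = np.abs(a.astype(float) - b.astype(float)).mean()
        assert after < before

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            stain_normalize(np.zeros((10, 10), np.uint8))


class TestComputeRaw:
    def test_length_is_4800(self, small_patch_store):
        assert compute_raw(small_patch_store.patches[0]).shape == (4800,)

    def test_constant_patch_maps_to_constant_fraction(self):
        patch = np.full((224, 224, 3), 51, np.uint8)
        vec = compute_raw(patch)
        assert np.allclose(vec, 51 / 255.0)

    def test_already_40x40_is_flatten_only(self, rng):
        patch = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        assert np.array_equal(compute_raw(patch),
                              (patch / 255.0).ravel().astype(np.float32))

    def test_grayscale_input_rejected(self):
        with pytest.raises(ValueError):
            compute_raw(np.zeros((224, 224), np.uint8))


class TestComputeHog:
    def test_length_is_64(self, small_patch_store):
        assert compute_hog(small_patch_store.patches[0]).shape == (64,)

    def test_constant_image_gives_zero_vector(self):
        assert not compute_hog(np.full((40, 40, 3), 120, np.uint8)).any()

    def test_vertical_stripes_concentrate_in_horizontal_gradient_bins(self):
        xx = np.arange(40)
        stripes = (127 + 120 * np.sin(2 * np.pi * xx / 8))[None, :].repeat(40, 0)
        patch = np.stack([stripes] * 3, -1).astype(np.uint8)
        vec = compute_hog(patch)
        cells = vec.reshape(4, 16)
        for hist in cells:
            mass = hist.sum()
            # bins 0 and 15 straddle orientation 0 (horizontal gradient)
            assert hist[0] + hist[15] >= 0.8 * mass

    def test_matches_bruteforce_oracle_on_random_images(self, rng):
        params = HogParams()
        for _ in range(10):
            patch = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
            ours = compute_hog(patch, params)
            oracle = hog_bruteforce(patch)
            assert np.abs(ours - oracle).max() < 1e-6


class TestComputeLbp:
    def test_length_is_254(self, small_patch_store):
        assert compute_lbp(small_patch_store.patches[0]).shape == (254,)

    def test_constant_image_gives_constant_vector(self):
        vec = compute_lbp(np.full((64, 64, 3), 77, np.uint8))
        assert len(set(vec.tolist())) == 1

    def test_codes_bounded_by_p_plus_one(self, small_patch_store):
        params = LbpParams()
        for patch in small_patch_store.patches[:8]:
            vec = compute_lbp(patch, params)
            assert vec.min() >= 0
            assert vec.max() <= params.n_points + 1

    def test_matches_exhaustive_bit_rotation_oracle(self, rng):
        for _ in range(5):
            gray = rng.integers(0, 256, (8, 8))
            skimage_codes = local_binary_pattern(gray, 8, 1.0, "uniform")
            oracle_codes = lbp_uniform_oracle(gray.astype(float), p=8, r=1.0)
            interior = ~np.isnan(oracle_codes)
            assert np.array_equal(skimage_codes[interior], oracle_codes[interior])


class TestAugment:
    def test_horizontal_flip_is_an_involution(self, rng):
        patch = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        flip = AugmentSample(hflip=True)
        assert np.array_equal(
            apply_augmentation(apply_augmentation(patch, flip), flip), patch)

    def test_identity_sample_is_identity(self, rng):
        patch = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        assert np.array_equal(apply_augmentation(patch, AugmentSample()), patch)

    def test_multiplier_counts(self, rng):
        patch = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        assert augment(patch, AugmentationParams(multiplier=0)) == []
        assert len(augment(patch, AugmentationParams(multiplier=4))) == 4

    def test_augment_is_seeded(self, rng):
        patch = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        a = augment(patch, AugmentationParams(multiplier=3, seed=9))
        b = augment(patch, AugmentationParams(multiplier=3, seed=9))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestFeaturizeStore:
    def test_counts_without_augmentation(self, small_patch_store):
        feats = featurize_store(small_patch_store)
        assert len(feats) == len(small_patch_store)
        assert feats.raw.shape == (160, 4800)
        assert feats.hog.shape == (160, 64)
        assert feats.lbp.shape == (160, 254)

    def test_multiplier_three_triples_the_records(self, small_patch_store):
        subset = small_patch_store.subset(np.arange(8))
        feats = featurize_store(subset, AugmentationParams(multiplier=3, seed=0))
        assert len(feats) == 24

    def test_augmented_records_keep_source_labels(self, small_patch_store):
        subset = small_patch_store.subset(np.arange(12))
        feats = featurize_store(subset, AugmentationParams(multiplier=2, seed=1))
        for i in range(len(feats)):
            assert feats.labels[i] == subset.labels[feats.source_index[i]]

    def test_empty_store_rejected(self):
        from wsifuse.preprocess import PatchStore
        with pytest.raises(ValueError):
            featurize_store(PatchStore.empty())

    def test_feature_roundtrip(self, small_patch_store, tmp_path):
        feats = featurize_store(small_patch_store.subset(np.arange(4)))
        path = tmp_path / "features.h5"
        write_features(feats, path)
        loaded = read_features(path)
        assert np.array_equal(loaded.raw, feats.raw)
        assert np.array_equal(loaded.labels, feats.labels)
        assert loaded.params_json == feats.params_json
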