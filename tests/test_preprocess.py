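"""Tissue segmentation, patch extraction and HDF5 store round-trips."""

import json

import h5py
import numpy as np
import pytest

from wsifuse.preprocess import (PatchStore, SegmentationParams, SlideImage,
                                StoreSchemaError, balance_classes,
                                extract_patches, read_store, segment_tissue,
                                write_store)
from wsifuse.synthetic import SyntheticSlideSpec, make_slide

HE = (180, 105, 150)


def _upsample(mask, factor, shape):
    up = np.repeat(np.repeat(mask, factor, axis=0), factor, axis=1)
    return up[:shape[0], :shape[1]]


class TestSegmentTissue:
    def test_three_blobs_three_contours_with_high_iou(self, three_blob_slide,
                                                      seg_params):
        spec, slide, gt = three_blob_slide
        mask = segment_tissue(slide, seg_params)
        assert mask.n_regions == 3
        up = _upsample(mask.mask, 8, gt.shape)
        iou = (up & gt).sum() / (up | gt).sum()
        assert iou > 0.9
        # each blob centroid falls inside exactly one contour's span
        for (cx, cy), _, _ in spec.blobs:
            assert mask.mask[int(cy / 8), int(cx / 8)]

    def test_all_white_slide_has_no_contours(self, seg_params):
        slide, _ = make_slide(SyntheticSlideSpec(
            width=1024, height=1024, blobs=[], seed=2))
        mask = segment_tissue(slide, seg_params)
        assert mask.n_regions == 0
        assert not mask.mask.any()

    def test_small_blob_filtered_from_contours_but_in_prefilter_mask(self):
        r_small = 40.0  # area at 8x downsample ~ pi*5^2 ~ 79 px^2
        slide, _ = make_slide(SyntheticSlideSpec(
            width=1024, height=1024,
            blobs=[((300, 300), 200.0, HE), ((800, 800), r_small, HE)],
            seed=0))
        params = SegmentationParams(seg_downsample=8, min_contour_area=200)
        mask = segment_tissue(slide, params)
        assert mask.n_regions == 1
        assert mask.prefilter_mask[100, 100]  # small blob survives pre-filter
        assert not mask.mask[100, 100]

    def test_fixed_threshold_mode(self, three_blob_slide):
        _, slide, _ = three_blob_slide
        mask = segment_tissue(slide, SegmentationParams(
            seg_downsample=8, sat_threshold=0.1, min_contour_area=50))
        assert mask.n_regions == 3

    @pytest.mark.parametrize("kwargs", [
        {"median_kernel": 4}, {"median_kernel": 0},
        {"closing_kernel": 0}, {"min_contour_area": -1},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)


class TestExtractPatches:
    def _rect_slide(self, rect_w=896, rect_h=448):
        img = np.full((1344, 1344, 3), 245, np.uint8)
        x0, y0 = 224, 448
        img[y0:y0 + rect_h, x0:x0 + rect_w] = HE
        return SlideImage(img, slide_id="rect"), (x0, y0, rect_w, rect_h)

    def test_rectangular_tissue_gives_grid_count(self):
        slide, (x0, y0, w, h) = self._rect_slide()
        mask = segment_tissue(slide, SegmentationParams(
            seg_downsample=4, min_contour_area=50))
        store = extract_patches(slide, mask, 20.0, labels=0)
        assert len(store) == (w // 224) * (h // 224)  # 4 x 2 = 8

    def test_patch_dimensions_are_224(self, three_blob_slide, seg_params):
        _, slide, _ = three_blob_slide
        mask = segment_tissue(slide, seg_params)
        store = extract_patches(slide, mask, 20.0, labels=1)
        assert len(store) > 0
        assert store.patches.shape[1:] == (224, 224, 3)
        assert (store.labels == 1).all()

    def test_all_patch_centers_lie_in_foreground(self, three_blob_slide,
                                                 seg_params):
        _, slide, _ = three_blob_slide
        mask = segment_tissue(slide, seg_params)
        store = extract_patches(slide, mask, 20.0, labels=0)
        for (x, y) in store.coords:
            assert mask.mask[int((y + 112) / 8), int((x + 112) / 8)]

    def test_coordinate_consistency_reread_is_exact(self, three_blob_slide,
                                                    seg_params):
        _, slide, _ = three_blob_slide
        mask = segment_tissue(slide, seg_params)
        store = extract_patches(slide, mask, 20.0, labels=0)
        for i in range(len(store)):
            region = slide.read_region(tuple(store.coords[i]), 0, (224, 224))
            assert np.array_equal(region, store.patches[i])

    def test_empty_mask_gives_empty_store_with_warning(self, seg_params):
        slide, _ = make_slide(SyntheticSlideSpec(
            width=1024, height=1024, blobs=[], seed=0))
        mask = segment_tissue(slide, seg_params)
        with pytest.warns(UserWarning, match="empty"):
            store = extract_patches(slide, mask, 20.0, labels=0)
        assert len(store) == 0

    def test_magnification_above_native_rejected(self, three_blob_slide,
                                                 seg_params):
        _, slide, _ = three_blob_slide
        mask = segment_tissue(slide, seg_params)
        with pytest.raises(ValueError, match="magnification"):
            extract_patches(slide, mask, 40.0, labels=0)

    def test_lower_magnification_downsamples_regions(self, three_blob_slide,
                                                     seg_params):
        _, slide, _ = three_blob_slide
        mask = segment_tissue(slide, seg_params)
        store = extract_patches(slide, mask, 10.0, labels=0)
        # 10x on a 20x slide covers 448 px of level 0 per patch, served
        # from pyramid level 1 without resampling
        assert store.patches.shape[1:] == (224, 224, 3)
        assert len(store) > 0
        for i in range(len(store)):
            region = slide.read_region(tuple(store.coords[i]), 1, (224, 224))
            assert np.array_equal(region, store.patches[i])


class TestStoreRoundtrip:
    def test_roundtrip_is_field_identical(self, small_patch_store, tmp_path):
        path = tmp_path / "store.h5"
        write_store(small_patch_store, path)
        loaded = read_store(path)
        assert np.array_equal(loaded.patches, small_patch_store.patches)
        assert np.array_equal(loaded.coords, small_patch_store.coords)
        assert np.array_equal(loaded.labels, small_patch_store.labels)
        assert loaded.slide_ids.tolist() == small_patch_store.slide_ids.tolist()
        assert loaded.class_names == small_patch_store.class_names
        assert loaded.magnification == small_patch_store.magnification

    def test_manifest_fields_survive_roundtrip(self, three_blob_slide,
                                               seg_params, tmp_path):
        _, slide, _ = three_blob_slide
        mask = segment_tissue(slide, seg_params)
        store = extract_patches(slide, mask, 20.0, labels=0)
        path = tmp_path / "store.h5"
        write_store(store, path)
        loaded = read_store(path)
        assert loaded.manifest["segmentation"]["seg_downsample"] == 8
        assert loaded.manifest["segmentation"]["min_contour_area"] == 50
        sidecar = json.loads(
            (tmp_path / "store.h5.manifest.json").read_text())
        assert sidecar["n_patches"] == len(store)

    def test_empty_store_roundtrip(self, tmp_path):
        path = tmp_path / "empty.h5"
        write_store(PatchStore.empty(), path)
        assert len(read_store(path)) == 0

    def test_schema_version_mismatch_names_both_versions(self,
                                                         small_patch_store,
                                                         tmp_path):
        path = tmp_path / "store.h5"
        write_store(small_patch_store, path)
        with h5py.File(path, "r+") as f:
            f.attrs["schema_version"] = "99"
        with pytest.raises(StoreSchemaError, match=r"expected '1'.*found '99'"):
            read_store(path)


class TestBalanceClasses:
    def test_subsample_reaches_target(self, small_patch_store):
        out = balance_classes(small_patch_store, {0: 10}, seed=0)
        assert out.class_counts() == {0: 10, 1: 40, 2: 40, 3: 40}

    def test_target_equal_to_count_is_identity(self, small_patch_store):
        out = balance_classes(small_patch_store, {0: 40}, seed=0)
        src = small_patch_store.patches[small_patch_store.labels == 0]
        assert np.array_equal(out.patches[out.labels == 0], src)

    def test_same_seed_selects_same_records(self, small_patch_store):
        a = balance_classes(small_patch_store, {1: 7}, seed=5)
        b = balance_classes(small_patch_store, {1: 7}, seed=5)
        assert np.array_equal(a.patches, b.patches)

    def test_overdraw_names_the_class(self, small_patch_store):
        with pytest.raises(ValueError, match="class0"):
            balance_classes(small_patch_store, {0: 10_000}, seed=0)


class TestSlideImage:
    def test_pyramid_downsamples_increase_monotonically(self, three_blob_slide):
        _, slide, _ = three_blob_slide
        ds = slide.level_downsamples
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_out_of_bounds_region_rejected(self, three_blob_slide):
        _, slide, _ = three_blob_slide
        with pytest.raises(ValueError, match="out of bounds"):
            slide.read_region((2000, 2000), 0, (224, 224))

    def test_file_roundtrip(self, tmp_path, three_blob_slide):
        _, slide, _ = three_blob_slide
        path = tmp_path / "slide.png"
        slide.to_file(path)
        loaded = SlideImage.from_file(path)
        assert np.array_equal(loaded.read_region((0, 0), 0, (256, 256)),
                              slide.read_region((0, 0), 0, (256, 256)))
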