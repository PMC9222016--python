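import numpy as np
import pytest

from wsifuse.descriptors import featurize_store
from wsifuse.pipeline import split_dataset
from wsifuse.preprocess import SegmentationParams
from wsifuse.synthetic import (SyntheticPatchSpec, SyntheticSlideSpec,
                               make_patch_dataset, make_slide)

HE = (180, 105, 150)


@pytest.fixture(scope="session")
def three_blob_slide():
    """A 2048^2 slide with three disjoint stained blobs + ground truth."""
    spec = SyntheticSlideSpec(
        width=2048, height=2048,
        blobs=[((500, 500), 200, HE), ((1400, 600), 250, HE),
               ((900, 1500), 220, HE)],
        seed=1)
    slide, gt = make_slide(spec)
    return spec, slide, gt


@pytest.fixture(scope="session")
def seg_params():
    """Segmentation settings matched to the fixture scale (8x downsample)."""
    return SegmentationParams(seg_downsample=8, min_contour_area=50)


@pytest.fixture(scope="session")
def small_patch_store():
    """4 classes x 40 patches; small enough for fast descriptor tests."""
    return make_patch_dataset(SyntheticPatchSpec(
        n_classes=4, patches_per_class=40, seed=0))


@pytest.fixture(scope="session")
def small_features(small_patch_store):
    """Featurized stratified 80:20 record-level split of the small store."""
    train, test = split_dataset(small_patch_store, 0.8,
                                group_by_slide=False, seed=1)
    return featurize_store(train), featurize_store(test)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
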