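"""Per-patch descriptor triplet: RAW, HOG and LBP feature vectors.

Each 224x224 RGB patch is stain-normalized and converted into three flat
feature vectors that feed one autoencoder each:

* **RAW** (4800) — the patch bilinearly rescaled to 40x40x3, scaled to
  [0, 1] and flattened; carries color/holistic appearance.
* **HOG** (64) — histogram of oriented gradients of the 40x40 grayscale
  patch with 16 orientations, 14x14-pixel cells and single-cell blocks:
  floor(40/14)^2 * 16 = 64 features; carries shape/orientation.
* **LBP** (254) — uniform local binary pattern codes (P=16 circular
  neighbors, radius 2) of the grayscale patch; the code image is resized
  to 16x16 (nearest neighbor), flattened and trimmed to 254 entries so the
  downstream same-size dense encoder has 254*(254+1) = 64,770 parameters;
  carries micro-texture.

Stain normalization maps a patch's H&E optical-density profile onto a
stored reference profile (color-deconvolution based), so over-/under-
stained inputs agree in color distribution before featurization.
Augmentation (flips, right-angle rotations, shifts, brightness, zoom,
blur) operates on pixels; descriptors are always recomputed from the
augmented pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.color import hed2rgb, rgb2hed
from skimage.feature import local_binary_pattern
from skimage.filters import gaussian
from skimage.transform import resize, rotate, rescale

from .preprocess import PatchStore

RAW_DIM = 4800
HOG_DIM = 64
LBP_DIM = 254
RAW_SIZE = 40

__all__ = [
    "RAW_DIM", "HOG_DIM", "LBP_DIM", "RAW_SIZE",
    "HogParams", "LbpParams", "AugmentationParams", "AugmentSample",
    "StainProfile", "NoStainWarning", "DescriptorSet",
    "stain_profile", "stain_normalize",
    "compute_raw", "compute_hog", "compute_lbp",
    "augment", "apply_augmentation", "featurize_store",
    "write_features", "read_features",
]


class NoStainWarning(UserWarning):
    """A patch carried no measurable stain; normalization was skipped."""


# -- stain normalization ----------------------------------------------------

@dataclass(frozen=True)
class StainProfile:
    """Reference H&E staining intensity: 99th-percentile optical-density
    concentration of the hematoxylin and eosin channels."""

    hematoxylin: float
    eosin: float


# Profile of a well-stained target; patches are rescaled in concentration
# space so their 99th percentiles match these values.
DEFAULT_REFERENCE = StainProfile(hematoxylin=0.25, eosin=0.20)

_OD_FLOOR = 0.02  # mean optical density below which a patch counts as unstained


def stain_profile(patch: np.ndarray) -> StainProfile:
    """Measure a patch's H&E concentration profile (99th percentiles)."""
    hed = rgb2hed(patch.astype(np.float64) / 255.0)
    return StainProfile(
        hematoxylin=float(np.percentile(hed[..., 0], 99)),
        eosin=float(np.percentile(hed[..., 1], 99)),
    )


def stain_normalize(patch: np.ndarray,
                    reference: StainProfile = DEFAULT_REFERENCE) -> np.ndarray:
    """Normalize a patch's color distribution to a reference stain profile.

    The RGB patch is deconvolved into H&E optical-density concentrations,
    each stain channel is rescaled so its 99th percentile matches the
    reference profile, and the result is recomposed to RGB.  A patch with
    essentially no optical density (blank glass) is returned unchanged
    with a :class:`NoStainWarning`.
    """
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("expected an RGB patch")
    rgb = patch.astype(np.float64) / 255.0
    od = -np.log10(np.clip(rgb, 1e-6, None))
    if float(od.mean()) < _OD_FLOOR:
        warnings.warn("patch carries no stain; returned unchanged", NoStainWarning)
        return patch.copy()
    hed = rgb2hed(rgb)
    own = stain_profile(patch)
    for channel, ref, cur in ((0, reference.hematoxylin, own.hematoxylin),
                              (1, reference.eosin, own.eosin)):
        if cur > 1e-6:
            hed[..., channel] *= ref / cur
    out = hed2rgb(hed)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


# -- RAW --------------------------------------------------------------------

def compute_raw(patch: np.ndarray) -> np.ndarray:
    """Bilinearly rescale to 40x40, scale to [0, 1], flatten (row-major,
    channel-last) -> 4800-vector."""
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("expected an RGB patch")
    img = patch.astype(np.float64)
    if patch.shape[:2] != (RAW_SIZE, RAW_SIZE):
        img = resize(img, (RAW_SIZE, RAW_SIZE), order=1,
                     anti_aliasing=False, preserve_range=True)
    return (img / 255.0).ravel().astype(np.float32)


def _grayscale(patch: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma in [0, 1]."""
    if patch.ndim == 2:
        return patch.astype(np.float64) / 255.0
    rgb = patch.astype(np.float64) / 255.0
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


# -- HOG --------------------------------------------------------------------

@dataclass(frozen=True)
class HogParams:
    """HOG geometry; the defaults give floor(40/14)^2 cells x 16 bins = 64."""

    orientations: int = 16
    pixels_per_cell: tuple[int, int] = (14, 14)
    cells_per_block: tuple[int, int] = (1, 1)
    input_size: int = RAW_SIZE


def compute_hog(patch: np.ndarray, params: HogParams = HogParams()) -> np.ndarray:
    """Histogram of oriented gradients of the downscaled grayscale patch.

    Central-difference gradients, unsigned orientation in [0, 180), hard
    assignment into ``orientations`` bins weighted by gradient magnitude,
    cellwise histograms over the top-left complete cell grid, and L2
    normalization per (single-cell) block.  Constant images yield the zero
    vector.
    """
    gray = _grayscale(patch)
    if gray.shape != (params.input_size, params.input_size):
        gray = resize(gray, (params.input_size, params.input_size), order=1,
                      anti_aliasing=False, preserve_range=True)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ang = np.rad2deg(np.arctan2(gy, gx)) % 180.0

    cy, cx = params.pixels_per_cell
    ncy = gray.shape[0] // cy
    ncx = gray.shape[1] // cx
    nbins = params.orientations
    bin_idx = np.minimum((ang / (180.0 / nbins)).astype(int), nbins - 1)

    features = []
    for i in range(ncy):
        for j in range(ncx):
            sl = np.s_[i * cy:(i + 1) * cy, j * cx:(j + 1) * cx]
            hist = np.bincount(bin_idx[sl].ravel(), weights=mag[sl].ravel(),
                               minlength=nbins)
            norm = np.sqrt((hist ** 2).sum())
            features.append(hist / norm if norm > 1e-12 else hist)
    return np.concatenate(features).astype(np.float32)


# -- LBP --------------------------------------------------------------------

@dataclass(frozen=True)
class LbpParams:
    """Uniform LBP settings; code values lie in [0, n_points + 1]."""

    n_points: int = 16
    radius: float = 2.0
    method: str = "uniform"
    code_image_size: int = 16
    output_dim: int = LBP_DIM


def compute_lbp(patch: np.ndarray, params: LbpParams = LbpParams()) -> np.ndarray:
    """Uniform LBP code image, resized to 16x16 and trimmed to 254 entries.

    Codes are rotation-invariant uniform patterns (bilinear-interpolated
    circular neighbors): patterns with at most two 0/1 transitions map to
    their popcount, all others to ``n_points + 1``.  The code image is
    resized with nearest-neighbor interpolation so code values stay exact,
    then flattened; the last two entries are dropped to match the dense
    encoder dimension downstream.
    """
    gray = np.round(_grayscale(patch) * 255.0).astype(np.uint8)
    codes = local_binary_pattern(gray, params.n_points, params.radius,
                                 method=params.method)
    # border pixels sample neighbors outside the image; drop that ring
    r = int(np.ceil(params.radius))
    if min(codes.shape) > 2 * r + 1:
        codes = codes[r:-r, r:-r]
    side = params.code_image_size
    if codes.shape != (side, side):
        codes = resize(codes, (side, side), order=0,
                       anti_aliasing=False, preserve_range=True)
    return codes.ravel()[:params.output_dim].astype(np.float32)


# -- augmentation -----------------------------------------------------------

@dataclass
class AugmentationParams:
    """Stochastic augmentation ranges mimicking how slides are examined
    under varying orientation, focus and staining conditions.

    ``multiplier`` is the number of independently sampled augmented copies
    produced per patch by :func:`augment`.
    """

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_range: float = 90.0
    right_angle_rotation: bool = True
    shift_fraction: float = 0.1
    brightness_range: tuple[float, float] = (0.8, 1.2)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    blur_sigma_max: float = 1.0
    multiplier: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        for lo, hi in (self.brightness_range, self.zoom_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError("ranges must be finite with lo <= hi")


@dataclass(frozen=True)
class AugmentSample:
    """One concrete sampled transform (identity by default)."""

    hflip: bool = False
    vflip: bool = False
    rotation: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)   # (dy, dx) as fraction of size
    brightness: float = 1.0
    zoom: float = 1.0
    blur_sigma: float = 0.0


def _sample_transform(params: AugmentationParams,
                      rng: np.random.Generator) -> AugmentSample:
    rot = 0.0
    if params.rotation_range > 0:
        if params.right_angle_rotation:
            steps = int(params.rotation_range // 90)
            rot = 90.0 * rng.integers(-steps, steps + 1)
        else:
            rot = float(rng.uniform(-params.rotation_range, params.rotation_range))
    return AugmentSample(
        hflip=bool(params.horizontal_flip and rng.random() < 0.5),
        vflip=bool(params.vertical_flip and rng.random() < 0.5),
        rotation=rot,
        shift=(float(rng.uniform(-params.shift_fraction, params.shift_fraction)),
               float(rng.uniform(-params.shift_fraction, params.shift_fraction))),
        brightness=float(rng.uniform(*params.brightness_range)),
        zoom=float(rng.uniform(*params.zoom_range)),
        blur_sigma=float(rng.uniform(0.0, params.blur_sigma_max)),
    )


def apply_augmentation(patch: np.ndarray, sample: AugmentSample) -> np.ndarray:
    """Apply one concrete transform to an RGB patch (uint8 in, uint8 out)."""
    img = patch.astype(np.float64)
    size = img.shape[0]
    if sample.hflip:
        img = img[:, ::-1]
    if sample.vflip:
        img = img[::-1, :]
    rot = sample.rotation % 360.0
    if rot:
        if rot % 90 == 0:
            img = np.rot90(img, k=int(rot // 90))
        else:
            img = rotate(img, rot, mode="reflect", preserve_range=True)
    dy, dx = sample.shift
    if dy or dx:
        img = ndi.shift(img, (dy * size, dx * size, 0), order=1, mode="reflect")
    if sample.zoom != 1.0:
        zoomed = rescale(img, sample.zoom, order=1, mode="reflect",
                         channel_axis=-1, anti_aliasing=False,
                         preserve_range=True)
        img = _center_crop_or_pad(zoomed, size)
    if sample.blur_sigma > 1e-3:
        img = gaussian(img, sigma=sample.blur_sigma, channel_axis=-1,
                       preserve_range=True)
    if sample.brightness != 1.0:
        img = img * sample.brightness
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _center_crop_or_pad(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h >= size:
        top = (h - size) // 2
        left = (w - size) // 2
        return img[top:top + size, left:left + size]
    pad_h = size - h
    pad_w = size - w
    return np.pad(img, ((pad_h // 2, pad_h - pad_h // 2),
                        (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
                  mode="reflect")


def augment(patch: np.ndarray, params: AugmentationParams) -> list[np.ndarray]:
    """``params.multiplier`` independently sampled augmented copies."""
    rng = np.random.default_rng(params.seed)
    return [apply_augmentation(patch, _sample_transform(params, rng))
            for _ in range(params.multiplier)]


# -- featurization ----------------------------------------------------------

@dataclass
class DescriptorSet:
    """Aligned descriptor matrices for a patch set.

    ``source_index[i]`` is the row of the originating patch in the input
    store, so augmented records trace back to their source (and keep its
    label).
    """

    raw: np.ndarray        # (N, 4800) float32
    hog: np.ndarray        # (N, 64)   float32
    lbp: np.ndarray        # (N, 254)  float32
    labels: np.ndarray     # (N,) int16
    source_index: np.ndarray
    params_json: str = "{}"

    def __len__(self) -> int:
        return len(self.labels)

    def by_name(self, name: str) -> np.ndarray:
        return {"raw": self.raw, "hog": self.hog, "lbp": self.lbp}[name]

    def subset(self, idx: np.ndarray) -> "DescriptorSet":
        return DescriptorSet(self.raw[idx], self.hog[idx], self.lbp[idx],
                             self.labels[idx], self.source_index[idx],
                             self.params_json)


def _triplet(patch: np.ndarray, hog_params: HogParams,
             lbp_params: LbpParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (compute_raw(patch), compute_hog(patch, hog_params),
            compute_lbp(patch, lbp_params))


def featurize_store(store: PatchStore,
                    augmentation: AugmentationParams | None = None,
                    reference: StainProfile = DEFAULT_REFERENCE,
                    hog_params: HogParams = HogParams(),
                    lbp_params: LbpParams = LbpParams(),
                    normalize_stain: bool = True) -> DescriptorSet:
    """Featurize every patch; optionally expand with augmented copies.

    With augmentation, each patch contributes ``multiplier`` records in
    total: the original plus ``multiplier - 1`` augmented copies, all
    carrying the source patch's label.  Augmentation is meant for the
    training split only; descriptors of augmented records are recomputed
    from the transformed pixels.
    """
    if len(store) == 0:
        raise ValueError("cannot featurize an empty patch store")
    if augmentation is not None and augmentation.multiplier < 1:
        raise ValueError("featurization multiplier must be >= 1")
    rng = (np.random.default_rng(augmentation.seed)
           if augmentation is not None else None)
    raws, hogs, lbps, labels, sources = [], [], [], [], []
    for i in range(len(store)):
        patch = store.patches[i]
        if normalize_stain:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NoStainWarning)
                patch = stain_normalize(patch, reference)
        try:
            copies = [patch]
            if augmentation is not None:
                copies += [apply_augmentation(patch, _sample_transform(augmentation, rng))
                           for _ in range(augmentation.multiplier - 1)]
            for img in copies:
                r, h, l = _triplet(img, hog_params, lbp_params)
                raws.append(r)
                hogs.append(h)
                lbps.append(l)
                labels.append(store.labels[i])
                sources.append(i)
        except Exception as exc:  # re-raise with patch provenance
            raise RuntimeError(
                f"descriptor failure on patch {i} "
                f"(slide {store.slide_ids[i]!r}, coords {store.coords[i].tolist()})"
            ) from exc
    params_json = json.dumps({
        "hog": asdict(hog_params), "lbp": asdict(lbp_params),
        "stain_reference": asdict(reference),
        "augmentation": asdict(augmentation) if augmentation else None,
    })
    return DescriptorSet(
        raw=np.stack(raws), hog=np.stack(hogs), lbp=np.stack(lbps),
        labels=np.asarray(labels, np.int16),
        source_index=np.asarray(sources, np.int64),
        params_json=params_json,
    )


def write_features(features: DescriptorSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=features.raw)
        f.create_dataset("hog", data=features.hog)
        f.create_dataset("lbp", data=features.lbp)
        f.create_dataset("labels", data=features.labels)
        f.create_dataset("source_index", data=features.source_index)
        f.attrs["descriptor_params_json"] = features.params_json


def read_features(path) -> DescriptorSet:
    import h5py

    with h5py.File(path, "r") as f:
        return DescriptorSet(
            raw=f["raw"][...], hog=f["hog"][...], lbp=f["lbp"][...],
            labels=f["labels"][...], source_index=f["source_index"][...],
            params_json=str(f.attrs["descriptor_params_json"]),
        )
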