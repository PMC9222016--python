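"""Whole-slide preprocessing: tissue segmentation, patch extraction, storage.

A slide is held as a :class:`SlideImage` — a multi-resolution RGB pyramid
with an openslide-like coordinate convention (regions are addressed by
level-0 top-left coordinates).  Plain RGB images (PNG/TIFF) are accepted as
slides; a power-of-two pyramid is derived from the base image so that
segmentation can run at a coarse downsample without external pyramid
metadata.

Tissue is segmented in HSV space: the saturation channel is median-blurred,
thresholded (Otsu by default), morphologically closed, and the resulting
components are filtered by area.  Patches of 224x224 px are then tiled over
the foreground contours at a requested magnification and persisted to HDF5
together with coordinates, labels, and the segmentation-parameter manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing, footprint_rectangle
from skimage.transform import resize

PATCH_SIZE = 224
SCHEMA_VERSION = "1"

__all__ = [
    "PATCH_SIZE",
    "SCHEMA_VERSION",
    "SlideImage",
    "SegmentationParams",
    "TissueMask",
    "PatchStore",
    "StoreSchemaError",
    "segment_tissue",
    "extract_patches",
    "write_store",
    "read_store",
    "balance_classes",
]


class StoreSchemaError(RuntimeError):
    """Raised when an HDF5 patch store has an unexpected schema version."""


class SlideImage:
    """Multi-resolution RGB slide with a level-0 coordinate frame.

    Parameters
    ----------
    level0:
        ``(H, W, 3)`` uint8 RGB array at full resolution.
    slide_id:
        Identifier recorded with every patch extracted from this slide.
    objective_magnification:
        Nominal objective power of the base level (e.g. 20x).
    max_levels:
        Pyramid depth cap; levels halve in resolution until the smaller
        dimension would drop below 32 px.
    """

    def __init__(self, level0: np.ndarray, slide_id: str = "slide",
                 objective_magnification: float = 20.0, max_levels: int = 8):
        level0 = np.asarray(level0)
        if level0.ndim != 3 or level0.shape[2] != 3:
            raise ValueError("slide must be an (H, W, 3) RGB array")
        if level0.dtype != np.uint8:
            raise ValueError("slide must be uint8")
        self.slide_id = slide_id
        self.objective_magnification = float(objective_magnification)
        self._levels = [level0]
        while len(self._levels) < max_levels:
            prev = self._levels[-1]
            h, w = prev.shape[:2]
            if min(h, w) // 2 < 32:
                break
            hh, ww = (h // 2) * 2, (w // 2) * 2
            blocks = prev[:hh, :ww].reshape(h // 2, 2, w // 2, 2, 3).astype(np.float32)
            self._levels.append(
                np.round(blocks.mean(axis=(1, 3))).astype(np.uint8))

    # -- pyramid geometry ---------------------------------------------------
    @property
    def level_count(self) -> int:
        return len(self._levels)

    @property
    def level_downsamples(self) -> list[float]:
        return [float(2 ** i) for i in range(self.level_count)]

    @property
    def level_dimensions(self) -> list[tuple[int, int]]:
        """Per-level (width, height)."""
        return [(a.shape[1], a.shape[0]) for a in self._levels]

    @property
    def dimensions(self) -> tuple[int, int]:
        return self.level_dimensions[0]

    def best_level_for_downsample(self, downsample: float) -> int:
        """Finest level whose downsample does not exceed ``downsample``."""
        if downsample < 1:
            raise ValueError("downsample must be >= 1")
        best = 0
        for i, ds in enumerate(self.level_downsamples):
            if ds <= downsample:
                best = i
        return best

    def read_region(self, location: tuple[int, int], level: int,
                    size: tuple[int, int]) -> np.ndarray:
        """Read an RGB region.

        ``location`` is the (x, y) top-left corner in the *level-0* frame;
        ``size`` is (width, height) in pixels of the requested *level*.
        """
        if not 0 <= level < self.level_count:
            raise ValueError(f"level {level} not in [0, {self.level_count})")
        x0, y0 = location
        w, h = size
        ds = self.level_downsamples[level]
        lx, ly = int(round(x0 / ds)), int(round(y0 / ds))
        arr = self._levels[level]
        if lx < 0 or ly < 0 or lx + w > arr.shape[1] or ly + h > arr.shape[0]:
            raise ValueError(
                f"region {(x0, y0)}+{(w, h)} at level {level} out of bounds "
                f"{self.level_dimensions[level]}")
        return arr[ly:ly + h, lx:lx + w].copy()

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_file(cls, path, slide_id: str | None = None,
                  objective_magnification: float = 20.0) -> "SlideImage":
        path = Path(path)
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        return cls(arr.astype(np.uint8), slide_id=slide_id or path.stem,
                   objective_magnification=objective_magnification)

    def to_file(self, path) -> None:
        iio.imwrite(Path(path), self._levels[0])


@dataclass
class SegmentationParams:
    """Tissue-segmentation settings.

    ``sat_threshold`` is either the string ``"otsu"`` or a fixed saturation
    cut in [0, 1].  ``otsu_floor`` guards Otsu against stain-free slides
    whose saturation channel is pure sensor noise: the effective threshold
    is ``max(otsu, otsu_floor)``.  Areas are in px^2 at the segment level.
    """

    seg_downsample: int = 64
    sat_threshold: str | float = "otsu"
    median_kernel: int = 7
    closing_kernel: int = 4
    min_contour_area: float = 64.0
    otsu_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.closing_kernel < 1:
            raise ValueError("closing_kernel must be >= 1")
        if self.min_contour_area < 0:
            raise ValueError("min_contour_area must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class TissueMask:
    """Binary tissue mask at the segment level plus its foreground contours.

    ``contours`` are closed polygons in (x, y) segment-level coordinates,
    one per retained connected component.  ``prefilter_mask`` retains the
    components that were dropped by the area filter.
    """

    mask: np.ndarray
    prefilter_mask: np.ndarray
    contours: list[np.ndarray]
    params: SegmentationParams
    level: int
    downsample: float

    @property
    def n_regions(self) -> int:
        return len(self.contours)


def segment_tissue(slide: SlideImage, params: SegmentationParams | None = None) -> TissueMask:
    """Segment stained tissue from the slide background.

    Pipeline: read a coarse level -> HSV -> median-blur the saturation
    channel -> threshold (Otsu or fixed) -> morphological closing ->
    connected components -> drop components below ``min_contour_area``.
    """
    params = params or SegmentationParams()
    level = slide.best_level_for_downsample(params.seg_downsample)
    ds = slide.level_downsamples[level]
    img = slide.read_region((0, 0), level, slide.level_dimensions[level])
    sat = rgb2hsv(img)[..., 1]
    k = params.median_kernel
    sat = ndi.median_filter(sat, size=k)
    if params.sat_threshold == "otsu":
        if float(sat.max() - sat.min()) < 1e-6:
            thr = np.inf  # constant saturation: nothing to segment
        else:
            thr = max(float(threshold_otsu(sat)), params.otsu_floor)
    else:
        thr = float(params.sat_threshold)
    raw_mask = sat > thr
    raw_mask = closing(raw_mask, footprint_rectangle(
        (params.closing_kernel, params.closing_kernel)))

    labeled, n = ndi.label(raw_mask)
    mask = np.zeros_like(raw_mask)
    for region in measure.regionprops(labeled):
        if region.area >= params.min_contour_area:
            mask[labeled == region.label] = True

    contours = _mask_contours(mask)
    return TissueMask(mask=mask, prefilter_mask=raw_mask, contours=contours,
                      params=params, level=level, downsample=ds)


def _mask_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Closed (x, y) polygons around each foreground component."""
    padded = np.pad(mask.astype(float), 1)
    polys = measure.find_contours(padded, 0.5)
    out = []
    for poly in polys:
        xy = poly[:, ::-1] - 1.0  # (row, col) -> (x, y), undo pad
        out.append(xy)
    return out


@dataclass
class PatchStore:
    """Labeled 224x224 RGB patches with provenance.

    ``coords`` are 0-based level-0 top-left corners.  ``manifest`` carries
    the segmentation parameters and the list of slides that produced the
    records, and is persisted both inside the HDF5 file and as a sibling
    human-readable JSON file.
    """

    patches: np.ndarray                    # (N, 224, 224, 3) uint8
    coords: np.ndarray                     # (N, 2) int64
    labels: np.ndarray                     # (N,) int16
    slide_ids: np.ndarray                  # (N,) unicode
    magnification: float
    class_names: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        n = len(self.patches)
        if self.patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 3) and n > 0:
            raise ValueError(f"patches must be (N, {PATCH_SIZE}, {PATCH_SIZE}, 3)")
        if len(self.coords) != n or len(self.labels) != n or len(self.slide_ids) != n:
            raise ValueError("patches/coords/labels/slide_ids lengths differ")

    def __len__(self) -> int:
        return len(self.patches)

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}

    def subset(self, indices: np.ndarray) -> "PatchStore":
        indices = np.asarray(indices)
        return PatchStore(
            patches=self.patches[indices],
            coords=self.coords[indices],
            labels=self.labels[indices],
            slide_ids=self.slide_ids[indices],
            magnification=self.magnification,
            class_names=list(self.class_names),
            manifest=dict(self.manifest),
        )

    @staticmethod
    def empty(magnification: float = 20.0, class_names: Sequence[str] = (),
              manifest: dict | None = None) -> "PatchStore":
        return PatchStore(
            patches=np.zeros((0, PATCH_SIZE, PATCH_SIZE, 3), np.uint8),
            coords=np.zeros((0, 2), np.int64),
            labels=np.zeros(0, np.int16),
            slide_ids=np.array([], dtype="U64"),
            magnification=magnification,
            class_names=list(class_names),
            manifest=manifest or {},
        )

    @staticmethod
    def concatenate(stores: Sequence["PatchStore"]) -> "PatchStore":
        stores = [s for s in stores]
        if not stores:
            raise ValueError("nothing to concatenate")
        names = max((s.class_names for s in stores), key=len)
        manifest: dict = {"slides": []}
        for s in stores:
            manifest["slides"].extend(s.manifest.get("slides", []))
            if "segmentation" in s.manifest:
                manifest["segmentation"] = s.manifest["segmentation"]
        return PatchStore(
            patches=np.concatenate([s.patches for s in stores]),
            coords=np.concatenate([s.coords for s in stores]),
            labels=np.concatenate([s.labels for s in stores]),
            slide_ids=np.concatenate([s.slide_ids.astype("U64") for s in stores]),
            magnification=stores[0].magnification,
            class_names=list(names),
            manifest=manifest,
        )


LabelMap = int | Mapping[int, int] | Callable[[float, float], int]


def extract_patches(slide: SlideImage, mask: TissueMask, magnification: float,
                    labels: LabelMap, class_names: Sequence[str] = (),
                    patch_size: int = PATCH_SIZE) -> PatchStore:
    """Tile non-overlapping ``patch_size`` patches over the tissue contours.

    A non-overlapping grid is laid over each contour's bounding box at the
    target magnification; a tile is kept iff its center, scaled to the
    segment level, falls inside the (area-filtered) foreground mask.
    ``labels`` is a slide-level class index, a mapping from contour index
    to class, or a callable ``(center_x, center_y) -> class`` in level-0
    coordinates.
    """
    native = slide.objective_magnification
    if magnification > native + 1e-9:
        raise ValueError(
            f"requested magnification {magnification}x exceeds native {native}x")
    ds_t = native / magnification  # level-0 px per output px
    stride0 = patch_size * ds_t
    seg_ds = mask.downsample
    manifest = {
        "slides": [{"slide_id": slide.slide_id,
                    "magnification": magnification,
                    "segmentation": json.loads(mask.params.to_json())}],
        "segmentation": json.loads(mask.params.to_json()),
    }
    if mask.n_regions == 0:
        warnings.warn(f"slide {slide.slide_id}: empty tissue mask, no patches")
        return PatchStore.empty(magnification, class_names, manifest)

    level = slide.best_level_for_downsample(ds_t)
    level_ds = slide.level_downsamples[level]
    w0, h0 = slide.dimensions

    out_patches, out_coords, out_labels = [], [], []
    for ci, contour in enumerate(mask.contours):
        xs, ys = contour[:, 0], contour[:, 1]
        bx0 = max(0.0, xs.min() * seg_ds)
        by0 = max(0.0, ys.min() * seg_ds)
        bx1 = min(float(w0), (xs.max() + 1) * seg_ds)
        by1 = min(float(h0), (ys.max() + 1) * seg_ds)
        nx = int((bx1 - bx0) // stride0)
        ny = int((by1 - by0) // stride0)
        for iy in range(ny):
            for ix in range(nx):
                x0 = bx0 + ix * stride0
                y0 = by0 + iy * stride0
                cx = x0 + stride0 / 2
                cy = y0 + stride0 / 2
                mi = int(cy / seg_ds)
                mj = int(cx / seg_ds)
                if not (0 <= mi < mask.mask.shape[0] and 0 <= mj < mask.mask.shape[1]):
                    continue
                if not mask.mask[mi, mj]:
                    continue
                xi, yi = int(round(x0)), int(round(y0))
                if xi + stride0 > w0 or yi + stride0 > h0:
                    continue
                wl = int(round(patch_size * ds_t / level_ds))
                region = slide.read_region((xi, yi), level, (wl, wl))
                if region.shape[:2] != (patch_size, patch_size):
                    region = np.round(resize(
                        region.astype(np.float64), (patch_size, patch_size),
                        order=1, anti_aliasing=False, preserve_range=True,
                    )).astype(np.uint8)
                out_patches.append(region)
                out_coords.append((xi, yi))
                out_labels.append(_resolve_label(labels, ci, cx, cy))

    if not out_patches:
        warnings.warn(f"slide {slide.slide_id}: mask has tissue but no full tile fits")
        return PatchStore.empty(magnification, class_names, manifest)
    return PatchStore(
        patches=np.stack(out_patches).astype(np.uint8),
        coords=np.asarray(out_coords, np.int64),
        labels=np.asarray(out_labels, np.int16),
        slide_ids=np.array([slide.slide_id] * len(out_patches), dtype="U64"),
        magnification=magnification,
        class_names=list(class_names),
        manifest=manifest,
    )


def _resolve_label(labels: LabelMap, contour_index: int, cx: float, cy: float) -> int:
    if callable(labels):
        return int(labels(cx, cy))
    if isinstance(labels, Mapping):
        return int(labels[contour_index])
    return int(labels)


# -- HDF5 persistence -------------------------------------------------------

def write_store(store: PatchStore, path) -> Path:
    """Write a patch store to HDF5 plus a sibling JSON manifest file."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=store.patches, dtype=np.uint8)
        f.create_dataset("coords", data=store.coords, dtype=np.int64)
        f.create_dataset("labels", data=store.labels, dtype=np.int16)
        f.create_dataset("slide_ids", data=store.slide_ids.astype(object),
                         dtype=h5py.string_dtype())
        f.attrs["slide_id"] = ";".join(sorted(set(store.slide_ids.tolist())))
        f.attrs["magnification"] = store.magnification
        f.attrs["class_names"] = json.dumps(store.class_names)
        f.attrs["seg_params_json"] = json.dumps(store.manifest.get("segmentation", {}))
        f.attrs["manifest_json"] = json.dumps(store.manifest)
        f.attrs["schema_version"] = store.schema_version
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(
        {"schema_version": store.schema_version,
         "n_patches": len(store),
         "class_counts": {str(k): v for k, v in store.class_counts().items()},
         **store.manifest}, indent=2))
    return path


def read_store(path) -> PatchStore:
    import h5py

    with h5py.File(path, "r") as f:
        version = str(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise StoreSchemaError(
                f"patch store schema mismatch: expected {SCHEMA_VERSION!r}, "
                f"found {version!r}")
        slide_ids = np.array([s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["slide_ids"][...]], dtype="U64")
        return PatchStore(
            patches=f["patches"][...],
            coords=f["coords"][...],
            labels=f["labels"][...],
            slide_ids=slide_ids,
            magnification=float(f.attrs["magnification"]),
            class_names=json.loads(f.attrs["class_names"]),
            manifest=json.loads(f.attrs["manifest_json"]),
            schema_version=version,
        )


def balance_classes(store: PatchStore, targets: Mapping[int, int],
                    seed: int) -> PatchStore:
    """Uniform random per-class subsample without replacement.

    Classes absent from ``targets`` are kept in full.  Requesting more
    records than a class holds is an error naming the class.
    """
    rng = np.random.default_rng(seed)
    counts = store.class_counts()
    keep: list[np.ndarray] = []
    for label in sorted(counts):
        idx = np.flatnonzero(store.labels == label)
        if label in targets:
            target = int(targets[label])
            if target > len(idx):
                name = (store.class_names[label]
                        if label < len(store.class_names) else str(label))
                raise ValueError(
                    f"class {name!r}: requested {target} > available {len(idx)}")
            idx = np.sort(rng.choice(idx, size=target, replace=False))
        keep.append(idx)
    return store.subset(np.concatenate(keep) if keep else np.zeros(0, int))
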