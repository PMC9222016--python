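"""Synthetic slides and labeled patch sets for end-to-end testing.

The generator emulates the two kinds of input the pipeline consumes:

* **Slides** — large, near-white RGB images containing H&E-like stained
  blobs, emitted together with the exact binary blob mask so that the
  tissue-segmentation stage can be checked against ground truth.
* **Labeled patches** — 224x224 RGB patches whose classes differ in
  procedural texture channels, each chosen to map onto one descriptor
  family: sinusoidal stripe *orientation* (picked up by HOG), speckle
  *grain size* plus nucleus-like spot density (picked up by LBP), and the
  base *stain hue* (picked up by the downscaled RAW image).  No single
  channel identifies the class on its own: hue is shared between pairs of
  classes and stripe orientation repeats across the pairs, so fusing
  descriptors is genuinely required for full separation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk

from .preprocess import PATCH_SIZE, PatchStore, SlideImage

# H&E-like default stain colors (pink/purple) so saturation thresholding
# behaves as it does on real slides.
HE_PINK = (199, 128, 165)
HE_PURPLE = (130, 94, 170)
BACKGROUND = (244, 242, 243)

__all__ = [
    "SyntheticSlideSpec",
    "SyntheticPatchSpec",
    "PatchClassParams",
    "make_slide",
    "make_patch_dataset",
    "make_labeled_slide",
    "default_class_params",
    "render_texture",
]


@dataclass
class SyntheticSlideSpec:
    """A mostly-white slide containing circular stained-tissue blobs.

    ``blobs`` is a list of ``((cx, cy), radius, rgb_color)`` tuples in
    level-0 pixel coordinates.  An empty list is allowed and produces an
    all-background slide with an empty mask.
    """

    width: int = 2048
    height: int = 2048
    blobs: list[tuple[tuple[float, float], float, tuple[int, int, int]]] = field(
        default_factory=list)
    background_color: tuple[int, int, int] = BACKGROUND
    noise_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1024 or self.height < 1024:
            raise ValueError("slide must be at least 1024x1024 px")
        for _, radius, color in self.blobs:
            if radius <= 0:
                raise ValueError("blob radii must be > 0")
            if not all(0 <= c <= 255 for c in color):
                raise ValueError("blob colors must be in [0, 255]^3")


def make_slide(spec: SyntheticSlideSpec) -> tuple[SlideImage, np.ndarray]:
    """Render the slide and return it with its ground-truth tissue mask."""
    rng = np.random.default_rng(spec.seed)
    img = np.empty((spec.height, spec.width, 3), np.float32)
    img[...] = np.asarray(spec.background_color, np.float32)
    mask = np.zeros((spec.height, spec.width), bool)
    for (cx, cy), radius, color in spec.blobs:
        rr, cc = disk((cy, cx), radius, shape=mask.shape)
        mask[rr, cc] = True
        img[rr, cc] = np.asarray(color, np.float32)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape).astype(np.float32)
    slide = SlideImage(np.clip(np.round(img), 0, 255).astype(np.uint8),
                       slide_id=f"synthetic-{spec.seed}")
    return slide, mask


@dataclass
class PatchClassParams:
    """Procedural texture of one synthetic class.

    stripe_orientation : degrees of the sinusoidal stripe pattern
    spot_density : expected dark nucleus-like spots per 100x100 px
    base_color : H&E-like stain color of the tissue background
    grain_sigma : correlation length (px) of the multiplicative speckle
        texture — fine vs coarse grain, the channel LBP is sensitive to
    """

    stripe_orientation: float
    spot_density: float
    base_color: tuple[int, int, int]
    stripe_period: float = 28.0
    stripe_amplitude: float = 26.0
    spot_radius: float = 5.0
    grain_sigma: float = 1.0
    grain_amplitude: float = 10.0
    name: str = ""


def default_class_params(n_classes: int) -> list[PatchClassParams]:
    """Class definitions with complementary descriptor signal.

    Hue distinguishes only *pairs* of classes (pink vs purple), stripe
    orientation distinguishes classes within a pair, and speckle grain /
    spot density vary over all classes — so RAW, HOG and LBP each carry
    partial, complementary information.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    orientations = [0.0, 90.0, 45.0]
    densities = [1.0, 6.0, 12.0, 3.0, 9.0]
    grains = [0.6, 2.5, 1.2, 4.0, 2.0]
    out = []
    for c in range(n_classes):
        color = HE_PINK if c < (n_classes + 1) // 2 else HE_PURPLE
        out.append(PatchClassParams(
            # orientation repeats across the two hue groups, so neither
            # hue (RAW) nor orientation (HOG) alone identifies the class
            stripe_orientation=orientations[c % 2 if n_classes <= 4 else c % 3],
            spot_density=densities[c % len(densities)],
            grain_sigma=grains[c % len(grains)],
            base_color=color,
            name=f"class{c}",
        ))
    return out


@dataclass
class SyntheticPatchSpec:
    """A labeled patch dataset with ``n_classes`` procedural textures.

    ``slides_per_class`` pseudo-slide identifiers are assigned round-robin
    within each class so that grouped (per-slide) train/test splitting is
    exercised on synthetic data.
    """

    n_classes: int = 4
    patches_per_class: int = 100
    patch_size: int = PATCH_SIZE
    slides_per_class: int = 5
    class_params: list[PatchClassParams] | None = None
    orientation_jitter: float = 8.0
    color_jitter: float = 10.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 28:
            raise ValueError("patch_size < 28 px: HOG cell geometry infeasible")
        if self.patches_per_class < 1:
            raise ValueError("patches_per_class must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def resolved_class_params(self) -> list[PatchClassParams]:
        if self.class_params is not None:
            if len(self.class_params) != self.n_classes:
                raise ValueError("class_params length must equal n_classes")
            return self.class_params
        return default_class_params(self.n_classes)


def render_texture(params: PatchClassParams, size: int,
                   rng: np.random.Generator, orientation_jitter: float = 0.0,
                   color_jitter: float = 0.0, noise_sigma: float = 0.0) -> np.ndarray:
    """Render one textured RGB tile for a class: stripes + spots + noise."""
    base = np.asarray(params.base_color, np.float32)
    if color_jitter > 0:
        base = base + rng.normal(0.0, color_jitter, 3).astype(np.float32)
    img = np.empty((size, size, 3), np.float32)
    img[...] = base

    theta = np.deg2rad(params.stripe_orientation
                       + rng.normal(0.0, orientation_jitter))
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * (np.cos(theta) * xx + np.sin(theta) * yy)
                  / params.stripe_period + phase)
    img += (params.stripe_amplitude * wave)[..., None]

    n_spots = rng.poisson(params.spot_density * (size / 100.0) ** 2)
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, size, 2)
        rr, cc = disk((cy, cx), params.spot_radius, shape=(size, size))
        img[rr, cc] *= 0.45  # dark nucleus-like dots

    if params.grain_amplitude > 0:
        grain = rng.normal(0.0, 1.0, (size, size))
        if params.grain_sigma > 0:
            grain = ndi.gaussian_filter(grain, params.grain_sigma)
            grain /= max(grain.std(), 1e-9)
        img += (params.grain_amplitude * grain[..., None]).astype(np.float32)

    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, img.shape).astype(np.float32)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_patch_dataset(spec: SyntheticPatchSpec) -> PatchStore:
    """Generate the labeled synthetic patch store described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    class_params = spec.resolved_class_params()
    patches, labels, slide_ids = [], [], []
    for c, params in enumerate(class_params):
        for i in range(spec.patches_per_class):
            patches.append(render_texture(
                params, spec.patch_size, rng,
                orientation_jitter=spec.orientation_jitter,
                color_jitter=spec.color_jitter,
                noise_sigma=spec.noise_sigma))
            labels.append(c)
            slide_ids.append(f"synth-c{c}-s{i % spec.slides_per_class}")
    return PatchStore(
        patches=np.stack(patches),
        coords=np.zeros((len(patches), 2), np.int64),
        labels=np.asarray(labels, np.int16),
        slide_ids=np.asarray(slide_ids, dtype="U64"),
        magnification=20.0,
        class_names=[p.name or f"class{c}" for c, p in enumerate(class_params)],
        manifest={"slides": sorted(set(slide_ids)), "generator": "synthetic"},
    )


def make_labeled_slide(class_params: PatchClassParams, *, width: int = 1344,
                       height: int = 1344, n_blobs: int = 2,
                       blob_radius: float = 420.0, seed: int = 0,
                       orientation_jitter: float = 8.0, color_jitter: float = 10.0,
                       noise_sigma: float = 2.0,
                       slide_id: str = "") -> tuple[SlideImage, np.ndarray]:
    """A slide whose blobs are filled with one class's texture.

    Used by the orchestration layer to drive the *whole* pipeline —
    segmentation, patching, featurization, training — from slide-level
    synthetic input with a single slide-level label.
    """
    rng = np.random.default_rng(seed)
    img = np.empty((height, width, 3), np.float32)
    img[...] = np.asarray(BACKGROUND, np.float32)
    img += rng.normal(0.0, 1.5, img.shape).astype(np.float32)
    mask = np.zeros((height, width), bool)
    for b in range(n_blobs):
        # independent texture realization per blob: within-slide diversity
        texture = render_texture(class_params, max(height, width), rng,
                                 orientation_jitter=orientation_jitter,
                                 color_jitter=color_jitter,
                                 noise_sigma=noise_sigma).astype(np.float32)
        margin = blob_radius * 1.05
        cx = rng.uniform(margin, width - margin)
        cy = rng.uniform(margin, height - margin)
        rr, cc = disk((cy, cx), blob_radius, shape=mask.shape)
        mask[rr, cc] = True
        img[rr, cc] = texture[rr, cc]
    slide = SlideImage(np.clip(np.round(img), 0, 255).astype(np.uint8),
                       slide_id=slide_id or f"labeled-{seed}")
    return slide, mask
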