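# Methods

## Model

`wsifuse` classifies whole-slide-image (WSI) patches by fusing
unsupervised representations of three image descriptors. For a patch
x, descriptor vectors d_i(x) are computed (i = RAW, HOG, LBP). Each
descriptor stream has its own autoencoder h_i = D_i ∘ E_i, trained by
backpropagation to minimize the reconstruction loss

    L = Σ_i ‖ h_i(d_i(x)) − d_i(x) ‖²,

averaged over the batch. The per-descriptor losses are independent, so
the sum is minimized by training each autoencoder separately. After
unsupervised training the decoders are discarded and the latents
d̃_i = E_i(d_i) are concatenated in fixed order (RAW, HOG, LBP) into
y(x); a dense softmax head is trained on y(x) with cross-entropy.
Encoders stay frozen while the head trains: the representation is
learned without labels, and the same latents can feed any downstream
classifier. (A fine-tuning path would be a one-line change but is
deliberately not the default, to keep the unsupervised/supervised
stages decoupled.)

Assumptions: descriptors are flat vectors (the autoencoders are MLPs,
not convolutional); a single hidden layer per autoencoder suffices when
its width is at input scale ("same") or twice it ("double"); class
information survives the 40×40 RAW downscale and the two texture
descriptors jointly.

## Descriptors

* **RAW** — bilinear resize to 40×40×3, values scaled to [0, 1],
  flattened row-major channel-last → 4800 floats. Carries
  color/holistic morphology.
* **HOG** — the 40×40 ITU-R 601 grayscale patch; central-difference
  gradients, unsigned orientation in [0°, 180°) hard-assigned to 16
  bins weighted by magnitude, cells of 14×14 px (so ⌊40/14⌋² = 4
  complete cells), single-cell blocks L2-normalized → 64 floats. The
  hard binning with a first-principles gradient makes the oracle test
  (an explicit-loop reimplementation, 1e-6 agreement) meaningful.
* **LBP** — rotation-invariant uniform local binary patterns with
  P = 16 circular neighbors at radius 2 (bilinearly interpolated),
  giving codes in [0, 17]. The border ring of width ⌈R⌉, whose
  neighbors fall outside the image, is cropped; the code image is
  resized to 16×16 with nearest-neighbor interpolation (codes are
  categorical — averaging them would be meaningless) and flattened,
  and the last two entries are dropped to give 254 features. 254 is
  deliberate: it makes the same-size dense encoder hold
  254 × 255 = 64,770 parameters and the fused width
  4800 + 64 + 254 = 5118, keeping the whole architecture's parameter
  table internally consistent.

Stain normalization precedes featurization: the RGB patch is
deconvolved into hematoxylin/eosin optical-density concentrations
(Ruifrok H&E matrix), each channel is rescaled so its 99th percentile
matches a stored reference profile, and the result is recomposed.
Normalizing a patch against its own profile is a near-identity (mean
absolute error below 2/255, the round-trip error of the
deconvolution), and patches with essentially no optical density (blank
glass) are passed through unchanged with a warning.

## Tissue segmentation and patching

Segmentation runs at a coarse pyramid level (default downsample 64 for
real slides; the synthetic configurations use 8 because fixture slides
are only ~2k px): HSV saturation → median blur (kernel 7) → threshold
(Otsu, floored at 0.05 so a stain-free slide cannot be split on sensor
noise; a fixed threshold can be configured) → morphological closing
(4×4 square) → connected components → area filter. Contours are traced
around the retained components; the pre-filter mask is kept so small
regions remain inspectable.

Patching tiles a non-overlapping 224×224 grid from each contour's
bounding-box origin at the requested magnification; a tile is kept iff
its center, scaled to the segment level, lies on the filtered mask.
Coordinates are 0-based level-0 top-left (the usual WSI convention).
At native magnification the stored pixels reproduce
`read_region(x, y, 224, 224)` exactly. Plain PNG/TIFF images are
accepted as slides; a power-of-two pyramid is derived in memory, so
fixtures need no pyramidal container. Patch stores are HDF5
(`patches`, `coords`, `labels`, `slide_ids` + attributes including the
serialized segmentation parameters and a schema version) with a
human-readable JSON manifest alongside.

## Training configuration

Reference defaults (the tuned values for the real cohorts): one hidden
layer per autoencoder, ReLU, 200 epochs, Adam, learning rate 1e-4,
batch 64, latent sizing "same" for multi-class work ("double" is the
binary-task variant); classifier 30 epochs, Adam 1e-4, batch 32
(binary: 128). Weight init is uniform Glorot from a seeded generator;
batch-norm momentum 0.9, eps 1e-5; all arithmetic float32.

The desk-scale synthetic study (`run_synthetic_benchmark`) uses 8
autoencoder epochs, 15 classifier epochs, Adam 1e-3 and batch 64 —
sized so the full study with all three single-descriptor ablations
completes in minutes on one CPU core. The synthetic classes are far
easier than real histology, so the shortened schedule trains to
convergence; the schedule is a runtime choice, not a tuning knob.

## Synthetic fixtures

The generator emulates two input kinds. *Slides*: near-white 2k-px
images with disk-shaped stained blobs (H&E-like pink/purple, so
saturation thresholding behaves as on glass), emitted with the exact
blob mask as a segmentation oracle. *Labeled patches*: four (or 2/5)
classes of procedural texture — sinusoidal stripes whose orientation
maps to HOG, multiplicative speckle whose grain size (Gaussian
correlation length) plus dark nucleus-like spots map to LBP, and an
H&E base hue that maps to RAW. The channels are deliberately
redundant-free: hue is shared within class pairs and stripe
orientation repeats across the pairs, so no single descriptor
separates all classes and fusion is genuinely required; per-patch
jitter (orientation ±8°, hue ±10, additive noise) keeps every channel
noisy. Grain size rather than spot density is the primary LBP channel
because the architecture's LBP descriptor is a subsampled code image,
which is nearly blind to sparse spot placement but strongly sensitive
to texture correlation length.

What passing on these fixtures shows: the pipeline's stages compose
correctly, the descriptors carry the signal they are designed for, the
autoencoders preserve class-relevant structure, and fusion helps when
information is complementary. What it does not show: performance on
real histology — no nuclei, glands, compression artifacts, scanner
variation, or annotation noise are modeled.

## Evaluation

Confusion matrices use rows = true, columns = predicted. Per class
(one-vs-rest): sensitivity TP/(TP+FN), precision TP/(TP+FP), F1
2TP/(2TP+FP+FN), and `precision_as_printed` TN/(TN+FP) — the
specificity formula, reported side by side because some reports print
it under the name "precision"; consumers choose explicitly. Scalar
summaries are unweighted macro averages; overall accuracy is
trace(cm)/N (identical to (TP+TN)/N in the binary case — a macro
average of one-vs-rest accuracies would overstate multi-class
accuracy). Zero denominators yield 0 with a per-metric flag rather
than NaN. ROC/AUC is one-vs-rest with trapezoidal integration (ties
handled by the standard joint-threshold traversal, equivalent to rank
averaging; verified against a pair-counting oracle); classes absent
from the truth are flagged and excluded from the macro average. The
2-D view of the learned representation is t-SNE with PCA
initialization and a fixed seed; it requires perplexity < N and at
least 5 samples.

## Splits and determinism

The default split is 80:20, grouped by slide: all patches of a slide
land on one side, stratified over each slide's majority class, with
`n_train = round(ratio · n_slides)` clamped so both sides are
non-empty. This mirrors patient-level separation; the record-level
split (used by the patch benchmark) applies the same rule per class to
records. Every stochastic component — generators, weight init, batch
shuffling, subsampling, t-SNE — draws from seeds derived from one
configuration seed, so a rerun of the same configuration reproduces
the metrics byte-for-byte. Pipeline artifacts are stamped with a hash
of the configuration and reused on rerun only when the hash matches.

## Numerical choices and degenerate inputs

Softmax and cross-entropy are computed in the usual max-shifted /
clipped forms; argmax ties resolve to the lowest class index. HOG cell
histograms with zero gradient energy normalize to the zero vector
(constant images yield all-zero HOG). Autoencoder training aborts on a
non-finite loss with a learning-rate hint. An empty tissue mask
produces an empty store with a warning, not an error; an empty store
refuses featurization. Requesting magnification above the slide's
native power, schema-version mismatches, and single-class training
sets are hard errors.

## Known limitations

* MLP autoencoders on flattened descriptors ignore spatial structure;
  the design trades representational power for a small, fully
  inspectable model.
* Pyramids are synthesized from single-level images; vendor pyramidal
  formats (e.g. SVS) are out of scope, and objective magnification
  must be supplied for plain images.
* The patch-labeling rule for regions spanning multiple annotation
  classes is a slide-level or per-contour label; polygon-level
  multi-class annotations are not modeled.
* Single-threaded CPU training bounds practical dataset size to the
  tens of thousands of patches.
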