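"""End-to-end orchestration: configuration, seeding, staging, artifacts.

A run proceeds through seven stages — synthesize (or ingest), segment,
patch, featurize, train the per-descriptor autoencoders, fuse latents and
train the classifier head, evaluate — writing every artifact under one
output directory together with a manifest that records the configuration
hash, per-stage status and timing.  Reruns with the same configuration
and seed are deterministic and resume from on-disk artifacts where the
hash matches.

Augmentation is applied to the training portion only; a configuration
that requests it on the test split is rejected at validation time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .classifier import (ClassifierConfig, predict, save_classifier,
                         train_classifier)
from .descriptors import (AugmentationParams, DescriptorSet, HogParams,
                          LbpParams, featurize_store, read_features,
                          write_features)
from .evaluation import confusion, metrics, roc_auc, project_embedding
from .preprocess import (PatchStore, SegmentationParams, extract_patches,
                         read_store, segment_tissue, write_store)
from .sae import (AEConfig, DESCRIPTOR_ORDER, encode, fuse, save_autoencoder,
                  train_autoencoder)

log = logging.getLogger("wsifuse")

STAGES = ("synthesize", "segment", "patch", "featurize",
          "train_autoencoders", "fuse_train_classifier", "evaluate")

__all__ = [
    "STAGES",
    "DatasetConfig",
    "PipelineConfig",
    "split_dataset",
    "run_pipeline",
    "run_descriptor_study",
    "run_synthetic_benchmark",
    "default_synthetic_config",
]


@dataclass
class DatasetConfig:
    """Input description: synthetic slides, synthetic patches, or files.

    ``synthetic-slides`` drives all seven stages (textured blob slides are
    segmented and patched); ``synthetic-patches`` starts from labeled
    patches, so the segment/patch stages are recorded as skipped.
    ``slide-files`` ingests RGB images listed in ``paths`` with per-file
    integer labels.
    """

    kind: str = "synthetic-slides"
    n_classes: int = 4
    slides_per_class: int = 2
    patches_per_class: int = 100
    slide_width: int = 1344
    slide_height: int = 1344
    blobs_per_slide: int = 2
    blob_radius: float = 420.0
    magnification: float = 20.0
    paths: list[str] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("synthetic-slides", "synthetic-patches", "slide-files"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")


@dataclass
class PipelineConfig:
    """Complete, serializable run description."""

    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(seg_downsample=8))
    hog: HogParams = field(default_factory=HogParams)
    lbp: LbpParams = field(default_factory=LbpParams)
    autoencoder: AEConfig = field(default_factory=AEConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    augmentation: AugmentationParams | None = None
    augment_split: str = "train"
    descriptors: tuple[str, ...] = DESCRIPTOR_ORDER
    train_ratio: float = 0.8
    group_by_slide: bool = True
    normalize_stain: bool = True
    embed_test_set: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_ratio < 1:
            raise ValueError("train_ratio must be in (0, 1)")
        if self.augmentation is not None and self.augment_split != "train":
            raise ValueError(
                "augmentation is restricted to the training portion; "
                f"augment_split={self.augment_split!r} is not allowed")
        unknown = set(self.descriptors) - set(DESCRIPTOR_ORDER)
        if unknown:
            raise ValueError(f"unknown descriptors {sorted(unknown)}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["descriptors"] = list(self.descriptors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["dataset"] = DatasetConfig(**d.get("dataset", {}))
        d["segmentation"] = SegmentationParams(**d.get("segmentation", {}))
        d["hog"] = _from_dict_frozen(HogParams, d.get("hog", {}))
        d["lbp"] = _from_dict_frozen(LbpParams, d.get("lbp", {}))
        d["autoencoder"] = AEConfig(**d.get("autoencoder", {}))
        clf = dict(d.get("classifier", {}))
        if "hidden" in clf:
            clf["hidden"] = tuple(clf["hidden"])
        d["classifier"] = ClassifierConfig(**clf)
        aug = d.get("augmentation")
        if aug is not None:
            if "brightness_range" in aug:
                aug["brightness_range"] = tuple(aug["brightness_range"])
            if "zoom_range" in aug:
                aug["zoom_range"] = tuple(aug["zoom_range"])
            d["augmentation"] = AugmentationParams(**aug)
        d["descriptors"] = tuple(d.get("descriptors", DESCRIPTOR_ORDER))
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _from_dict_frozen(cls, d: dict):
    d = dict(d)
    for f in dataclasses.fields(cls):
        if f.name in d and isinstance(d[f.name], list):
            d[f.name] = tuple(d[f.name])
    return cls(**d)


def default_synthetic_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale synthetic-slide configuration exercising all stages."""
    return PipelineConfig(
        dataset=DatasetConfig(kind="synthetic-slides", slides_per_class=4),
        segmentation=SegmentationParams(seg_downsample=8, min_contour_area=64),
        autoencoder=AEConfig(epochs=10, learning_rate=1e-3, batch_size=32),
        classifier=ClassifierConfig(epochs=20, learning_rate=1e-3, batch_size=32),
        seed=seed,
    )


# -- dataset splitting ------------------------------------------------------

def split_dataset(store: PatchStore, ratio: float = 0.8,
                  group_by_slide: bool = True, seed: int = 0,
                  ) -> tuple[PatchStore, PatchStore]:
    """Stratified train/test split; grouped so no slide spans both sides.

    With grouping, each slide's patches land wholly on one side and the
    split ratio applies to slides within each (majority-label) class:
    ``n_train = round(ratio * n_slides)``, clamped so both sides are
    non-empty.  Without grouping the same rule applies to records within
    each class.
    """
    rng = np.random.default_rng(seed)
    n = len(store)
    if n == 0:
        raise ValueError("cannot split an empty store")
    train_mask = np.zeros(n, bool)
    if group_by_slide:
        slides = np.unique(store.slide_ids)
        if len(slides) < 2:
            raise ValueError(
                "grouped split requires >= 2 slides; got "
                f"{len(slides)} (disable group_by_slide for patch-level splits)")
        slide_label = {}
        for s in slides:
            labs = store.labels[store.slide_ids == s]
            slide_label[s] = int(np.bincount(labs).argmax())
        classes = sorted(set(slide_label.values()))
        train_slides: set[str] = set()
        for c in classes:
            members = np.array([s for s in slides if slide_label[s] == c])
            rng.shuffle(members)
            k = len(members)
            n_train = int(round(ratio * k))
            if k >= 2:
                n_train = min(max(n_train, 1), k - 1)
            train_slides.update(members[:n_train].tolist())
        train_mask = np.isin(store.slide_ids, sorted(train_slides))
    else:
        for c in sorted(store.class_counts()):
            idx = np.flatnonzero(store.labels == c)
            rng.shuffle(idx)
            k = len(idx)
            n_train = int(round(ratio * k))
            if k >= 2:
                n_train = min(max(n_train, 1), k - 1)
            train_mask[idx[:n_train]] = True
    return store.subset(np.flatnonzero(train_mask)), \
        store.subset(np.flatnonzero(~train_mask))


# -- core study: descriptors -> AEs -> fusion -> classifier -> metrics ------

def run_descriptor_study(train: DescriptorSet, test: DescriptorSet,
                         ae_config: AEConfig | None = None,
                         clf_config: ClassifierConfig | None = None,
                         descriptors: tuple[str, ...] = DESCRIPTOR_ORDER,
                         seed: int = 0, n_classes: int | None = None) -> dict:
    """Train per-descriptor autoencoders, fuse, classify, evaluate.

    Returns a dict with the trained models, the fused representations,
    predictions, the metrics report and one-vs-rest AUCs on ``test``.
    """
    ae_config = ae_config or AEConfig()
    clf_config = clf_config or ClassifierConfig()
    n_classes = int(n_classes if n_classes is not None
                    else max(train.labels.max(), test.labels.max()) + 1)
    models = {}
    for i, name in enumerate(descriptors):
        models[name] = train_autoencoder(train.by_name(name), ae_config,
                                         seed=seed + 10 + i, descriptor=name)
    fused_train = fuse({n: encode(models[n], train.by_name(n)) for n in descriptors})
    fused_test = fuse({n: encode(models[n], test.by_name(n)) for n in descriptors})
    clf_config = dataclasses.replace(clf_config, seed=seed + 20)
    clf = train_classifier(fused_train.data, train.labels, n_classes, clf_config)
    proba, pred = predict(clf, fused_test.data)
    cm = confusion(test.labels, pred, n_classes)
    report = metrics(cm)
    roc = roc_auc(test.labels, proba)
    report.auc_per_class = roc.auc_per_class
    report.auc_macro = roc.macro_auc
    return {
        "autoencoders": models,
        "classifier": clf,
        "fused_train": fused_train,
        "fused_test": fused_test,
        "probabilities": proba,
        "predictions": pred,
        "confusion": cm,
        "metrics": report,
        "roc": roc,
        "accuracy": report.accuracy,
    }


def run_synthetic_benchmark(seed: int = 0, n_classes: int = 4,
                            patches_per_class: int = 250,
                            ae_config: AEConfig | None = None,
                            clf_config: ClassifierConfig | None = None,
                            ablate: bool = True) -> dict:
    """The standard synthetic classification study at desk scale.

    Generates the default ``n_classes``-class patch set (250 patches per
    class -> an 800/200 stratified split for four classes), featurizes it,
    and runs the fused-descriptor study plus, optionally, each
    single-descriptor ablation.  The default training schedule (8
    autoencoder epochs, 15 classifier epochs, Adam at 1e-3, batch 64) is
    sized for a single CPU core; the synthetic classes are separable
    enough that the schedule trains to convergence.

    Returns the triplet study result plus ``accuracies`` — a dict keyed
    by descriptor combination ("raw+hog+lbp", "raw", ...).
    """
    ae_config = ae_config or AEConfig(epochs=8, learning_rate=1e-3, batch_size=64)
    clf_config = clf_config or ClassifierConfig(epochs=15, learning_rate=1e-3,
                                                batch_size=64)
    store = synthetic.make_patch_dataset(synthetic.SyntheticPatchSpec(
        n_classes=n_classes, patches_per_class=patches_per_class, seed=seed))
    train_store, test_store = split_dataset(store, 0.8, group_by_slide=False,
                                            seed=seed + 1)
    train = featurize_store(train_store)
    test = featurize_store(test_store)
    combos = [DESCRIPTOR_ORDER] + ([("raw",), ("hog",), ("lbp",)] if ablate else [])
    accuracies: dict[str, float] = {}
    results: dict[str, dict] = {}
    for combo in combos:
        res = run_descriptor_study(train, test, ae_config, clf_config,
                                   descriptors=tuple(combo), seed=seed,
                                   n_classes=n_classes)
        key = "+".join(combo)
        accuracies[key] = res["accuracy"]
        results[key] = res
    main = results["+".join(DESCRIPTOR_ORDER)]
    return {**main, "accuracies": accuracies, "results": results,
            "n_train": len(train), "n_test": len(test)}


# -- full pipeline ----------------------------------------------------------

@dataclass
class StageRecord:
    name: str
    status: str
    seconds: float = 0.0
    artifacts: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the seven-stage pipeline and return its artifact index."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    records: list[StageRecord] = []
    seed = config.seed

    def _stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    def _done(name, t0, status="completed", artifacts=()):
        records.append(StageRecord(name, status, time.perf_counter() - t0,
                                   [str(a) for a in artifacts]))

    # 1. synthesize / ingest ------------------------------------------------
    t0 = _stage("synthesize")
    slides: list[tuple] = []
    store: PatchStore | None = None
    ds = config.dataset
    class_names = [f"class{c}" for c in range(ds.n_classes)]
    if ds.kind == "synthetic-slides":
        params = synthetic.default_class_params(ds.n_classes)
        class_names = [p.name for p in params]
        for c, cp in enumerate(params):
            for s in range(ds.slides_per_class):
                slide, _ = synthetic.make_labeled_slide(
                    cp, width=ds.slide_width, height=ds.slide_height,
                    n_blobs=ds.blobs_per_slide, blob_radius=ds.blob_radius,
                    seed=seed * 1000 + c * 10 + s,
                    slide_id=f"synth-c{c}-s{s}")
                slides.append((slide, c))
    elif ds.kind == "synthetic-patches":
        spec = synthetic.SyntheticPatchSpec(
            n_classes=ds.n_classes, patches_per_class=ds.patches_per_class,
            slides_per_class=ds.slides_per_class, seed=seed)
        store = synthetic.make_patch_dataset(spec)
        class_names = store.class_names
    else:
        for path, label in zip(ds.paths, ds.labels):
            from .preprocess import SlideImage
            slides.append((SlideImage.from_file(path), int(label)))
    _done("synthesize", t0)

    # 2-3. segment + patch --------------------------------------------------
    patches_path = out / "patches.h5"
    if store is None:
        t0 = _stage("segment")
        masks = [segment_tissue(slide, config.segmentation) for slide, _ in slides]
        _done("segment", t0)
        t0 = _stage("patch")
        if _fresh(patches_path, out, chash):
            store = read_store(patches_path)
        else:
            parts = [extract_patches(slide, mask, ds.magnification, label,
                                     class_names=class_names)
                     for (slide, label), mask in zip(slides, masks)]
            store = PatchStore.concatenate(parts)
            write_store(store, patches_path)
        _done("patch", t0, artifacts=[patches_path])
    else:
        _done("segment", _stage("segment"), status="skipped (patch-level input)")
        t0 = _stage("patch")
        if not _fresh(patches_path, out, chash):
            write_store(store, patches_path)
        _done("patch", t0, status="completed (store persisted)",
              artifacts=[patches_path])

    # 4. split + featurize --------------------------------------------------
    t0 = _stage("featurize")
    train_store, test_store = split_dataset(
        store, config.train_ratio, config.group_by_slide, seed=seed + 1)
    feat_paths = {split: out / f"features_{split}.h5" for split in ("train", "test")}
    if all(_fresh(p, out, chash) for p in feat_paths.values()):
        feats = {split: read_features(p) for split, p in feat_paths.items()}
    else:
        aug = config.augmentation
        if aug is not None:
            aug = dataclasses.replace(aug, seed=seed + 2)
        feats = {
            "train": featurize_store(train_store, aug,
                                     hog_params=config.hog, lbp_params=config.lbp,
                                     normalize_stain=config.normalize_stain),
            "test": featurize_store(test_store, None,
                                    hog_params=config.hog, lbp_params=config.lbp,
                                    normalize_stain=config.normalize_stain),
        }
        for split, p in feat_paths.items():
            write_features(feats[split], p)
    _done("featurize", t0, artifacts=list(feat_paths.values()))

    # 5. autoencoders -------------------------------------------------------
    t0 = _stage("train_autoencoders")
    models = {}
    ae_paths = []
    for i, name in enumerate(config.descriptors):
        model = train_autoencoder(feats["train"].by_name(name),
                                  config.autoencoder, seed=seed + 10 + i,
                                  descriptor=name)
        p = out / f"autoencoder_{name}.h5"
        save_autoencoder(model, p)
        models[name] = model
        ae_paths.append(p)
    _done("train_autoencoders", t0, artifacts=ae_paths)

    # 6. fuse + classifier --------------------------------------------------
    t0 = _stage("fuse_train_classifier")
    fused_train = fuse({n: encode(models[n], feats["train"].by_name(n))
                        for n in config.descriptors})
    fused_test = fuse({n: encode(models[n], feats["test"].by_name(n))
                       for n in config.descriptors})
    clf_config = dataclasses.replace(config.classifier, seed=seed + 20)
    clf = train_classifier(fused_train.data, feats["train"].labels,
                           ds.n_classes, clf_config)
    clf_path = out / "classifier.h5"
    save_classifier(clf, clf_path)
    _done("fuse_train_classifier", t0, artifacts=[clf_path])

    # 7. evaluate -----------------------------------------------------------
    t0 = _stage("evaluate")
    proba, pred = predict(clf, fused_test.data)
    cm = confusion(feats["test"].labels, pred, ds.n_classes, class_names)
    report = metrics(cm)
    roc = roc_auc(feats["test"].labels, proba, class_names)
    report.auc_per_class = roc.auc_per_class
    report.auc_macro = roc.macro_auc
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(
        {"config_hash": chash, "n_train": len(feats["train"]),
         "n_test": len(feats["test"]),
         "confusion": cm.counts.tolist(),
         **report.to_dict()}, indent=2))
    eval_artifacts = [metrics_path]
    if config.embed_test_set:
        coords = project_embedding(
            fused_test.data, seed=seed + 30,
            perplexity=min(30.0, max(2.0, len(fused_test.data) / 4)))
        emb_path = out / "embedding_test.csv"
        np.savetxt(emb_path, np.column_stack([coords, feats["test"].labels]),
                   delimiter=",", header="x,y,label", comments="")
        eval_artifacts.append(emb_path)
    _done("evaluate", t0, artifacts=eval_artifacts)

    manifest = {
        "config_hash": chash,
        "config": config.to_dict(),
        "stages": [asdict(r) for r in records],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "store": store,
        "features": feats,
        "autoencoders": models,
        "classifier": clf,
        "metrics": report,
        "confusion": cm,
        "manifest": manifest,
        "out_dir": out,
    }


def _fresh(path: Path, out: Path, chash: str) -> bool:
    """An artifact is reusable iff it exists and the manifest hash matches."""
    manifest = out / "manifest.json"
    if not path.exists() or not manifest.exists():
        return False
    try:
        return json.loads(manifest.read_text())["config_hash"] == chash
    except Exception:
        return False
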