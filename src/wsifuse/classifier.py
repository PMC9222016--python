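"""Fully connected classification head over the fused latent vector.

The head replaces the autoencoder decoders once unsupervised training is
done:  fused y(x) -> Dense(1024) -> BatchNorm -> ReLU -> Dense(512) ->
BatchNorm -> ReLU -> Dense(C) -> softmax, trained with cross-entropy and
Adam.  Parameter accounting follows the usual conventions — a dense layer
holds out*(in+1) parameters, batch normalization 4 per feature (gamma,
beta, running mean, running variance) — which for a 5118-dimensional
fused input gives 5,241,856 + 4,096 + 524,800 + 2,048 parameters before
the softmax layer, whose size varies with the number of classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import (Adam, BatchNorm, Dense, ReLU, Sequential,
                  batchnorm_parameter_count, dense_parameter_count,
                  load_arrays, minibatch_indices, save_arrays, softmax,
                  softmax_cross_entropy)

__all__ = [
    "ClassifierConfig",
    "ClassifierModel",
    "build_head",
    "count_parameters",
    "train_classifier",
    "predict",
    "architecture_parameter_table",
    "save_classifier",
    "load_classifier",
]


@dataclass
class ClassifierConfig:
    """Classifier head hyperparameters.

    The layer plan (1024, 512) with batch normalization is fixed by
    default; epochs/batch size defaults follow the tuned multi-class
    settings (30 epochs, batch 32), with 128 the tuned batch size for the
    binary case.
    """

    hidden: tuple[int, ...] = (1024, 512)
    batch_norm: bool = True
    epochs: int = 30
    learning_rate: float = 1e-4
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden layer sizes must be >= 1")


@dataclass
class ClassifierModel:
    """Dense head with per-layer parameter accounting and history."""

    network: Sequential
    input_dim: int
    n_classes: int
    config: ClassifierConfig
    history: list[dict] = field(default_factory=list)
    trained: bool = False

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.network.forward(np.asarray(x, np.float32), training)


def build_head(fused_dim: int, n_classes: int,
               config: ClassifierConfig | None = None) -> ClassifierModel:
    """Build the dense classification head for ``fused_dim`` inputs."""
    config = config or ClassifierConfig()
    if fused_dim < 1:
        raise ValueError("fused_dim must be positive")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(config.seed)
    layers = []
    n_in = fused_dim
    for width in config.hidden:
        layers.append(Dense(n_in, width, rng))
        if config.batch_norm:
            layers.append(BatchNorm(width))
        layers.append(ReLU())
        n_in = width
    layers.append(Dense(n_in, n_classes, rng))  # softmax applied in predict
    return ClassifierModel(network=Sequential(layers), input_dim=fused_dim,
                           n_classes=n_classes, config=config)


def count_parameters(model: ClassifierModel) -> dict[str, int]:
    """Per-layer and total parameter counts of a built head.

    Dense layers count out*(in+1); batch-norm layers count 4*features.
    The final dense layer (feeding the softmax) is listed as
    ``softmax_dense``.
    """
    counts: dict[str, int] = {}
    dense_seen = 0
    for layer in model.network.layers:
        if isinstance(layer, Dense):
            dense_seen += 1
            is_last = dense_seen == sum(
                isinstance(l, Dense) for l in model.network.layers)
            name = "softmax_dense" if is_last else f"dense_{layer.n_out}"
            counts[name] = dense_parameter_count(layer.n_in, layer.n_out)
        elif isinstance(layer, BatchNorm):
            counts[f"batch_norm_{layer.n_features}"] = batchnorm_parameter_count(
                layer.n_features)
    counts["total"] = sum(v for k, v in counts.items())
    return counts


def architecture_parameter_table(raw_dim: int = 4800, hog_dim: int = 64,
                                 lbp_dim: int = 254) -> dict[str, int]:
    """Parameter counts of the full architecture at the reference sizes.

    Builds the actual layers (same-size dense encoder per descriptor plus
    the classification head over the concatenated latent) and counts their
    parameters; the classifier's softmax layer is excluded because its
    size varies with the class count.
    """
    fused = raw_dim + hog_dim + lbp_dim
    encoders = {
        "encoder_raw": Dense(raw_dim, raw_dim),
        "encoder_hog": Dense(hog_dim, hog_dim),
        "encoder_lbp": Dense(lbp_dim, lbp_dim),
    }
    table = {name: layer.n_params for name, layer in encoders.items()}
    head = build_head(fused, 4)
    head_counts = count_parameters(head)
    table["head_dense_1024"] = head_counts["dense_1024"]
    table["head_batch_norm_1024"] = head_counts["batch_norm_1024"]
    table["head_dense_512"] = head_counts["dense_512"]
    table["head_batch_norm_512"] = head_counts["batch_norm_512"]
    table["fused_dim"] = fused
    return table


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     n_classes: int | None = None,
                     config: ClassifierConfig | None = None) -> ClassifierModel:
    """Train the head with softmax cross-entropy and Adam (seeded).

    ``labels`` must cover at least two classes; per-epoch mean loss and
    training accuracy are recorded in ``model.history``.
    """
    config = config or ClassifierConfig()
    x = np.ascontiguousarray(features, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("training set contains a single class")
    n_classes = int(n_classes if n_classes is not None else present.max() + 1)
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    model = build_head(x.shape[1], n_classes, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1F]))
    opt = Adam(lr=config.learning_rate)
    net = model.network
    n = len(x)
    for _epoch in range(config.epochs):
        losses, hits, seen = [], 0, 0
        for idx in minibatch_indices(n, config.batch_size, rng):
            xb, yb = x[idx], y[idx]
            logits = net.forward(xb, training=True)
            loss, grad = softmax_cross_entropy(logits, yb)
            net.backward(grad)
            opt.step(net.params, net.grads)
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yb).sum())
            seen += len(yb)
        model.history.append({"loss": float(np.mean(losses)),
                              "accuracy": hits / seen})
    model.trained = True
    return model


def predict(model: ClassifierModel,
            features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (softmax) and argmax labels.

    Probabilities sum to one per sample; argmax ties resolve to the
    lowest class index.  Inference uses the batch-norm running statistics,
    so batch prediction equals per-sample prediction.
    """
    if not model.trained:
        raise RuntimeError("classifier has not been trained")
    x = np.asarray(features, np.float32)
    if x.ndim != 2 or x.shape[1] != model.input_dim:
        raise ValueError(
            f"features have dimension {x.shape[-1] if x.ndim else '?'}, "
            f"model expects {model.input_dim}")
    proba = softmax(model.logits(x, training=False))
    return proba, proba.argmax(axis=1)


def save_classifier(model: ClassifierModel, path) -> None:
    meta = {
        "kind": "classifier",
        "input_dim": model.input_dim,
        "n_classes": model.n_classes,
        "config": {**asdict(model.config), "hidden": list(model.config.hidden)},
        "history": model.history,
        "trained": model.trained,
    }
    save_arrays(path, model.network.state_arrays(), meta)


def load_classifier(path) -> ClassifierModel:
    arrays, meta = load_arrays(path)
    if meta.get("kind") != "classifier":
        raise ValueError(f"{path} is not a classifier checkpoint")
    cfg = dict(meta["config"])
    cfg["hidden"] = tuple(cfg["hidden"])
    config = ClassifierConfig(**cfg)
    model = build_head(meta["input_dim"], meta["n_classes"], config)
    model.network.load_state_arrays(arrays)
    model.history = list(meta["history"])
    model.trained = bool(meta["trained"])
    return model
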