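"""Stacked autoencoders over descriptor streams and latent fusion.

One autoencoder is trained per descriptor family (RAW, HOG, LBP) to
minimize the summed squared reconstruction error

    L = sum_i || dhat_i(x) - d_i(x) ||^2   (averaged over the batch),

where d_i is the i-th descriptor vector, dhat_i its reconstruction, and
the encoder output dtilde_i = E_i(d_i(x)) is the latent representation.
After unsupervised training the decoders are discarded; the latents are
concatenated in a fixed order (RAW, HOG, LBP) into the fused vector
y(x), which feeds the supervised classifier head.  With single hidden
layers in "same" sizing the fused dimension is 4800 + 64 + 254 = 5118.

Latent sizing modes: ``"same"`` keeps the latent at the input dimension
d, ``"double"`` uses 2d.  Encoders stay frozen during classifier training
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from ._nn import (Adam, Dense, Identity, ReLU, Sequential, load_arrays,
                  minibatch_indices, save_arrays)

DESCRIPTOR_ORDER = ("raw", "hog", "lbp")

__all__ = [
    "DESCRIPTOR_ORDER",
    "AEConfig",
    "AutoencoderModel",
    "FusedRepresentation",
    "build_autoencoder",
    "train_autoencoder",
    "encode",
    "reconstruction_loss",
    "fuse",
    "save_autoencoder",
    "load_autoencoder",
]


@dataclass
class AEConfig:
    """Autoencoder hyperparameters.

    ``neuron_mode`` selects the latent width relative to the input
    dimension d: ``"same"`` -> d, ``"double"`` -> 2d; ``latent_override``
    fixes an explicit width instead (e.g. for bottleneck experiments).
    Defaults follow the tuned single-hidden-layer ReLU configuration
    (200 epochs, Adam).
    """

    hidden_layers: int = 1
    neuron_mode: str = "same"
    activation: str = "relu"
    epochs: int = 200
    learning_rate: float = 1e-4
    batch_size: int = 64
    latent_override: int | None = None

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if self.neuron_mode not in ("same", "double"):
            raise ValueError("neuron_mode must be 'same' or 'double'")
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")

    def latent_dim(self, input_dim: int) -> int:
        if self.latent_override is not None:
            if self.latent_override < 1:
                raise ValueError("latent_override must be >= 1")
            return self.latent_override
        return input_dim if self.neuron_mode == "same" else 2 * input_dim


def _act(name: str):
    return ReLU() if name == "relu" else Identity()


@dataclass
class AutoencoderModel:
    """Encoder/decoder pair for one descriptor stream."""

    encoder: Sequential
    decoder: Sequential
    input_dim: int
    latent_dim: int
    config: AEConfig
    descriptor: str = ""
    history: list[float] = field(default_factory=list)
    trained: bool = False

    def reconstruct(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x, training), training)

    @property
    def n_params(self) -> int:
        return self.encoder.n_params + self.decoder.n_params


def build_autoencoder(input_dim: int, config: AEConfig | None = None,
                      seed: int = 0, descriptor: str = "") -> AutoencoderModel:
    """Construct an (untrained) autoencoder with seeded Glorot weights.

    The encoder applies ``hidden_layers`` affine+activation blocks; the
    decoder mirrors them, ending in a linear map back to the input
    dimension.
    """
    config = config or AEConfig()
    rng = np.random.default_rng(seed)
    latent = config.latent_dim(input_dim)
    enc_layers = [Dense(input_dim, latent, rng), _act(config.activation)]
    for _ in range(config.hidden_layers - 1):
        enc_layers += [Dense(latent, latent, rng), _act(config.activation)]
    dec_layers = []
    for _ in range(config.hidden_layers - 1):
        dec_layers += [Dense(latent, latent, rng), _act(config.activation)]
    dec_layers += [Dense(latent, input_dim, rng)]
    return AutoencoderModel(
        encoder=Sequential(enc_layers), decoder=Sequential(dec_layers),
        input_dim=input_dim, latent_dim=latent, config=config,
        descriptor=descriptor)


def train_autoencoder(features: np.ndarray, config: AEConfig | None = None,
                      seed: int = 0, descriptor: str = "") -> AutoencoderModel:
    """Train by backpropagation with Adam on the reconstruction loss.

    The per-epoch history records the batch-averaged loss
    mean_n ||dhat - d||^2.  Divergence to NaN aborts with a hint to lower
    the learning rate.
    """
    config = config or AEConfig()
    x = np.ascontiguousarray(features, dtype=np.float32)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    n, d = x.shape
    if n < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} samples, got {n}")
    model = build_autoencoder(d, config, seed=seed, descriptor=descriptor)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5AE]))
    opt = Adam(lr=config.learning_rate)
    params = model.encoder.params + model.decoder.params
    for epoch in range(config.epochs):
        batch_losses = []
        for idx in minibatch_indices(n, config.batch_size, rng):
            xb = x[idx]
            recon = model.reconstruct(xb, training=True)
            diff = recon - xb
            loss = float((diff ** 2).sum(axis=1).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"autoencoder loss diverged to {loss} at epoch {epoch}; "
                    f"try a lower learning rate than {config.learning_rate}")
            grad = (2.0 / len(idx)) * diff.astype(np.float32)
            model.encoder.backward(model.decoder.backward(grad))
            grads = model.encoder.grads + model.decoder.grads
            opt.step(params, grads)
            batch_losses.append(loss)
        model.history.append(float(np.mean(batch_losses)))
    model.trained = True
    return model


def encode(model: AutoencoderModel, features: np.ndarray) -> np.ndarray:
    """Latent representations dtilde = E(d); deterministic, order-preserving."""
    if not model.trained:
        raise RuntimeError("autoencoder has not been trained")
    x = np.asarray(features, dtype=np.float32)
    return model.encoder.forward(x, training=False)


def reconstruction_loss(features: Mapping[str, np.ndarray] | Sequence[np.ndarray],
                        models: Mapping[str, AutoencoderModel] | Sequence[AutoencoderModel],
                        ) -> float:
    """Summed-over-descriptors squared L2 reconstruction error, batch mean."""
    if isinstance(features, Mapping):
        keys = list(features)
        feats = [features[k] for k in keys]
        mods = [models[k] for k in keys]
    else:
        keys = [m.descriptor or str(i) for i, m in enumerate(models)]
        feats = list(features)
        mods = list(models)
    total = 0.0
    for key, f, m in zip(keys, feats, mods):
        f = np.asarray(f, dtype=np.float32)
        if f.ndim != 2 or f.shape[1] != m.input_dim:
            raise ValueError(
                f"descriptor {key!r}: features have dimension "
                f"{f.shape[-1] if f.ndim else '?'}, model expects {m.input_dim}")
        diff = m.reconstruct(f) - f
        total += float((diff ** 2).sum(axis=1).mean())
    return total


@dataclass
class FusedRepresentation:
    """Concatenated latents y(x) with per-descriptor offsets."""

    data: np.ndarray                      # (N, sum of latent dims)
    offsets: dict[str, tuple[int, int]]   # name -> (start, stop)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    def component(self, name: str) -> np.ndarray:
        start, stop = self.offsets[name]
        return self.data[:, start:stop]


def fuse(latents: Mapping[str, np.ndarray] | Sequence[np.ndarray],
         order: Sequence[str] = DESCRIPTOR_ORDER) -> FusedRepresentation:
    """Concatenate per-descriptor latents in fixed order (RAW, HOG, LBP)."""
    if isinstance(latents, Mapping):
        names = [k for k in order if k in latents]
        names += [k for k in latents if k not in names]
        mats = [np.asarray(latents[k]) for k in names]
    else:
        mats = [np.asarray(m) for m in latents]
        names = [order[i] if i < len(order) else f"latent{i}"
                 for i in range(len(mats))]
    if not mats:
        raise ValueError("no latents to fuse")
    sizes = {len(m) for m in mats}
    if len(sizes) != 1:
        raise ValueError(f"batch sizes differ across descriptors: {sorted(sizes)}")
    offsets = {}
    start = 0
    for name, m in zip(names, mats):
        offsets[name] = (start, start + m.shape[1])
        start += m.shape[1]
    return FusedRepresentation(data=np.concatenate(mats, axis=1), offsets=offsets)


# -- checkpoints ------------------------------------------------------------

def save_autoencoder(model: AutoencoderModel, path) -> None:
    meta = {
        "kind": "autoencoder",
        "input_dim": model.input_dim,
        "latent_dim": model.latent_dim,
        "descriptor": model.descriptor,
        "config": asdict(model.config),
        "history": model.history,
        "trained": model.trained,
        "n_encoder_arrays": len(model.encoder.state_arrays()),
    }
    save_arrays(path, model.encoder.state_arrays() + model.decoder.state_arrays(), meta)


def load_autoencoder(path) -> AutoencoderModel:
    arrays, meta = load_arrays(path)
    if meta.get("kind") != "autoencoder":
        raise ValueError(f"{path} is not an autoencoder checkpoint")
    config = AEConfig(**meta["config"])
    model = build_autoencoder(meta["input_dim"], config,
                              descriptor=meta["descriptor"])
    k = meta["n_encoder_arrays"]
    model.encoder.load_state_arrays(arrays[:k])
    model.decoder.load_state_arrays(arrays[k:])
    model.history = list(meta["history"])
    model.trained = bool(meta["trained"])
    return model
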