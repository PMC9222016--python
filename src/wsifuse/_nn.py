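"""Feed-forward neural-network primitives with explicit backpropagation.

Small, dependency-free (NumPy only) building blocks shared by the
autoencoder and classifier modules: dense and batch-normalization layers,
ReLU, softmax cross-entropy, and an Adam optimizer.  Everything runs in
float32; weight initialization is uniform Glorot from a caller-supplied
``numpy.random.Generator`` so that training is reproducible.
"""

from __future__ import annotations

import json
from typing import Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "Dense",
    "BatchNorm",
    "ReLU",
    "Identity",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "minibatch_indices",
    "dense_parameter_count",
    "batchnorm_parameter_count",
    "save_arrays",
    "load_arrays",
]


def dense_parameter_count(n_in: int, n_out: int) -> int:
    """Parameters of a dense layer with bias: ``n_out * (n_in + 1)``."""
    return n_out * (n_in + 1)


def batchnorm_parameter_count(n_features: int) -> int:
    """Batch-norm bookkeeping: gamma + beta + running mean + running var."""
    return 4 * n_features


class Layer:
    """Base class; stateless layers leave ``params``/``grads`` empty."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    """Affine map ``x @ W + b`` with uniform Glorot initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        if n_in < 1 or n_out < 1:
            raise ValueError(f"degenerate dense layer {n_in}->{n_out}: sizes must be >= 1")
        self.n_in = n_in
        self.n_out = n_out
        rng = rng if rng is not None else np.random.default_rng(0)
        limit = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    @property
    def weight(self) -> np.ndarray:
        return self.params[0]

    @property
    def bias(self) -> np.ndarray:
        return self.params[1]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward() before forward(training=True)"
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0].T


class BatchNorm(Layer):
    """Batch normalization over features, running statistics for inference.

    Counts 4 parameters per feature (gamma, beta, running mean, running
    variance); only gamma/beta receive gradients.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.n_features = n_features
        self.momentum = momentum
        self.eps = eps
        gamma = np.ones(n_features, dtype=np.float32)
        beta = np.zeros(n_features, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self._cache: tuple | None = None

    @property
    def n_params(self) -> int:
        return batchnorm_parameter_count(self.n_features)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            std = np.sqrt(var + self.eps)
            xhat = (x - mu) / std
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
            self._cache = (xhat, std)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.params[0] * xhat + self.params[1]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, std = self._cache
        n = grad.shape[0]
        g_sum = grad.sum(axis=0)
        gx_sum = (grad * xhat).sum(axis=0)
        self.grads[0][...] = gx_sum
        self.grads[1][...] = g_sum
        return (self.params[0] / (std * n)) * (n * grad - g_sum - xhat * gx_sum)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Identity(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Sequential:
    """Ordered layer stack with forward/backward passes."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def state_arrays(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for layer in self.layers:
            arrays.extend(layer.params)
            if isinstance(layer, BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers:
            for i in range(len(layer.params)):
                layer.params[i][...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


class Adam:
    """Adam optimizer; per-parameter first/second moment estimates."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def minibatch_indices(n: int, batch_size: int,
                      rng: np.random.Generator) -> Iterator[np.ndarray]:
    """Shuffled minibatch index blocks covering ``range(n)`` once."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def save_arrays(path, arrays: Sequence[np.ndarray], meta: dict) -> None:
    """Persist a flat list of arrays plus a JSON metadata attribute (HDF5)."""
    with h5py.File(path, "w") as f:
        f.attrs["meta_json"] = json.dumps(meta)
        f.attrs["n_arrays"] = len(arrays)
        for i, a in enumerate(arrays):
            f.create_dataset(f"arr_{i:04d}", data=a)


def load_arrays(path) -> tuple[list[np.ndarray], dict]:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta_json"])
        arrays = [f[f"arr_{i:04d}"][...] for i in range(int(f.attrs["n_arrays"]))]
    return arrays, meta
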