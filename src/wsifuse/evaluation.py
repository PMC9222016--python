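"""Evaluation suite: confusion matrices, classification metrics, ROC/AUC,
and 2-D embedding of learned representations.

Multi-class metrics are derived one-vs-rest per class from the confusion
matrix (rows = true, columns = predicted) and macro-averaged.  Two
precision variants are reported side by side:

* ``precision`` — the standard TP / (TP + FP);
* ``precision_as_printed`` — TN / (TN + FP), i.e. the specificity
  formula, kept for parity with reports that print it under the name
  "precision".

Overall accuracy is trace(cm)/N (identical to (TP+TN)/N in the binary
one-vs-rest case).  Any metric whose denominator is zero is reported as
0 and flagged.  AUC is one-vs-rest with trapezoidal integration; ties in
the scores are handled by the ROC convention of traversing tied
thresholds jointly, which matches rank-averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocResult",
    "confusion",
    "metrics",
    "roc_auc",
    "project_embedding",
    "plot_confusion_matrix",
    "plot_roc_curves",
]


@dataclass
class ConfusionMatrix:
    """C x C integer counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")
        if not self.class_names:
            self.class_names = [f"class{i}" for i in range(len(self.counts))]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) counts treating class ``c`` as positive."""
        cm = self.counts
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum() - cm[c, c])
        fn = int(cm[c, :].sum() - cm[c, c])
        tn = int(cm.sum() - tp - fp - fn)
        return tp, fp, tn, fn


def confusion(y_true, y_pred, n_classes: int,
              class_names: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if len(arr) and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels must lie in [0, {n_classes})")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts, class_names or [])


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


@dataclass
class MetricsReport:
    """Scalar summaries (macro-averaged for C > 2) plus per-class detail."""

    accuracy: float
    sensitivity: float
    precision: float
    precision_as_printed: float
    f1: float
    per_class: dict[str, dict[str, float]]
    zero_division_flags: list[str] = field(default_factory=list)
    auc_per_class: dict[str, float] = field(default_factory=dict)
    auc_macro: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "precision_as_printed": self.precision_as_printed,
            "f1": self.f1,
            "per_class": self.per_class,
            "zero_division_flags": self.zero_division_flags,
            "auc_per_class": self.auc_per_class,
            "auc_macro": self.auc_macro,
        }


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, both precision variants, and F1 from ``cm``.

    Per class (one-vs-rest): sensitivity = TP/(TP+FN), precision =
    TP/(TP+FP), precision-as-printed = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN),
    one-vs-rest accuracy = (TP+TN)/N.  Scalars are unweighted macro
    averages; overall ``accuracy`` is trace(cm)/N.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for c in range(cm.n_classes):
        tp, fp, tn, fn = cm.one_vs_rest(c)
        name = cm.class_names[c]
        per_class[name] = {
            "sensitivity": _safe_div(tp, tp + fn, flags, f"sensitivity[{name}]"),
            "precision": _safe_div(tp, tp + fp, flags, f"precision[{name}]"),
            "precision_as_printed": _safe_div(
                tn, tn + fp, flags, f"precision_as_printed[{name}]"),
            "f1": _safe_div(2 * tp, 2 * tp + fp + fn, flags, f"f1[{name}]"),
            "accuracy_ovr": (tp + tn) / cm.total,
        }
    macro = {k: float(np.mean([v[k] for v in per_class.values()]))
             for k in ("sensitivity", "precision", "precision_as_printed", "f1")}
    return MetricsReport(
        accuracy=float(np.trace(cm.counts)) / cm.total,
        sensitivity=macro["sensitivity"],
        precision=macro["precision"],
        precision_as_printed=macro["precision_as_printed"],
        f1=macro["f1"],
        per_class=per_class,
        zero_division_flags=flags,
    )


@dataclass
class RocResult:
    """One-vs-rest ROC curves and AUCs."""

    auc_per_class: dict[str, float]
    macro_auc: float
    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (fpr, tpr)
    skipped_classes: list[str] = field(default_factory=list)


def roc_auc(y_true, probabilities: np.ndarray,
            class_names: list[str] | None = None) -> RocResult:
    """Per-class one-vs-rest AUC (trapezoidal) and the macro average.

    Classes absent from ``y_true`` have no defined AUC; they are flagged
    in ``skipped_classes`` and excluded from the macro average.
    """
    y_true = np.asarray(y_true)
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 2 or len(p) != len(y_true):
        raise ValueError("probabilities must be (N, C) aligned with y_true")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_classes = p.shape[1]
    names = class_names or [f"class{i}" for i in range(n_classes)]
    aucs: dict[str, float] = {}
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    skipped: list[str] = []
    for c in range(n_classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            skipped.append(names[c])
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), p[:, c])
        curves[names[c]] = (fpr, tpr)
        aucs[names[c]] = float(np.trapezoid(tpr, fpr))
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return RocResult(auc_per_class=aucs, macro_auc=macro, curves=curves,
                     skipped_classes=skipped)


def project_embedding(activations: np.ndarray, seed: int = 0,
                      perplexity: float = 30.0) -> np.ndarray:
    """t-SNE projection of layer activations to N x 2 coordinates.

    Deterministic under a fixed seed.  Requires at least 5 samples and
    ``perplexity < N``; smaller batches should lower the perplexity.
    """
    from sklearn.manifold import TSNE

    x = np.asarray(activations, dtype=np.float64)
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 samples for embedding, got {n}")
    if perplexity >= n:
        raise ValueError(
            f"perplexity {perplexity} must be < n_samples {n}; "
            f"pass a smaller perplexity for small batches")
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed)
    return tsne.fit_transform(x)


# -- plotting ---------------------------------------------------------------

def plot_confusion_matrix(cm: ConfusionMatrix, path, normalize: bool = True) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = cm.counts.astype(float)
    shown = counts / counts.sum(axis=1, keepdims=True).clip(min=1) if normalize else counts
    fig, ax = plt.subplots(figsize=(4 + 0.4 * cm.n_classes,) * 2)
    im = ax.imshow(shown, cmap="Blues", vmin=0)
    ax.set_xticks(range(cm.n_classes), cm.class_names, rotation=45, ha="right")
    ax.set_yticks(range(cm.n_classes), cm.class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(cm.n_classes):
        for j in range(cm.n_classes):
            ax.text(j, i, f"{shown[i, j]:.2f}" if normalize else f"{int(counts[i, j])}",
                    ha="center", va="center", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_curves(roc: RocResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    grid = np.linspace(0, 1, 101)
    mean_tpr = np.zeros_like(grid)
    for name, (fpr, tpr) in roc.curves.items():
        ax.plot(fpr, tpr, lw=1.2,
                label=f"{name} (AUC={roc.auc_per_class[name]:.2f})")
        mean_tpr += np.interp(grid, fpr, tpr)
    if roc.curves:
        mean_tpr /= len(roc.curves)
        ax.plot(grid, mean_tpr, "k--", lw=1.5,
                label=f"average (AUC={roc.macro_auc:.2f})")
    ax.plot([0, 1], [0, 1], color="gray", lw=0.8, ls=":")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
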