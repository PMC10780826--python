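"""Training loop and the five-metric evaluation suite.

Training follows the study protocol: mini-batches of 5, the Adadelta
optimizer, categorical cross-entropy over the softmax output, and up to 100
epochs, with per-epoch training and validation accuracy/loss recorded as a
:class:`History` (the learning curves). Fixed seeds make histories exactly
reproducible in single-threaded mode.

Evaluation works from a 5x5 confusion matrix. Per class (one-vs-rest):

    Pr  = TP / (TP + FP) * 100          Re  = TP / (TP + FN) * 100
    Acc = (TP + TN) / total * 100       IoU = TP / (TP + FP + FN) * 100
    Fm  = 2 Pr Re / (Pr + Re)

Aggregate Pr/Re/Fm/IoU are support-weighted means of the per-class values;
the aggregate Acc is the overall accuracy trace/total * 100. In single-label
multiclass evaluation the support-weighted recall equals the overall
accuracy identically, which is why validation tables report Re = Acc while
Pr can differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    NUM_CLASSES,
    TRAIN,
    VALIDATION,
    LabeledDataset,
    label_name,
    one_hot,
)
from .exceptions import ContractError, DivergenceError
from .image_io import normalize, resize
from .nn import Adadelta, Model, softmax


@dataclass
class TrainingConfig:
    batch_size: int = 5
    epochs: int = 100
    optimizer: str = "adadelta"
    loss: str = "categorical_crossentropy"
    learning_rate: float = 1.0
    seed: int = 0
    early_stopping_patience: int | None = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ContractError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if self.optimizer != "adadelta":
            raise ContractError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ContractError(f"unsupported loss {self.loss!r}")


@dataclass
class History:
    """Per-epoch learning curves."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_acc": self.train_acc,
                "train_loss": self.train_loss,
                "val_acc": self.val_acc,
                "val_loss": self.val_loss,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def _slice_inputs(inputs, idx):
    if isinstance(inputs, (tuple, list)):
        return tuple(x[idx] for x in inputs)
    return inputs[idx]


def _ce_loss_and_grad(logits: np.ndarray, y_onehot: np.ndarray):
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.sum(y_onehot * np.log(p + eps), axis=1))
    grad = (p - y_onehot) / logits.shape[0]
    return loss, grad, p


def fit_arrays(
    model: Model,
    train_inputs,
    y_train: np.ndarray,
    val_inputs,
    y_val: np.ndarray,
    config: TrainingConfig,
) -> History:
    """Core mini-batch training loop over prepared arrays.

    ``*_inputs`` is an array for single-branch models or an
    ``(image, sequence)`` tuple for fused ones. Labels are integer codes.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adadelta(lr=config.learning_rate)
    n = y_train.shape[0]
    yt = one_hot(y_train, model_num_classes(model))
    history = History()
    best_val, wait = np.inf, 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for s in range(0, n, config.batch_size):
            idx = perm[s : s + config.batch_size]
            xb = _slice_inputs(train_inputs, idx)
            logits = model.forward(xb, training=True)
            loss, grad, p = _ce_loss_and_grad(logits, yt[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch + 1)
            model.backward(grad)
            opt.step(model)
            losses.append(loss * idx.size)
            correct += int((p.argmax(axis=1) == y_train[idx]).sum())
        history.train_loss.append(float(np.sum(losses) / n))
        history.train_acc.append(correct / n)

        pv = model.predict_proba(val_inputs)
        vl = -np.mean(
            np.log(pv[np.arange(y_val.size), y_val] + 1e-12)
        )
        history.val_loss.append(float(vl))
        history.val_acc.append(float((pv.argmax(axis=1) == y_val).mean()))

        if config.early_stopping_patience is not None:
            if history.val_loss[-1] < best_val - 1e-12:
                best_val, wait = history.val_loss[-1], 0
            else:
                wait += 1
                if wait >= config.early_stopping_patience:
                    break
    return history


def model_num_classes(model: Model) -> int:
    return int(model.config.get("num_classes", NUM_CLASSES))


def prepare_images(images, input_shape: tuple[int, int, int]) -> np.ndarray:
    """Resize to the network input size and min-max normalize each image."""
    h, w, _ = input_shape
    out = []
    for img in images:
        r = resize(img, (h, w))
        if r.value_range == "raw_0_255":
            r = normalize(r)
        out.append(r.pixels)
    return np.stack(out)


def train_model(
    model: Model,
    data: LabeledDataset,
    config: TrainingConfig,
    sequences: np.ndarray | None = None,
) -> tuple[Model, History]:
    """Train on a split dataset; fused families need the GLCM ``sequences``.

    ``sequences`` must be aligned with the dataset items (n, T, 6) and
    already scaled; see :class:`SequenceScaler`.
    """
    if data.split is None:
        raise ContractError("dataset must carry train/validation split tags")
    tr = data.split_indices(TRAIN)
    va = data.split_indices(VALIDATION)
    if tr.size == 0 or va.size == 0:
        raise ContractError("both train and validation splits must be non-empty")
    fused = model.config.get("family", "").endswith("_lstm")
    if fused and sequences is None:
        raise ContractError("fused families require GLCM sequences")
    X = prepare_images(data.images, tuple(model.config["input_shape"]))
    y = data.labels
    if fused:
        train_inputs = (X[tr], sequences[tr])
        val_inputs = (X[va], sequences[va])
    else:
        train_inputs, val_inputs = X[tr], X[va]
    history = fit_arrays(model, train_inputs, y[tr], val_inputs, y[va], config)
    return model, history


class SequenceScaler:
    """Per-feature min-max scaling of GLCM sequences, fitted on training data.

    Each of the six texture features spans a very different scale (contrast
    can reach hundreds while ASM lives in (0, 1]); scaling each feature to
    [0, 1] over the training set keeps the LSTM gates in their responsive
    range. State is two 6-vectors, JSON-serializable for checkpoints.
    """

    def __init__(self, mins=None, maxs=None):
        self.mins = None if mins is None else np.asarray(mins, float)
        self.maxs = None if maxs is None else np.asarray(maxs, float)

    def fit(self, sequences: np.ndarray) -> "SequenceScaler":
        self.mins = sequences.min(axis=(0, 1))
        self.maxs = sequences.max(axis=(0, 1))
        return self

    def transform(self, sequences: np.ndarray) -> np.ndarray:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return np.clip((sequences - self.mins) / span, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceScaler":
        return cls(d["mins"], d["maxs"])


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Counts C[r][c] = items of true class r predicted as class c."""

    C: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.C)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ContractError(f"confusion matrix must be square, got {C.shape}")
        if (C < 0).any():
            raise ContractError("confusion counts must be non-negative")
        self.C = C.astype(np.int64)

    @property
    def num_classes(self) -> int:
        return self.C.shape[0]

    @property
    def total(self) -> int:
        return int(self.C.sum())

    def per_class_counts(self) -> pd.DataFrame:
        """One-vs-rest TP, FP, FN, TN per class."""
        C = self.C
        tp = np.diag(C)
        fp = C.sum(axis=0) - tp
        fn = C.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return pd.DataFrame(
            {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
            index=[label_name(k) for k in range(self.num_classes)]
            if self.num_classes == NUM_CLASSES
            else range(self.num_classes),
        )

    def to_csv(self, path: str) -> None:
        names = (
            [label_name(k) for k in range(self.num_classes)]
            if self.num_classes == NUM_CLASSES
            else list(range(self.num_classes))
        )
        pd.DataFrame(self.C, index=names, columns=names).to_csv(path)


def confusion(
    pred_labels: np.ndarray, true_labels: np.ndarray, num_classes: int = NUM_CLASSES
) -> ConfusionMatrix:
    """Count the confusion matrix of predicted vs true integer labels."""
    pred = np.asarray(pred_labels, dtype=np.intp)
    true = np.asarray(true_labels, dtype=np.intp)
    if pred.shape != true.shape:
        raise ContractError(
            f"length mismatch: {pred.shape[0]} predictions vs {true.shape[0]} labels"
        )
    if pred.size and (min(pred.min(), true.min()) < 0
                      or max(pred.max(), true.max()) >= num_classes):
        raise ContractError(f"labels must lie in 0..{num_classes - 1}")
    C = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(C, (true, pred), 1)
    return ConfusionMatrix(C)


@dataclass
class EvalReport:
    """Aggregate and per-class metrics on the 0-100 scale, plus loss."""

    precision: float
    recall: float
    accuracy: float
    iou: float
    f_measure: float
    loss: float
    per_class: pd.DataFrame
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "iou": self.iou,
            "f_measure": self.f_measure,
            "loss": self.loss,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.C.tolist(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = [
            f"overall:  Pr={self.precision:6.2f}  Re={self.recall:6.2f}  "
            f"Acc={self.accuracy:6.2f}  IoU={self.iou:6.2f}  "
            f"Fm={self.f_measure:6.2f}  loss={self.loss:.4f}",
            "",
            self.per_class.round(2).to_string(),
        ]
        return "\n".join(lines)


def _safe_div(num, den):
    return num / den if den > 0 else 0.0


def evaluate(C: ConfusionMatrix, loss: float = 0.0) -> EvalReport:
    """Per-class and aggregate Pr/Re/Acc/IoU/Fm from a confusion matrix.

    Classes with zero support and zero predictions score 0 on Pr/Re/Fm/IoU
    and drop out of the support-weighted aggregates (weight zero).
    """
    if C.total == 0:
        raise ContractError("cannot evaluate an empty confusion matrix")
    counts = C.per_class_counts()
    total = C.total
    rows = {}
    for cls, r in counts.iterrows():
        pr = _safe_div(r.tp, r.tp + r.fp) * 100.0
        re = _safe_div(r.tp, r.tp + r.fn) * 100.0
        acc = (r.tp + r.tn) / total * 100.0
        iou = _safe_div(r.tp, r.tp + r.fp + r.fn) * 100.0
        fm = _safe_div(2.0 * pr * re, pr + re)
        rows[cls] = {
            "precision": pr,
            "recall": re,
            "accuracy": acc,
            "iou": iou,
            "f_measure": fm,
            "support": int(r.tp + r.fn),
        }
    per_class = pd.DataFrame(rows).T
    support = per_class["support"].to_numpy(dtype=float)
    weights = support / support.sum()

    def agg(col):
        return float(per_class[col].to_numpy() @ weights)

    overall_acc = float(np.trace(C.C) / total * 100.0)
    return EvalReport(
        precision=agg("precision"),
        recall=agg("recall"),
        accuracy=overall_acc,
        iou=agg("iou"),
        f_measure=agg("f_measure"),
        loss=float(loss),
        per_class=per_class,
        confusion=C,
    )


def plot_confusion(C: ConfusionMatrix, path: str) -> None:
    """Write the confusion matrix as a heat-map PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = (
        [label_name(k) for k in range(C.num_classes)]
        if C.num_classes == NUM_CLASSES
        else [str(k) for k in range(C.num_classes)]
    )
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(C.C, cmap="Blues")
    ax.set_xticks(range(C.num_classes), names, rotation=45, ha="right")
    ax.set_yticks(range(C.num_classes), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for r in range(C.num_classes):
        for c in range(C.num_classes):
            ax.text(c, r, str(C.C[r, c]), ha="center", va="center", fontsize=9)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
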