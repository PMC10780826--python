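"""Scikit-learn style estimators wrapping the pipeline stages.

:class:`GrapeDiseaseClassifier` is the top-level fit/predict surface: it
resizes and normalizes images, derives GLCM feature sequences for the
LSTM-bearing families, trains the configured network with Adadelta, and
predicts class probabilities. :class:`GlcmFeaturizer` and
:class:`LeafSegmenter` expose the texture and segmentation stages as
transformers so they compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .datasets import TRAIN, VALIDATION
from .exceptions import ContractError
from .image_io import RgbImage, resize
from .networks import ArchitectureConfig, build_model
from .segmentation import BinaryMask, apply_mask, threshold_segment, to_grayscale
from .texture import DEFAULT_OFFSETS, glcm_sequence, quantize
from .train_eval import (
    SequenceScaler,
    TrainingConfig,
    confusion,
    evaluate,
    fit_arrays,
    prepare_images,
)


def _as_rgb_images(X) -> list[RgbImage]:
    if isinstance(X, np.ndarray):
        if X.ndim != 4 or X.shape[3] != 3:
            raise ContractError(f"expected (n, H, W, 3) array, got shape {X.shape}")
        return [RgbImage(x) for x in X]
    out = []
    for x in X:
        out.append(x if isinstance(x, RgbImage) else RgbImage(np.asarray(x)))
    return out


class LeafSegmenter(TransformerMixin, BaseEstimator):
    """Threshold-based background removal as a transformer.

    ``transform`` returns the masked images (background zeroed); use
    :meth:`segment` for a single image when the mask itself is needed.
    """

    def __init__(self, threshold="otsu", foreground="dark", cleanup=False):
        self.threshold = threshold
        self.foreground = foreground
        self.cleanup = cleanup

    def fit(self, X, y=None):
        return self

    def segment(self, image: RgbImage) -> tuple[RgbImage, BinaryMask]:
        mask = threshold_segment(
            to_grayscale(image), self.threshold, self.foreground, self.cleanup
        )
        return apply_mask(image, mask), mask

    def transform(self, X) -> list[RgbImage]:
        return [self.segment(img)[0] for img in _as_rgb_images(X)]


class GlcmFeaturizer(TransformerMixin, BaseEstimator):
    """GLCM texture features over a fixed offset list, as a transformer.

    ``transform`` maps n images to an ``(n, n_offsets * 6)`` feature matrix
    (or ``(n, n_offsets, 6)`` sequences with ``flatten=False``), computed on
    the luminance grayscale quantized to ``levels`` gray levels.
    """

    def __init__(self, levels=32, offsets=DEFAULT_OFFSETS, symmetric=True,
                 flatten=True):
        self.levels = levels
        self.offsets = offsets
        self.symmetric = symmetric
        self.flatten = flatten

    def fit(self, X, y=None):
        return self

    def transform(self, X, masks=None) -> np.ndarray:
        imgs = _as_rgb_images(X)
        seqs = []
        for i, img in enumerate(imgs):
            q = quantize(to_grayscale(img), self.levels)
            mask = masks[i] if masks is not None else None
            seqs.append(
                glcm_sequence(q, tuple(self.offsets), self.levels,
                              self.symmetric, mask)
            )
        out = np.stack(seqs)
        return out.reshape(out.shape[0], -1) if self.flatten else out


class GrapeDiseaseClassifier(ClassifierMixin, BaseEstimator):
    """Hybrid image + GLCM-sequence disease classifier.

    Parameters
    ----------
    family
        ``"dnn"``, ``"cnn"``, ``"dnn_lstm"`` or ``"cnn_lstm"``.
    backbone
        ``"none"``, ``"tiny"`` (offline seeded random-weight CNN), or a
        pretrained name (``"vgg16"`` etc.; requires weights).
    epochs, batch_size, learning_rate
        Training protocol (study defaults: batch 5, Adadelta).
    validation_fraction
        Internal 80/20-style holdout used when ``fit`` is not given an
        explicit split (train count = floor((1 - fraction) ... ) complement).
    levels, offsets, symmetric
        GLCM settings for the LSTM branch's feature sequences.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in ``fit``.
    model_ : Model
        The trained network.
    history_ : History
        Per-epoch learning curves.
    """

    def __init__(
        self,
        family="cnn_lstm",
        backbone="tiny",
        input_size=50,
        epochs=30,
        batch_size=5,
        learning_rate=1.0,
        validation_fraction=0.2,
        levels=32,
        offsets=DEFAULT_OFFSETS,
        symmetric=True,
        lstm_units=64,
        leaky_alpha=0.3,
        dropout_rate=0.25,
        early_stopping_patience=None,
        seed=0,
    ):
        self.family = family
        self.backbone = backbone
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.levels = levels
        self.offsets = offsets
        self.symmetric = symmetric
        self.lstm_units = lstm_units
        self.leaky_alpha = leaky_alpha
        self.dropout_rate = dropout_rate
        self.early_stopping_patience = early_stopping_patience
        self.seed = seed

    # -- internals ---------------------------------------------------------

    @property
    def _is_fused(self) -> bool:
        return self.family.endswith("_lstm")

    def _input_shape(self):
        return (self.input_size, self.input_size, 3)

    def _sequences(self, imgs: list[RgbImage]) -> np.ndarray:
        feats = GlcmFeaturizer(
            self.levels, tuple(self.offsets), self.symmetric, flatten=False
        )
        resized = [resize(img, self._input_shape()[:2]) for img in imgs]
        return feats.transform(resized)

    def _prepare(self, X, fit_scaler=False, train_idx=None):
        imgs = _as_rgb_images(X)
        Ximg = prepare_images(imgs, self._input_shape())
        if not self._is_fused:
            return Ximg
        seq = self._sequences(imgs)
        if fit_scaler:
            ref = seq if train_idx is None else seq[train_idx]
            self.scaler_ = SequenceScaler().fit(ref)
        return (Ximg, self.scaler_.transform(seq))

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y, split=None):
        """Train on images ``X`` with labels ``y``.

        ``split`` optionally assigns each item to ``"train"`` or
        ``"validation"``; otherwise a seeded holdout of
        ``validation_fraction`` is drawn internally.
        """
        y = np.asarray(y)
        if len(y) != len(X):
            raise ContractError("X and y must have equal length")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ContractError("need at least two classes to fit")

        n = len(y)
        if split is not None:
            split = list(split)
            tr = np.array([i for i, s in enumerate(split) if s == TRAIN], dtype=np.intp)
            va = np.array([i for i, s in enumerate(split) if s == VALIDATION], dtype=np.intp)
        else:
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(n)
            k = int(np.floor((1.0 - self.validation_fraction) * n))
            tr, va = perm[:k], perm[k:]
        if tr.size == 0 or va.size == 0:
            raise ContractError("both splits must be non-empty")

        inputs = self._prepare(X, fit_scaler=True, train_idx=tr)
        config = ArchitectureConfig(
            family=self.family,
            backbone=self.backbone,
            input_shape=self._input_shape(),
            num_classes=int(self.classes_.size),
            glcm_sequence_shape=(len(self.offsets), 6),
            lstm_units=self.lstm_units,
            leaky_alpha=self.leaky_alpha,
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )
        self.model_ = build_model(config)
        if self._is_fused:
            self.model_.config["seq_scaler"] = self.scaler_.to_dict()
        tcfg = TrainingConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            seed=self.seed,
            early_stopping_patience=self.early_stopping_patience,
        )

        def sel(idx):
            if self._is_fused:
                return (inputs[0][idx], inputs[1][idx])
            return inputs[idx]

        self.history_ = fit_arrays(
            self.model_, sel(tr), y_idx[tr], sel(va), y_idx[va], tcfg
        )
        self._train_idx, self._val_idx = tr, va
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ContractError("classifier is not fitted")
        return self.model_.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def evaluation_report(self, X, y):
        """Confusion matrix + Pr/Re/Acc/IoU/Fm on labeled data."""
        y = np.asarray(y)
        proba = self.predict_proba(X)
        y_idx = np.searchsorted(self.classes_, y)
        loss = -np.mean(np.log(proba[np.arange(y.size), y_idx] + 1e-12))
        C = confusion(proba.argmax(axis=1), y_idx, num_classes=self.classes_.size)
        return evaluate(C, loss)
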