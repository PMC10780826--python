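"""The four classifier families and the transfer-learning backbone registry.

Families
--------
``dnn``
    flattened image (or backbone features) -> dense stack
    512-256-256-64-64-32 -> softmax(5);
``cnn``
    backbone ``none``: three Conv2D/LeakyReLU/MaxPool/BatchNorm/Dropout
    blocks with filter widths 1024, 512, 64, then Flatten -> softmax(5);
    with a backbone: frozen features -> dense(512) -> dense(256) ->
    softmax(5);
``dnn_lstm`` / ``cnn_lstm``
    the image branch's penultimate feature vector concatenated with an
    LSTM's final hidden state over the ordered GLCM feature sequence, then
    a dense softmax head; both branches train jointly.

Backbones are frozen feature extractors. ``tiny`` is a small seeded
random-weight CNN that needs no downloaded weights and is the offline
default; the registry also declares vgg16, vgg19, resnet50 and resnet101v2,
whose pretrained weights are not distributable here — requesting them
raises a weights-missing error that names ``tiny`` as the alternative.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import ConfigurationError, WeightsMissingError
from .nn import (
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    FusedNetwork,
    GlobalAveragePool2D,
    LeakyReLU,
    LSTM,
    MaxPool2D,
    Model,
    ReLU,
    Sequential,
)

#: The four model families.
FAMILIES = ("dnn", "cnn", "dnn_lstm", "cnn_lstm")

#: Hidden-layer widths of the dense classifier stack.
DNN_HIDDEN = (512, 256, 256, 64, 64, 32)

#: Filter widths of the three convolutional blocks.
CNN_FILTERS = (1024, 512, 64)

#: backbone name -> declared feature dimensionality (None = no backbone).
BACKBONE_FEATURES = {
    "none": None,
    "tiny": 64,
    "vgg16": 512,
    "vgg19": 512,
    "resnet50": 2048,
    "resnet101v2": 2048,
}

# Fixed seed for the tiny backbone so its (frozen) features are reproducible
# across processes and independent of the classifier seed.
_TINY_SEED = 20240135

ModelHandle = Model


@dataclass
class ArchitectureConfig:
    """Declarative description of one model; a model is reconstructible
    from this config plus its seed."""

    family: str = "cnn_lstm"
    backbone: str = "tiny"
    input_shape: tuple[int, int, int] = (50, 50, 3)
    num_classes: int = 5
    glcm_sequence_shape: tuple[int, int] = (8, 6)
    lstm_units: int = 64
    leaky_alpha: float = 0.3
    dropout_rate: float = 0.25
    seed: int = 0

    def __post_init__(self):
        self.input_shape = tuple(self.input_shape)
        self.glcm_sequence_shape = tuple(self.glcm_sequence_shape)
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.backbone not in BACKBONE_FEATURES:
            raise ConfigurationError(
                f"backbone must be one of {tuple(BACKBONE_FEATURES)}, got {self.backbone!r}"
            )
        if len(self.input_shape) != 3 or self.input_shape[2] != 3:
            raise ConfigurationError(f"input_shape must be (H, W, 3), got {self.input_shape}")
        if self.family.endswith("_lstm"):
            t, f = self.glcm_sequence_shape
            if t < 1:
                raise ConfigurationError("glcm sequence length must be >= 1")
            if f < 1:
                raise ConfigurationError("glcm feature width must be >= 1")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        d["glcm_sequence_shape"] = list(self.glcm_sequence_shape)
        return d


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

def _build_tiny_backbone(input_channels: int = 3) -> list:
    """A small fixed-random-weight CNN: 16-32-64 conv/pool, global-avg-pool."""
    rng = np.random.default_rng(_TINY_SEED)
    layers = [
        Conv2D(input_channels, 16, rng),
        LeakyReLU(0.3),
        MaxPool2D(),
        Conv2D(16, 32, rng),
        LeakyReLU(0.3),
        MaxPool2D(),
        Conv2D(32, 64, rng),
        LeakyReLU(0.3),
        GlobalAveragePool2D(),
    ]
    for layer in layers:
        layer.trainable = False  # frozen feature extractor
    return layers


def _backbone_layers(backbone: str) -> list:
    if backbone == "none":
        raise ConfigurationError("no backbone requested")
    if backbone == "tiny":
        return _build_tiny_backbone()
    raise WeightsMissingError(
        f"pretrained weights for backbone {backbone!r} are not available in "
        "this installation; use backbone='tiny' for an offline feature "
        "extractor with the same interface"
    )


def extract_backbone_features(images: np.ndarray, backbone: str) -> np.ndarray:
    """Frozen-backbone forward pass over a batch of (B, H, W, 3) images."""
    if backbone == "none":
        raise ConfigurationError("extract_backbone_features requires a backbone")
    net = Sequential(_backbone_layers(backbone))
    return net.forward(np.asarray(images, dtype=np.float64), training=False)


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------

def _dense_stack(in_features: int, rng) -> tuple[list, int]:
    layers = []
    fan = in_features
    for width in DNN_HIDDEN:
        layers += [Dense(fan, width, rng), ReLU()]
        fan = width
    return layers, fan


def _image_branch(config: ArchitectureConfig, rng) -> tuple[Sequential, int]:
    """The image-side feature extractor; returns (branch, feature dim)."""
    h, w, c = config.input_shape
    fam = "dnn" if config.family.startswith("dnn") else "cnn"
    if config.backbone == "none":
        if fam == "dnn":
            layers, dim = _dense_stack(h * w * c, rng)
            return Sequential([Flatten()] + layers), dim
        layers = []
        ch, hh, ww = c, h, w
        for width in CNN_FILTERS:
            layers += [
                Conv2D(ch, width, rng),
                LeakyReLU(config.leaky_alpha),
                MaxPool2D(),
                BatchNorm(width),
                Dropout(config.dropout_rate, rng),
            ]
            ch, hh, ww = width, hh // 2, ww // 2
        layers.append(Flatten())
        return Sequential(layers), hh * ww * ch
    feat = BACKBONE_FEATURES[config.backbone]
    base = _backbone_layers(config.backbone)
    if fam == "dnn":
        layers, dim = _dense_stack(feat, rng)
        return Sequential(base + layers), dim
    head = [
        Dense(feat, 512, rng),
        LeakyReLU(config.leaky_alpha),
        Dense(512, 256, rng),
        LeakyReLU(config.leaky_alpha),
    ]
    return Sequential(base + head), 256


def _lstm_branch(config: ArchitectureConfig, rng) -> tuple[Sequential, int]:
    t, f = config.glcm_sequence_shape
    return Sequential([LSTM(f, config.lstm_units, rng)]), config.lstm_units


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def build_dnn(config: ArchitectureConfig) -> Model:
    """Dense-stack image classifier (512-256-256-64-64-32 -> softmax)."""
    if config.family != "dnn":
        raise ConfigurationError(f"build_dnn requires family='dnn', got {config.family!r}")
    rng = np.random.default_rng(config.seed)
    branch, dim = _image_branch(config, rng)
    model = Sequential(
        branch.layers + [Dense(dim, config.num_classes, rng)], config.to_dict()
    )
    return model


def build_cnn(config: ArchitectureConfig) -> Model:
    """Convolutional image classifier (Table-style conv blocks or a frozen
    backbone with a dense head)."""
    if config.family != "cnn":
        raise ConfigurationError(f"build_cnn requires family='cnn', got {config.family!r}")
    rng = np.random.default_rng(config.seed)
    branch, dim = _image_branch(config, rng)
    return Sequential(
        branch.layers + [Dense(dim, config.num_classes, rng)], config.to_dict()
    )


def build_lstm_branch(config: ArchitectureConfig) -> Model:
    """Standalone LSTM classifier over the GLCM feature sequence."""
    if not config.family.endswith("_lstm"):
        raise ConfigurationError("build_lstm_branch requires an *_lstm family")
    rng = np.random.default_rng(config.seed)
    branch, dim = _lstm_branch(config, rng)
    return Sequential(
        branch.layers + [Dense(dim, config.num_classes, rng)], config.to_dict()
    )


def build_fused(config: ArchitectureConfig) -> Model:
    """Joint image + GLCM-sequence network with a concatenation fusion head."""
    if config.family not in ("dnn_lstm", "cnn_lstm"):
        raise ConfigurationError(
            f"build_fused requires family in ('dnn_lstm', 'cnn_lstm'), got {config.family!r}"
        )
    rng = np.random.default_rng(config.seed)
    image_branch, img_dim = _image_branch(config, rng)
    seq_branch, seq_dim = _lstm_branch(config, rng)
    head = Sequential([Dense(img_dim + seq_dim, config.num_classes, rng)])
    return FusedNetwork(image_branch, seq_branch, head, config.to_dict())


def build_model(config: ArchitectureConfig) -> Model:
    """Dispatch on the configured family."""
    if config.family == "dnn":
        return build_dnn(config)
    if config.family == "cnn":
        return build_cnn(config)
    return build_fused(config)
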