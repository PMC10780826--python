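"""Dataset expansion by the fixed five-transform augmentation policy.

Each source image yields exactly six outputs: the untouched original plus
one sample each of zoom (scale uniform in 1 +/- 0.3), rotation (angle
uniform in +/- 90 deg), horizontal flip, width shift (uniform in +/- 10% of
the width) and height shift (uniform in +/- 20% of the height). A 295-image
set therefore expands to exactly 1770 images. Vacated regions are filled by
nearest-edge replication so no artificial black borders enter the texture
statistics; all interpolation is bilinear, which keeps values inside the
input's tagged range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .datasets import LabeledDataset
from .exceptions import ContractError
from .image_io import RgbImage

TRANSFORM_NAMES = ("orig", "zoom", "rotate", "hflip", "wshift", "hshift")


@dataclass
class AugmentationPolicy:
    """The fixed augmentation policy: original + five stochastic variants."""

    zoom_range: float = 0.3
    rotation_max: float = 90.0
    horizontal_flip: bool = True
    width_shift_range: float = 0.1
    height_shift_range: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("zoom_range", "width_shift_range", "height_shift_range"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be non-negative")
        if not 0 <= self.rotation_max <= 360:
            raise ContractError("rotation_max must be in [0, 360] degrees")

    @property
    def variants_per_original(self) -> int:
        return len(TRANSFORM_NAMES)


def _zoom(px: np.ndarray, scale: float) -> np.ndarray:
    """Scale about the image center, keeping the original shape."""
    h, w = px.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    matrix = np.diag([1.0 / scale, 1.0 / scale, 1.0])
    offset = np.array([cy - cy / scale, cx - cx / scale, 0.0])
    return ndi.affine_transform(
        px, matrix, offset=offset, order=1, mode="nearest"
    )


def augment_image(
    image: RgbImage,
    policy: AugmentationPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> list[RgbImage]:
    """Produce the six policy outputs for one image.

    Element 0 is the untouched original; elements 1-5 are zoom, rotation,
    horizontal flip, width shift and height shift, in that order. Outputs
    keep the input shape and value range. With the same generator state the
    outputs are bit-identical.
    """
    policy = policy or AugmentationPolicy()
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    px = image.pixels
    h, w = image.height, image.width
    hi = 255.0 if image.value_range == "raw_0_255" else 1.0

    scale = rng.uniform(1.0 - policy.zoom_range, 1.0 + policy.zoom_range)
    angle = rng.uniform(-policy.rotation_max, policy.rotation_max)
    dx = rng.uniform(-policy.width_shift_range, policy.width_shift_range) * w
    dy = rng.uniform(-policy.height_shift_range, policy.height_shift_range) * h

    variants = [
        px.copy(),
        _zoom(px, scale),
        ndi.rotate(px, angle, axes=(1, 0), reshape=False, order=1, mode="nearest"),
        px[:, ::-1].copy() if policy.horizontal_flip else px.copy(),
        ndi.shift(px, (0.0, dx, 0.0), order=1, mode="nearest"),
        ndi.shift(px, (dy, 0.0, 0.0), order=1, mode="nearest"),
    ]
    out = []
    for name, v in zip(TRANSFORM_NAMES, variants):
        out.append(
            RgbImage(np.clip(v, 0.0, hi), image.value_range, f"{image.id}__{name}")
        )
    return out


def augment_dataset(
    data: LabeledDataset, policy: AugmentationPolicy | None = None
) -> LabeledDataset:
    """Expand a dataset sixfold; labels are copied to every variant.

    Provenance (source id, transform name) is recorded per output image in
    the returned dataset's ``provenance`` table. The input dataset is left
    unmodified.
    """
    if len(data) == 0:
        raise ContractError("cannot augment an empty dataset")
    policy = policy or AugmentationPolicy()
    rng = np.random.default_rng(policy.seed)
    images, labels, ids, prov = [], [], [], []
    for img, lab, iid in zip(data.images, data.labels, data.ids):
        for name, variant in zip(TRANSFORM_NAMES, augment_image(img, policy, rng)):
            images.append(variant)
            labels.append(lab)
            ids.append(variant.id)
            prov.append({"id": variant.id, "source": iid, "transform": name})
    return LabeledDataset(
        images,
        np.array(labels),
        ids,
        provenance=pd.DataFrame(prov),
    )
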