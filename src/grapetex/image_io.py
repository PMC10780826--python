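"""Reading, resizing and normalizing RGB leaf images.

All downstream stages consume the :class:`RgbImage` container defined here.
Pixel values live in one of two tagged ranges:

``raw_0_255``
    intensities as decoded from disk, floats in [0, 255];
``normalized_0_1``
    per-channel min-max scaled intensities in [0, 1].

Channel order is R, G, B at the API boundary regardless of the decoder.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .exceptions import ContractError, ImageFormatError

RAW = "raw_0_255"
NORMALIZED = "normalized_0_1"


@dataclass
class RgbImage:
    """An H x W x 3 intensity array with an explicit value-range tag.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array.
    value_range
        Either ``"raw_0_255"`` or ``"normalized_0_1"``.
    """

    pixels: np.ndarray
    value_range: str = RAW
    id: str = field(default="", compare=False)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ContractError(
                f"RgbImage requires an (H, W, 3) array, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < 2 or w < 2:
            raise ContractError(f"RgbImage requires H, W >= 2, got {h}x{w}")
        if self.value_range not in (RAW, NORMALIZED):
            raise ContractError(f"unknown value_range tag {self.value_range!r}")
        hi = 255.0 if self.value_range == RAW else 1.0
        lo, top = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or top > hi:
            raise ContractError(
                f"pixel values [{lo}, {top}] outside the {self.value_range} range"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def copy(self) -> "RgbImage":
        return RgbImage(self.pixels.copy(), self.value_range, self.id)


def load_image(path: str | os.PathLike) -> RgbImage:
    """Load a PNG/JPG/JPEG/TIFF image as a raw RGB image.

    Grayscale sources are replicated onto three identical channels; alpha
    channels are dropped.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ImageFormatError
        If the file content cannot be decoded as a raster image.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot decode image file: {path}") from exc
    return RgbImage(arr, RAW, id=os.path.splitext(os.path.basename(path))[0])


def save_image(image: RgbImage, path: str | os.PathLike) -> None:
    """Write an image as 8-bit PNG (values rescaled from its tagged range)."""
    px = image.pixels
    if image.value_range == NORMALIZED:
        px = px * 255.0
    arr = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(os.fspath(path))


def resize(image: RgbImage, target: tuple[int, int]) -> RgbImage:
    """Bilinearly resize to ``target = (H', W')``, preserving the value range.

    Resizing to the input's own shape is an exact identity.
    """
    th, tw = int(target[0]), int(target[1])
    if th < 2 or tw < 2:
        raise ContractError(f"resize target must be >= 2 in both axes, got {(th, tw)}")
    if (th, tw) == (image.height, image.width):
        return image.copy()
    out = _sk_resize(
        image.pixels,
        (th, tw, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    hi = 255.0 if image.value_range == RAW else 1.0
    return RgbImage(np.clip(out, 0.0, hi), image.value_range, image.id)


def normalize(image: RgbImage) -> RgbImage:
    """Per-channel min-max scaling ``x' = (x - min) / (max - min)``.

    A channel with ``max == min`` maps to all zeros. Double normalization is
    refused: the input must be tagged ``raw_0_255``.
    """
    if image.value_range == NORMALIZED:
        raise ContractError("image is already normalized; refusing to normalize twice")
    px = image.pixels
    mins = px.min(axis=(0, 1))
    maxs = px.max(axis=(0, 1))
    span = maxs - mins
    out = np.zeros_like(px)
    for c in range(3):
        if span[c] > 0:
            out[:, :, c] = (px[:, :, c] - mins[c]) / span[c]
    return RgbImage(out, NORMALIZED, image.id)
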