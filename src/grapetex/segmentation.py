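"""Leaf/background separation by grayscale thresholding.

The leaf is isolated by converting to luminance grayscale and thresholding,
producing a binary mask (1 = grapevine pixel, 0 = background). Otsu's method
is the default threshold rule; a manual intensity threshold and the
foreground polarity (darker or brighter side) are explicit options, since
field images put leaves on backgrounds of either kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import binary_closing, binary_opening, footprint_rectangle

from .exceptions import ContractError, DegenerateHistogramError
from .image_io import RgbImage

#: ITU-R BT.601 luminance weights.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class BinaryMask:
    """An H x W array with entries in {0, 1}; 1 marks grapevine pixels."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ContractError(f"mask must be 2-D, got shape {m.shape}")
        if not np.isin(m, (0, 1)).all():
            raise ContractError("mask entries must be exactly 0 or 1")
        self.mask = m.astype(np.uint8)

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def to_grayscale(image: RgbImage | np.ndarray) -> np.ndarray:
    """Luminance grayscale ``0.299 R + 0.587 G + 0.114 B`` as a float array."""
    px = image.pixels if isinstance(image, RgbImage) else np.asarray(image, float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ContractError(f"expected an (H, W, 3) array, got shape {px.shape}")
    return px @ LUMA_WEIGHTS


def threshold_segment(
    gray: np.ndarray,
    threshold: float | str = "otsu",
    foreground: str = "dark",
    cleanup: bool = False,
) -> BinaryMask:
    """Threshold a grayscale image into a leaf-foreground binary mask.

    Parameters
    ----------
    gray
        Single-channel image.
    threshold
        A manual intensity, or ``"otsu"`` to maximize between-class variance.
    foreground
        ``"dark"`` (default; leaf darker than background) selects pixels
        strictly below the threshold; ``"bright"`` selects pixels at or above.
    cleanup
        Apply a light morphological opening+closing (3x3) to the mask.
        Off by default.

    Raises
    ------
    DegenerateHistogramError
        With ``"otsu"`` on a constant image, where no threshold exists;
        supply a manual threshold instead.
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise ContractError(f"grayscale image must be 2-D, got shape {g.shape}")
    if foreground not in ("dark", "bright"):
        raise ContractError(f"foreground must be 'dark' or 'bright', got {foreground!r}")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ContractError(f"unknown threshold mode {threshold!r}")
        if np.ptp(g) == 0:
            raise DegenerateHistogramError(
                "constant image: Otsu's method is undefined on a single-bin "
                "histogram; pass a manual threshold"
            )
        t = float(threshold_otsu(g))
    else:
        t = float(threshold)
    m = (g < t) if foreground == "dark" else (g >= t)
    if cleanup:
        fp = footprint_rectangle((3, 3))
        m = binary_closing(binary_opening(m, fp), fp)
    return BinaryMask(m.astype(np.uint8))


def apply_mask(image: RgbImage, mask: BinaryMask) -> RgbImage:
    """Zero out background pixels in all channels; foreground is untouched."""
    if mask.shape != (image.height, image.width):
        raise ContractError(
            f"shape mismatch: image {(image.height, image.width)} vs mask {mask.shape}"
        )
    out = image.pixels * mask.mask[:, :, None]
    return RgbImage(out, image.value_range, image.id)


def save_mask(mask: BinaryMask, path: str) -> None:
    """Write a mask as a single-channel PNG with values {0, 255}."""
    from PIL import Image

    Image.fromarray(mask.mask * np.uint8(255), mode="L").save(path)
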