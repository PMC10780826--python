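"""Gray-level co-occurrence matrices and Haralick-style texture statistics.

A GLCM tabulates how often a pair of quantized gray levels ``(i, j)``
co-occurs at a fixed pixel displacement. Six statistics are derived from the
normalized matrix ``P``:

    contrast       = sum P_ij (i - j)^2
    dissimilarity  = sum P_ij |i - j|
    homogeneity    = sum P_ij / (1 + (i - j)^2)
    ASM            = sum P_ij^2            (angular second moment)
    energy         = sqrt(ASM)
    correlation    = sum P_ij (i - mu_i)(j - mu_j) / (sigma_i sigma_j)

with ``mu``/``sigma`` the marginal means and standard deviations. When
``sigma_i sigma_j = 0`` (a constant region) correlation is defined as 1 —
a constant region is perfectly self-correlated, and the convention keeps
NaNs out of downstream feature sequences.

Angles follow the usual image convention for a (row, col) grid: an offset of
distance ``d`` at 0 deg is ``(0, +d)`` (horizontal), 45 deg is ``(-d, +d)``,
90 deg is ``(-d, 0)`` (vertical) and 135 deg is ``(-d, -d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractError, EmptyPairError
from .segmentation import BinaryMask

FEATURE_NAMES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "energy",
    "correlation",
)

#: Default offsets for feature sequences: distances {1, 2} x four angles.
DEFAULT_OFFSETS = tuple(
    (d, a) for d in (1, 2) for a in (0, 45, 90, 135)
)

_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class CoMatrix:
    """A normalized N x N co-occurrence probability matrix for one offset."""

    P: np.ndarray
    levels: int
    offset: tuple[int, int]  # (distance, angle in degrees)
    symmetric: bool = True

    def __post_init__(self):
        P = np.asarray(self.P, dtype=np.float64)
        if P.shape != (self.levels, self.levels):
            raise ContractError(
                f"P must be {self.levels}x{self.levels}, got {P.shape}"
            )
        if (P < 0).any():
            raise ContractError("co-occurrence probabilities must be non-negative")
        if abs(P.sum() - 1.0) > 1e-12:
            raise ContractError(f"P must sum to 1, got {P.sum()!r}")
        self.P = P


@dataclass
class TextureFeatures:
    """The six GLCM statistics for one image/region/offset."""

    contrast: float
    dissimilarity: float
    homogeneity: float
    asm: float
    energy: float
    correlation: float
    mean_i: float = 0.0
    mean_j: float = 0.0
    std_i: float = 0.0
    std_j: float = 0.0

    def as_vector(self) -> np.ndarray:
        """The features in the canonical order of :data:`FEATURE_NAMES`."""
        return np.array(
            [
                self.contrast,
                self.dissimilarity,
                self.homogeneity,
                self.asm,
                self.energy,
                self.correlation,
            ]
        )


def offset_step(offset: tuple[int, int]) -> tuple[int, int]:
    """Convert a (distance, angle-degrees) offset to a (drow, dcol) step."""
    distance, angle = offset
    if distance < 1:
        raise ContractError(f"offset distance must be >= 1, got {distance}")
    if angle not in _ANGLE_STEPS:
        raise ContractError(f"angle must be one of {sorted(_ANGLE_STEPS)}, got {angle}")
    dr, dc = _ANGLE_STEPS[angle]
    return dr * distance, dc * distance


def quantize(gray: np.ndarray, levels: int = 32) -> np.ndarray:
    """Uniformly bin a [0, 255] grayscale image into ``levels`` gray levels.

    Returns an integer image with values in ``{0, ..., levels - 1}`` via
    ``floor(x * levels / 256)``.
    """
    if levels < 2:
        raise ContractError(f"levels must be >= 2, got {levels}")
    g = np.asarray(gray, dtype=np.float64)
    if g.min() < 0 or g.max() > 255:
        raise ContractError("grayscale values must lie in [0, 255]")
    q = np.floor(g * levels / 256.0).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    q: np.ndarray,
    offset: tuple[int, int] = (1, 0),
    levels: int | None = None,
    symmetric: bool = True,
    mask: BinaryMask | np.ndarray | None = None,
) -> CoMatrix:
    """Count level co-occurrences at one displacement and normalize.

    Ordered pairs ``(reference, neighbor)`` at the given ``(distance, angle)``
    displacement are counted; in symmetric mode the transposed counts are
    added before normalization. With a mask, only pairs whose *both* pixels
    are foreground contribute.

    Raises
    ------
    EmptyPairError
        If no valid pixel pair exists (image smaller than the offset, or the
        mask excludes every pair).
    """
    q = np.asarray(q)
    if q.ndim != 2:
        raise ContractError(f"quantized image must be 2-D, got shape {q.shape}")
    n = int(levels) if levels is not None else int(q.max()) + 1
    if q.min() < 0 or q.max() >= n:
        raise ContractError(f"quantized values must lie in [0, {n - 1}]")
    dr, dc = offset_step(offset)
    h, w = q.shape

    # Reference window and its displaced neighbor window.
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise EmptyPairError(
            f"image of shape {q.shape} admits no pair at offset {offset}"
        )
    ref = q[r0:r1, c0:c1]
    nbr = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]

    if mask is not None:
        m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask)
        if m.shape != q.shape:
            raise ContractError(f"mask shape {m.shape} != image shape {q.shape}")
        valid = (m[r0:r1, c0:c1] > 0) & (m[r0 + dr : r1 + dr, c0 + dc : c1 + dc] > 0)
        ref, nbr = ref[valid], nbr[valid]
        if ref.size == 0:
            raise EmptyPairError(f"mask excludes every pixel pair at offset {offset}")

    counts = np.bincount(
        (ref.ravel() * n + nbr.ravel()), minlength=n * n
    ).reshape(n, n).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return CoMatrix(counts / counts.sum(), n, tuple(offset), symmetric)


def texture_features(M: CoMatrix) -> TextureFeatures:
    """Evaluate the six texture statistics of a co-occurrence matrix."""
    P = M.P
    n = M.levels
    i = np.arange(n, dtype=np.float64)[:, None]
    j = np.arange(n, dtype=np.float64)[None, :]
    diff = i - j

    contrast = float((P * diff**2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    asm = float((P**2).sum())
    energy = float(np.sqrt(asm))

    pi = P.sum(axis=1)  # marginal over rows (reference pixel)
    pj = P.sum(axis=0)
    lv = np.arange(n, dtype=np.float64)
    mu_i = float(pi @ lv)
    mu_j = float(pj @ lv)
    var_i = float(pi @ (lv - mu_i) ** 2)
    var_j = float(pj @ (lv - mu_j) ** 2)
    std_i, std_j = np.sqrt(var_i), np.sqrt(var_j)
    denom = std_i * std_j
    if denom == 0.0:
        correlation = 1.0  # constant region: perfectly self-correlated
    else:
        cov = float((P * (i - mu_i) * (j - mu_j)).sum())
        correlation = cov / denom

    return TextureFeatures(
        contrast, dissimilarity, homogeneity, asm, energy, correlation,
        mu_i, mu_j, float(std_i), float(std_j),
    )


def glcm_features(
    gray: np.ndarray,
    offset: tuple[int, int] = (1, 0),
    levels: int = 32,
    symmetric: bool = True,
    mask: BinaryMask | np.ndarray | None = None,
) -> TextureFeatures:
    """Convenience: quantize, count, and evaluate in one call."""
    q = quantize(gray, levels)
    return texture_features(compute_glcm(q, offset, levels, symmetric, mask))


def glcm_sequence(
    q: np.ndarray,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int | None = None,
    symmetric: bool = True,
    mask: BinaryMask | np.ndarray | None = None,
) -> np.ndarray:
    """An ordered (n_offsets, 6) feature sequence for the LSTM branch.

    One six-feature vector per offset, in the order the offsets are given.
    The default offsets are distances {1, 2} crossed with the four angles,
    giving a length-8 sequence.
    """
    if len(offsets) == 0:
        raise ContractError("at least one offset is required")
    rows = [
        texture_features(
            compute_glcm(q, off, levels, symmetric, mask)
        ).as_vector()
        for off in offsets
    ]
    return np.stack(rows)


def texture_map(
    gray: np.ndarray,
    window: int = 7,
    offset: tuple[int, int] = (1, 0),
    levels: int = 32,
    symmetric: bool = True,
) -> dict[str, np.ndarray]:
    """Per-pixel texture maps: one image per statistic.

    Each output pixel holds the statistic of the GLCM of the ``window`` x
    ``window`` neighborhood centered on it; edges use reflected padding.
    Quantization is global, so window statistics are comparable across the
    image.
    """
    if window < 3 or window % 2 == 0:
        raise ContractError(f"window must be odd and >= 3, got {window}")
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise ContractError(f"grayscale image must be 2-D, got shape {g.shape}")
    q = quantize(g, levels)
    pad = window // 2
    qp = np.pad(q, pad, mode="reflect")
    h, w = g.shape
    out = {name: np.empty((h, w)) for name in FEATURE_NAMES}
    for y in range(h):
        for x in range(w):
            win = qp[y : y + window, x : x + window]
            feats = texture_features(compute_glcm(win, offset, levels, symmetric))
            vec = feats.as_vector()
            for k, name in enumerate(FEATURE_NAMES):
                out[name][y, x] = vec[k]
    return out
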