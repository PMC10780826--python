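"""Dataset container, label encoding, 80/20 splitting, and a synthetic
five-class leaf-image generator.

The five grapevine classes are encoded 0-4 in fixed alphabetical order:

    0 black_rot, 1 chlorosis, 2 esca, 3 healthy, 4 powdery_mildew

The synthetic generator draws an elliptical "leaf" on a near-white
background, with class-specific texture/color signatures chosen so the
classes differ in their GLCM statistics:

* ``healthy`` — mid-green leaf with moderate smooth (low-frequency) shading;
* ``chlorosis`` — yellow-shifted, very smooth (lowest contrast);
* ``esca`` — vertical stripe pattern of period 4 px: contrast is high for
  horizontal (0 deg) offsets and low for vertical (90 deg) ones;
* ``black_rot`` — green leaf peppered with dark necrotic speckle
  (Bernoulli p = 0.25), the highest distance-1 contrast;
* ``powdery_mildew`` — pale whitish-green with low-amplitude per-pixel
  (high-frequency) noise.

Every image comes with its ground-truth foreground mask, and the whole
dataset is a deterministic function of the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import CannotSplitError, ContractError
from .image_io import RgbImage, load_image, save_image
from .segmentation import BinaryMask, save_mask

CLASS_NAMES = ("black_rot", "chlorosis", "esca", "healthy", "powdery_mildew")
NUM_CLASSES = len(CLASS_NAMES)
_NAME_TO_CODE = {n: i for i, n in enumerate(CLASS_NAMES)}

TRAIN, VALIDATION = "train", "validation"


def label_code(name: str) -> int:
    """Integer code (0-4) for a class name."""
    try:
        return _NAME_TO_CODE[name]
    except KeyError:
        raise ContractError(f"unknown class {name!r}; expected one of {CLASS_NAMES}")


def label_name(code: int) -> str:
    if not 0 <= code < NUM_CLASSES:
        raise ContractError(f"class code must be in 0..{NUM_CLASSES - 1}, got {code}")
    return CLASS_NAMES[code]


def one_hot(labels: np.ndarray, num_classes: int = NUM_CLASSES) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.intp)
    out = np.zeros((labels.size, num_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


@dataclass
class LabeledDataset:
    """Images with class labels, unique ids, and optional split tags."""

    images: list[RgbImage]
    labels: np.ndarray  # integer codes
    ids: list[str]
    split: list[str] | None = None  # per-item "train" / "validation"
    masks: list[BinaryMask] | None = None
    provenance: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        n = len(self.images)
        if not (len(self.labels) == len(self.ids) == n):
            raise ContractError("images, labels and ids must have equal length")
        if len(set(self.ids)) != n:
            raise ContractError("ids must be unique")
        if self.split is not None:
            if len(self.split) != n:
                raise ContractError("split tags must cover every item")
            bad = set(self.split) - {TRAIN, VALIDATION}
            if bad:
                raise ContractError(f"unknown split tags {bad}")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return LabeledDataset(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            ids=[self.ids[i] for i in idx],
            split=[self.split[i] for i in idx] if self.split else None,
            masks=[self.masks[i] for i in idx] if self.masks else None,
        )

    def split_indices(self, tag: str) -> np.ndarray:
        if self.split is None:
            raise ContractError("dataset has no split assignment")
        return np.array([i for i, s in enumerate(self.split) if s == tag], dtype=np.intp)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=NUM_CLASSES)


def split_dataset(
    data: LabeledDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> LabeledDataset:
    """Assign train/validation tags by a seeded shuffle.

    The train count is ``floor(train_fraction * n)``; the remainder is
    validation. This reproduces 1770 -> 1416/354 and 295 -> 236/59. The
    counts depend only on ``n`` and the fraction, never on the seed.
    """
    n = len(data)
    if n < 2:
        raise CannotSplitError(f"cannot split a dataset of size {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ContractError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    tags = np.empty(n, dtype=object)
    if stratified:
        for c in np.unique(data.labels):
            idx = np.flatnonzero(data.labels == c)
            perm = rng.permutation(idx)
            k = int(np.floor(train_fraction * idx.size))
            tags[perm[:k]] = TRAIN
            tags[perm[k:]] = VALIDATION
        # stratified flooring can undershoot the global floor; leave as-is
    else:
        perm = rng.permutation(n)
        k = int(np.floor(train_fraction * n))
        tags[perm[:k]] = TRAIN
        tags[perm[k:]] = VALIDATION
    return LabeledDataset(
        images=data.images,
        labels=data.labels,
        ids=list(data.ids),
        split=list(tags),
        masks=data.masks,
    )


# ---------------------------------------------------------------------------
# Synthetic leaf generator
# ---------------------------------------------------------------------------

# Per-class recipe: (base RGB, smooth-noise sigma, smooth amplitude,
# pixel-noise amplitude). Stripes/speckle are handled separately.
_CLASS_RECIPES = {
    "healthy": ((70, 145, 75), 3.0, 25.0, 0.0),
    "chlorosis": ((205, 195, 90), 5.0, 10.0, 0.0),
    "esca": ((120, 110, 60), 0.0, 0.0, 3.0),
    "black_rot": ((100, 140, 90), 0.0, 0.0, 5.0),
    "powdery_mildew": ((185, 200, 185), 0.0, 0.0, 12.0),
}
_BACKGROUND_LEVEL = 245.0
_SPECKLE_P = 0.25
_SPECKLE_RGB = (40, 30, 20)
_STRIPE_PERIOD = 4
_STRIPE_AMP = 55.0


def _leaf_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    a = 0.40 * size * rng.uniform(0.95, 1.05)  # semi-axis along x
    b = 0.32 * size * rng.uniform(0.95, 1.05)  # semi-axis along y
    return (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0).astype(np.uint8)


def _synth_image(class_name: str, size: int, rng: np.random.Generator) -> tuple[RgbImage, BinaryMask]:
    base_rgb, sigma, smooth_amp, pix_amp = _CLASS_RECIPES[class_name]
    mask = _leaf_mask(size, rng)

    img = _BACKGROUND_LEVEL + rng.normal(0.0, 2.0, (size, size, 3))
    leaf = np.empty((size, size, 3))
    leaf[:] = base_rgb
    if smooth_amp > 0:
        field2d = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma)
        field2d /= max(field2d.std(), 1e-9)
        leaf += smooth_amp * field2d[:, :, None]
    if pix_amp > 0:
        leaf += pix_amp * rng.normal(0.0, 1.0, (size, size))[:, :, None]
    if class_name == "esca":
        xx = np.arange(size)
        stripe = np.where((xx // (_STRIPE_PERIOD // 2)) % 2 == 0, 1.0, -1.0)
        leaf += _STRIPE_AMP * stripe[None, :, None]
    if class_name == "black_rot":
        spots = rng.random((size, size)) < _SPECKLE_P
        leaf[spots] = np.array(_SPECKLE_RGB, dtype=float)

    img = np.where(mask[:, :, None] > 0, leaf, img)
    img = np.clip(img, 0.0, 255.0)
    return RgbImage(img), BinaryMask(mask)


def generate_synthetic_dataset(
    n_per_class: int = 20,
    image_size: int = 64,
    seed: int = 0,
    class_counts: dict[str, int] | None = None,
) -> LabeledDataset:
    """Generate a labeled five-class synthetic leaf dataset with true masks.

    Parameters
    ----------
    n_per_class
        Images per class (>= 1); ignored when ``class_counts`` is given.
    image_size
        Square image side in pixels (>= 32).
    seed
        Every pixel is a deterministic function of this seed.
    class_counts
        Optional per-class counts, e.g. to mimic an imbalanced survey.
    """
    if image_size < 32:
        raise ContractError(f"image_size must be >= 32, got {image_size}")
    counts = class_counts or {name: n_per_class for name in CLASS_NAMES}
    if any(c < 1 for c in counts.values()):
        raise ContractError("every class count must be >= 1")
    unknown = set(counts) - set(CLASS_NAMES)
    if unknown:
        raise ContractError(f"unknown classes {unknown}")

    rng = np.random.default_rng(seed)
    images: list[RgbImage] = []
    masks: list[BinaryMask] = []
    labels: list[int] = []
    ids: list[str] = []
    for name in CLASS_NAMES:  # fixed order => seed-determinism
        for k in range(counts.get(name, 0)):
            img, msk = _synth_image(name, image_size, rng)
            img.id = f"{name}_{k:04d}"
            images.append(img)
            masks.append(msk)
            labels.append(label_code(name))
            ids.append(img.id)
    return LabeledDataset(images, np.array(labels), ids, masks=masks)


# ---------------------------------------------------------------------------
# Disk layout: directory-per-class image tree + manifest CSV
# ---------------------------------------------------------------------------

def save_dataset(data: LabeledDataset, out_dir: str, write_masks: bool = False) -> str:
    """Write a dataset as ``<out_dir>/<class>/<id>.png`` plus manifest.csv.

    The layout mirrors a directory-per-class survey tree so real imagery can
    be dropped in unchanged. Returns the manifest path.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (img, lab, iid) in enumerate(zip(data.images, data.labels, data.ids)):
        cname = label_name(lab)
        cdir = os.path.join(out_dir, cname)
        os.makedirs(cdir, exist_ok=True)
        rel = os.path.join(cname, f"{iid}.png")
        save_image(img, os.path.join(out_dir, rel))
        if write_masks and data.masks is not None:
            os.makedirs(os.path.join(out_dir, "_masks", cname), exist_ok=True)
            save_mask(data.masks[i], os.path.join(out_dir, "_masks", cname, f"{iid}.png"))
        rows.append(
            {
                "id": iid,
                "path": rel,
                "label": cname,
                "split": data.split[i] if data.split else "",
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(in_dir: str) -> LabeledDataset:
    """Load a dataset written by :func:`save_dataset` (or a matching tree)."""
    manifest = os.path.join(in_dir, "manifest.csv")
    if os.path.exists(manifest):
        df = pd.read_csv(manifest, keep_default_na=False)
    else:  # fall back to scanning the class directories
        rows = []
        for cname in CLASS_NAMES:
            cdir = os.path.join(in_dir, cname)
            if not os.path.isdir(cdir):
                continue
            for fn in sorted(os.listdir(cdir)):
                if fn.lower().endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff")):
                    rows.append(
                        {
                            "id": f"{cname}/{os.path.splitext(fn)[0]}",
                            "path": os.path.join(cname, fn),
                            "label": cname,
                            "split": "",
                        }
                    )
        if not rows:
            raise ContractError(f"no images found under {in_dir}")
        df = pd.DataFrame(rows)
    images, labels, ids, split = [], [], [], []
    for _, row in df.iterrows():
        img = load_image(os.path.join(in_dir, row["path"]))
        img.id = str(row["id"])
        images.append(img)
        labels.append(label_code(row["label"]))
        ids.append(str(row["id"]))
        split.append(str(row["split"]) if row["split"] else None)
    has_split = all(s in (TRAIN, VALIDATION) for s in split)
    return LabeledDataset(
        images, np.array(labels), ids, split=split if has_split else None
    )
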