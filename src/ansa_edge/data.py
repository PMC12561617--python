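"""Dataset loading, augmentation, and split protocols.

Supported inputs:

* one-folder-per-class directories of JPEG/PNG slices (the common Kaggle
  brain-MRI layout),
* per-slice HDF5 ``.mat`` containers with a ``cjdata`` group holding the
  patient ID, image array, numeric label, tumor border and tumor mask (the
  figshare T1-CE layout),
* the synthetic phantom generator in :mod:`ansa_edge.synthetic`.

All images are converted to single-channel float arrays in [0, 1] and
resized to ``input_size`` x ``input_size``.

The augmentation stage applies exactly one of seven geometric transforms
(vertical flip, horizontal flip, rotation up to +-90 deg, width/height shift
up to 10%, zoom up to +-20%, shear up to +-0.2), chosen uniformly per image,
and appends the transformed copy — doubling the image count.  Splits are
either a random 70-10-20 holdout or five-fold partitions, both seeded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "LabeledImage", "AugmentationSpec", "SplitSpec", "HoldoutPartition",
    "KFoldPartition", "read_image_folder", "read_cheng_mat", "augment_double",
    "split", "UnsupportedMatFormatError", "TRANSFORM_NAMES",
]

logger = logging.getLogger(__name__)

CHENG_LABEL_NAMES = {1: "meningioma", 2: "glioma", 3: "pituitary"}


class UnsupportedMatFormatError(RuntimeError):
    """Raised for legacy (pre-v7.3, non-HDF5) MATLAB containers."""


@dataclass
class LabeledImage:
    pixels: np.ndarray                     # (H, W) float in [0, 1]
    label: int
    label_name: str = ""
    blob_mask: np.ndarray | None = None    # (H, W) bool, synthetic ground truth
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")


def _normalize01(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(float)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def _resize(arr: np.ndarray, size: int) -> np.ndarray:
    if arr.shape == (size, size):
        return arr
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(im.resize((size, size), Image.BILINEAR), dtype=float)


def read_image_folder(root: str | Path, input_size: int = 256) -> list[LabeledImage]:
    """Read a one-subdirectory-per-class tree of JPEG/PNG files.

    Class labels follow the lexicographic order of the subdirectory names;
    files are read in lexicographic order, so re-reads are deterministic.
    Unreadable files are skipped with a logged count.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    images: list[LabeledImage] = []
    skipped = 0
    for label, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in (".jpg", ".jpeg", ".png"))
        if not files:
            warnings.warn(f"class directory {cdir.name!r} is empty")
        for path in files:
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im.convert("L"), dtype=float) / 255.0
            except OSError:
                skipped += 1
                continue
            images.append(LabeledImage(pixels=_resize(arr, input_size), label=label,
                                       label_name=cdir.name, source_id=str(path)))
    if skipped:
        logger.warning("skipped %d unreadable files under %s", skipped, root)
    return images


def read_cheng_mat(root: str | Path, input_size: int = 256,
                   label_names: dict[int, str] | None = None) -> list[LabeledImage]:
    """Read per-slice HDF5 ``.mat`` containers (``cjdata`` group).

    Labels follow the dataset convention 1 = meningioma, 2 = glioma,
    3 = pituitary (overridable); the stored label is remapped to a 0-based
    class id (label - 1).  A missing tumor mask is tolerated — it is not used
    for classification.
    """
    root = Path(root)
    label_names = label_names or CHENG_LABEL_NAMES
    files = sorted(root.glob("*.mat"))
    images: list[LabeledImage] = []
    for path in files:
        try:
            f = h5py.File(path, "r")
        except OSError as exc:
            raise UnsupportedMatFormatError(
                f"{path.name}: not an HDF5 container (legacy v7 .mat files "
                f"are unsupported; re-save as v7.3)") from exc
        with f:
            if "cjdata" not in f:
                raise ValueError(f"{path.name}: missing 'cjdata' group")
            cj = f["cjdata"]
            for field_name in ("image", "label"):
                if field_name not in cj:
                    raise ValueError(f"{path.name}: missing field cjdata/{field_name}")
            arr = np.asarray(cj["image"], dtype=float)
            raw_label = int(np.asarray(cj["label"]).ravel()[0])
            pid = ""
            if "PID" in cj:
                pid_arr = np.asarray(cj["PID"]).ravel()
                pid = "".join(chr(int(c)) for c in pid_arr)
            mask = None
            if "tumorMask" in cj:
                mask_arr = np.asarray(cj["tumorMask"]).astype(bool)
                mask = _resize(mask_arr.astype(float), input_size) > 0.5
        images.append(LabeledImage(
            pixels=_resize(_normalize01(arr), input_size),
            label=raw_label - 1,
            label_name=label_names.get(raw_label, str(raw_label)),
            blob_mask=mask,
            source_id=pid or path.stem,
        ))
    return images


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

TRANSFORM_NAMES = ("vertical_flip", "horizontal_flip", "rotation",
                   "width_shift", "height_shift", "zoom", "shear")


@dataclass(frozen=True)
class AugmentationSpec:
    """The seven-transform schedule: flips, rotation by an angle drawn in
    [-rotation_limit, +rotation_limit] degrees, shifts up to a fraction of
    the image side, zoom in [1-zoom, 1+zoom], shear in [-shear, +shear]."""
    rotation_limit: float = 90.0
    width_shift: float = 0.1
    height_shift: float = 0.1
    zoom: float = 0.2
    shear: float = 0.2
    seed: int = 0


def _affine(img: np.ndarray, matrix: np.ndarray, order: int) -> np.ndarray:
    c = (np.asarray(img.shape, dtype=float) - 1) / 2.0
    offset = c - matrix @ c
    return ndimage.affine_transform(img, matrix, offset=offset, order=order,
                                    mode="nearest")


def _apply_transform(img: np.ndarray, name: str, params: dict,
                     order: int = 1) -> np.ndarray:
    if name == "vertical_flip":
        return img[::-1].copy()
    if name == "horizontal_flip":
        return img[:, ::-1].copy()
    if name == "rotation":
        return ndimage.rotate(img, params["angle"], reshape=False, order=order,
                              mode="nearest")
    if name == "width_shift":
        return ndimage.shift(img, (0.0, params["shift"]), order=order, mode="nearest")
    if name == "height_shift":
        return ndimage.shift(img, (params["shift"], 0.0), order=order, mode="nearest")
    if name == "zoom":
        z = params["factor"]
        return _affine(img, np.diag([1.0 / z, 1.0 / z]), order)
    if name == "shear":
        return _affine(img, np.array([[1.0, params["factor"]], [0.0, 1.0]]), order)
    raise ValueError(f"unknown transformation {name!r}")


def _draw_params(name: str, spec: AugmentationSpec, rng: np.random.Generator,
                 side: int) -> dict:
    if name == "rotation":
        return {"angle": rng.uniform(-spec.rotation_limit, spec.rotation_limit)}
    if name == "width_shift":
        return {"shift": rng.uniform(-spec.width_shift, spec.width_shift) * side}
    if name == "height_shift":
        return {"shift": rng.uniform(-spec.height_shift, spec.height_shift) * side}
    if name == "zoom":
        return {"factor": rng.uniform(1.0 - spec.zoom, 1.0 + spec.zoom)}
    if name == "shear":
        return {"factor": rng.uniform(-spec.shear, spec.shear)}
    return {}


def augment_double(images: list[LabeledImage],
                   spec: AugmentationSpec | None = None) -> list[LabeledImage]:
    """Return originals plus exactly one transformed copy per original
    (uniform choice among the seven transforms), doubling the count."""
    if not images:
        raise ValueError("augment_double requires a nonempty image list")
    spec = spec or AugmentationSpec()
    rng = np.random.default_rng(spec.seed)
    augmented: list[LabeledImage] = []
    for im in images:
        name = TRANSFORM_NAMES[rng.integers(len(TRANSFORM_NAMES))]
        params = _draw_params(name, spec, rng, im.pixels.shape[0])
        pixels = np.clip(_apply_transform(im.pixels, name, params, order=1), 0.0, 1.0)
        mask = im.blob_mask
        if mask is not None:
            mask = _apply_transform(mask.astype(float), name, params, order=0) > 0.5
        augmented.append(replace(im, pixels=pixels, blob_mask=mask,
                                 source_id=f"{im.source_id}+aug:{name}"))
    return list(images) + augmented


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    mode: str = "holdout_70_10_20"
    seed: int = 0
    stratified: bool = False

    def __post_init__(self):
        if self.mode not in ("holdout_70_10_20", "kfold_5"):
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass
class HoldoutPartition:
    train: list
    val: list
    test: list

    def __iter__(self):
        return iter((self.train, self.val, self.test))


@dataclass
class KFoldPartition:
    folds: list  # five disjoint lists

    def iterate(self):
        """Yield (train, test) pairs, each fold serving as test once."""
        for i, test in enumerate(self.folds):
            train = [im for j, f in enumerate(self.folds) for im in f if j != i]
            yield train, test


def _holdout_indices(n: int, rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    perm = rng.permutation(n)
    n_train, n_val = int(0.7 * n), int(0.1 * n)
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def split(images: list[LabeledImage], spec: SplitSpec):
    """Partition a dataset per the declared protocol.

    Holdout sizes are (floor(0.7 n), floor(0.1 n), remainder); five-fold
    partitions differ in size by at most one.  Both are exhaustive, disjoint,
    and reproducible from ``spec.seed``.
    """
    n = len(images)
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "holdout_70_10_20":
        if n < 10:
            raise ValueError(f"holdout split needs at least 10 images, got {n}")
        if spec.stratified:
            labels = sorted({im.label for im in images})
            parts = ([], [], [])
            for lab in labels:
                idx = np.array([i for i, im in enumerate(images) if im.label == lab])
                tr, va, te = _holdout_indices(len(idx), rng)
                for part, sel in zip(parts, (tr, va, te)):
                    part.extend(images[i] for i in idx[sel])
            return HoldoutPartition(*parts)
        tr, va, te = _holdout_indices(n, rng)
        return HoldoutPartition([images[i] for i in tr], [images[i] for i in va],
                                [images[i] for i in te])
    # five-fold
    if n < 5:
        raise ValueError(f"five-fold split needs at least 5 images, got {n}")
    if spec.stratified:
        folds: list[list] = [[] for _ in range(5)]
        offset = 0
        for lab in sorted({im.label for im in images}):
            idx = np.array([i for i, im in enumerate(images) if im.label == lab])
            perm = rng.permutation(len(idx))
            for j, p in enumerate(perm):
                folds[(offset + j) % 5].append(images[idx[p]])
            offset += len(idx)
        return KFoldPartition(folds)
    perm = rng.permutation(n)
    folds = [[images[i] for i in perm[k::5]] for k in range(5)]
    return KFoldPartition(folds)


def to_arrays(images: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack images into a (N, 1, H, W) batch and an integer label vector."""
    x = np.stack([im.pixels for im in images])[:, None, :, :]
    y = np.array([im.label for im in images], dtype=int)
    return x, y
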