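"""Synthetic brain-phantom image generator.

Produces grayscale head phantoms that emulate the coarse statistics of
axial brain MRI slices: an elliptical "head" with smooth low-amplitude
texture, and for tumor classes a single bright elliptical blob whose
position, eccentricity and texture are class-distinct:

* class 0 ("meningioma-like"): round smooth blob in the upper-left quadrant,
* class 1 ("glioma-like"): elongated, mildly textured blob, lower-right,
* class 2 ("pituitary-like"): high-eccentricity central blob,
* class 3 ("no tumor", 4-class mode only): no blob.

Each tumor image carries its ground-truth blob mask, used to score
explainability (does the saliency peak fall inside the blob?).  Generation
is fully deterministic given the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import LabeledImage

__all__ = ["generate_synthetic_dataset", "save_synthetic_dataset", "CLASS_NAMES"]

CLASS_NAMES = ("meningioma_like", "glioma_like", "pituitary_like", "no_tumor")

# per-class blob geometry and appearance, in fractions of the image side:
# (center_y, center_x, semi_axis_a, semi_axis_b, orientation_deg, amplitude,
#  textured)
_BLOB_SPECS = {
    0: (0.34, 0.34, 0.15, 0.13, 0.0, 0.50, False),   # upper-left, round, smooth
    1: (0.62, 0.62, 0.19, 0.10, 35.0, 0.50, True),   # lower-right, elongated, textured
    2: (0.50, 0.50, 0.21, 0.09, 0.0, 0.55, False),   # central, high eccentricity
}
# within-class positional jitter (fraction of the side, per axis)
_POSITION_JITTER = 0.03


def _head_phantom(size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    a = size * (0.42 + rng.uniform(-0.02, 0.02))
    b = size * (0.36 + rng.uniform(-0.02, 0.02))
    head = (((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2) <= 1.0
    texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 16)
    texture = 0.06 * texture / (np.abs(texture).max() + 1e-12)
    img = np.where(head, 0.32 + texture, 0.02)
    return img, head


def _add_blob(img: np.ndarray, label: int, size: int,
              rng: np.random.Generator) -> np.ndarray:
    cy_f, cx_f, a_f, b_f, angle, amp, textured = _BLOB_SPECS[label]
    j = _POSITION_JITTER
    cy = (cy_f + rng.uniform(-j, j)) * size
    cx = (cx_f + rng.uniform(-j, j)) * size
    a, b = a_f * size, b_f * size
    theta = np.deg2rad(angle + rng.uniform(-10.0, 10.0))
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(float)
    u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    d2 = (u / a) ** 2 + (v / b) ** 2
    profile = amp * np.exp(-1.5 * d2)
    if textured:
        ripple = ndimage.gaussian_filter(rng.standard_normal(img.shape), sigma=2.0)
        profile = profile * (1.0 + 0.15 * ripple / (np.abs(ripple).max() + 1e-12))
    mask = d2 <= 1.0
    return img + np.where(mask, profile, 0.0), mask


def generate_synthetic_dataset(n_per_class: int, num_classes: int = 3,
                               size: int = 64, seed: int = 0) -> list[LabeledImage]:
    """`n_per_class` phantoms per class, deterministic given `seed`."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if num_classes not in (3, 4):
        raise ValueError("num_classes must be 3 or 4")
    rng = np.random.default_rng(seed)
    images: list[LabeledImage] = []
    for label in range(num_classes):
        for i in range(n_per_class):
            img, _head = _head_phantom(size, rng)
            mask = None
            if label in _BLOB_SPECS:
                img, mask = _add_blob(img, label, size, rng)
            img = img + rng.normal(0.0, 0.02, size=img.shape)
            img = np.clip(img, 0.0, 1.0)
            images.append(LabeledImage(pixels=img, label=label,
                                       label_name=CLASS_NAMES[label],
                                       blob_mask=mask,
                                       source_id=f"synth-{label}-{i}"))
    return images


def save_synthetic_dataset(images: list[LabeledImage], out_dir: str | Path) -> None:
    """Write phantoms as PNGs with a JSON label manifest and mask PNGs."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for im in images:
        name = im.source_id.replace("/", "_") or f"img{len(manifest)}"
        Image.fromarray((im.pixels * 255).astype(np.uint8)).save(out / f"{name}.png")
        entry = {"file": f"{name}.png", "label": im.label, "label_name": im.label_name}
        if im.blob_mask is not None:
            Image.fromarray((im.blob_mask * 255).astype(np.uint8)).save(
                out / f"{name}_mask.png")
            entry["mask"] = f"{name}_mask.png"
        manifest.append(entry)
    (out / "labels.json").write_text(json.dumps(manifest, indent=2))
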