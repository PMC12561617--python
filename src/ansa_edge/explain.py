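"""Grad-CAM saliency maps and overlays.

Gradient-weighted class activation mapping: for a chosen convolutional
stage, the gradient of the target-class score with respect to the stage's
activations is spatially averaged into per-channel weights; the rectified
weighted sum of activation channels, bilinearly upsampled to the input size
and min-max normalized, is the heatmap.  The default target layer is the
deepest stage whose map still resolves lesion-scale structure (16 x 16 or
finer); for 256-input models that is the last backbone stage, after its
attention block.

On synthetic phantoms the heatmap peak can be scored against the
ground-truth blob mask, giving a quantitative localization check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .architecture import Network
from .data import LabeledImage
from .nn import Tensor

__all__ = ["Heatmap", "grad_cam", "overlay", "localization_score",
           "default_target_layer"]

MIN_CAM_RESOLUTION = 16


def default_target_layer(net: Network) -> str:
    """The deepest stage whose activation map is at least 16 x 16.

    Class-activation maps coarser than that cannot resolve lesion-scale
    structure (a 4 x 4 map upsampled to the input places its peak at one of
    sixteen cell centers).  For 256-input models the rule selects the last
    conv stage — the map there is 16 x 16 — and for smaller surrogate inputs
    it backs off to the deepest stage that still meets the floor.
    """
    size = net.spec.backbone.input_size
    for i in range(4, 0, -1):
        if size // 2 ** i >= MIN_CAM_RESOLUTION:
            return f"stage{i}"
    return "stage1"


@dataclass
class Heatmap:
    values: np.ndarray   # (H, W) in [0, 1] (all-zero iff pre-normalization map was zero)
    target_class: int
    target_layer: str

    def peak(self) -> tuple[int, int]:
        return tuple(np.unravel_index(int(self.values.argmax()), self.values.shape))


def grad_cam(net: Network, image: LabeledImage | np.ndarray,
             target_class: int | None = None,
             target_layer: str | None = None) -> Heatmap:
    """Saliency heatmap for one image.

    ``target_class`` defaults to the predicted class; ``target_layer`` is one
    of the stage names (default: the last stage).
    """
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    names = net.stage_names()
    target_layer = target_layer or default_target_layer(net)
    if target_layer not in names:
        raise ValueError(f"unknown layer {target_layer!r}; valid layers: {names}")
    layer_idx = names.index(target_layer)

    x = Tensor(pixels[None, None, :, :])
    logits = net.forward(x, record=True)
    if target_class is None:
        target_class = int(logits.data[0].argmax())
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    score = (logits * onehot).sum()
    score.backward()

    act = net.stage_outputs[layer_idx]
    grads = act.grad[0]          # (C, h, w)
    acts = act.data[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)

    h, w = pixels.shape
    cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1,
                       grid_mode=True, mode="nearest")
    peak = cam.max()
    values = cam / peak if peak > 0 else np.zeros_like(cam)
    return Heatmap(values=values, target_class=target_class,
                   target_layer=target_layer)


def overlay(image: LabeledImage | np.ndarray, heatmap: Heatmap, alpha: float,
            out_path: str | Path, cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the color-mapped heatmap over the grayscale image and
    write a PNG; returns the blended RGB array (floats in [0, 1])."""
    import matplotlib

    from PIL import Image

    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if pixels.shape != heatmap.values.shape:
        raise ValueError("image and heatmap shapes differ")
    gray_rgb = np.repeat(np.clip(pixels, 0, 1)[:, :, None], 3, axis=2)
    heat_rgb = matplotlib.colormaps[cmap](heatmap.values)[:, :, :3]
    blended = (1.0 - alpha) * gray_rgb + alpha * heat_rgb
    Image.fromarray((blended * 255).astype(np.uint8)).save(out_path)
    return blended


def localization_score(net: Network, images: list[LabeledImage],
                       target_layer: str | None = None) -> dict:
    """Fraction of correctly classified tumor images whose heatmap peak lies
    inside the ground-truth blob mask."""
    hits = 0
    evaluated = 0
    for im in images:
        if im.blob_mask is None:
            continue
        pred = int(net.predict(im.pixels[None, None])[0])
        if pred != im.label:
            continue
        hm = grad_cam(net, im, target_class=pred, target_layer=target_layer)
        evaluated += 1
        if im.blob_mask[hm.peak()]:
            hits += 1
    return {"n_correct_tumor": evaluated, "n_peak_in_mask": hits,
            "fraction": hits / evaluated if evaluated else float("nan")}
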