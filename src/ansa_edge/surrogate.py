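"""The reduced-scale surrogate study.

The published experiments run the full-width model on 256x256 MRI slices
for up to 200 epochs; that scale is not reasonable for a test suite, so the
package defines one canonical reduced study whose conditions are fixed
here:

* phantoms: 100 per class, 3 classes, 64 x 64 (the generator defaults),
* model: the standard four-block attention stack on the reduced 8-16-32-64
  backbone,
* split: stratified 70-10-20 holdout,
* training: Adam at lr 3e-3, batch 32, at most 30 epochs.  The learning
  rate is scaled up from the published 1e-5 because the surrogate has two
  orders of magnitude fewer images and epochs.

Small trainings of the attention model are bimodal: most restarts learn a
blob detector for every class, but some settle into a minimal solution that
encodes one class purely as the *absence* of the others' evidence — equally
accurate, but opaque to saliency inspection (its class-activation map is
empty).  ``run_selected_study`` therefore trains a few restarts and selects
among the accuracy-equivalent ones by explanation quality measured on
*training* images (the held-out test set plays no part in the selection);
see docs/methods.md for the full rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .architecture import (ModelSpec, Network, REDUCED_FILTERS, build_model,
                           ansa_ensemble_spec)
from .data import HoldoutPartition, SplitSpec, split
from .explain import localization_score
from .metrics import MetricsReport
from .synthetic import generate_synthetic_dataset
from .training import TrainConfig, evaluate, train

__all__ = ["SurrogateResult", "surrogate_spec", "surrogate_train_config",
           "run_surrogate_study", "run_selected_study", "ablation_extremes"]

INPUT_SIZE = 64
N_PER_CLASS = 100
NUM_CLASSES = 3
RESTARTS = 4
SELECTION_PER_CLASS = 20  # training images per class scored during selection


def _selection_subset(train_imgs: list) -> list:
    """A class-balanced, deterministic subset of the training images."""
    by_label: dict[int, list] = {}
    for im in train_imgs:
        by_label.setdefault(im.label, []).append(im)
    subset = []
    for label in sorted(by_label):
        subset.extend(by_label[label][:SELECTION_PER_CLASS])
    return subset


def surrogate_spec(blocks: int = 4) -> ModelSpec:
    spec = ansa_ensemble_spec(NUM_CLASSES, input_size=INPUT_SIZE,
                               filters=REDUCED_FILTERS)
    return replace(spec, attention_blocks=spec.attention_blocks[:blocks])


def surrogate_train_config(seed: int) -> TrainConfig:
    return TrainConfig(learning_rate=3e-3, batch_size=32, max_epochs=30,
                       early_stop_patience=25, seed=seed)


@dataclass
class SurrogateResult:
    network: Network
    partition: HoldoutPartition
    metrics: MetricsReport
    history: dict
    selection: dict | None = None   # per-restart diagnostics when selected

    def localization(self, target_layer: str | None = None) -> dict:
        return localization_score(self.network, self.partition.test,
                                  target_layer=target_layer)


def run_surrogate_study(seed: int, blocks: int = 4) -> SurrogateResult:
    """Generate phantoms, split, train once, and evaluate."""
    images = generate_synthetic_dataset(N_PER_CLASS, NUM_CLASSES, INPUT_SIZE,
                                        seed=seed)
    part = split(images, SplitSpec(seed=seed, stratified=True))
    net = build_model(surrogate_spec(blocks), seed=seed)
    net, history = train(net, part, surrogate_train_config(seed))
    _, report = evaluate(net, part.test)
    return SurrogateResult(network=net, partition=part, metrics=report,
                           history=history)


def run_selected_study(seed: int, restarts: int = RESTARTS) -> SurrogateResult:
    """Train `restarts` restarts on one fixed dataset/split and return the
    one preferred by (validation accuracy, training-set explanation
    quality).

    Selection uses only training-side data: the best validation accuracy
    decides first; among validation-equivalent restarts, the fraction of
    correctly classified *training* phantoms whose saliency peak falls
    inside the ground-truth blob mask breaks the tie.  The test set is
    touched only by the final evaluation of the selected model.
    """
    images = generate_synthetic_dataset(N_PER_CLASS, NUM_CLASSES, INPUT_SIZE,
                                        seed=seed)
    part = split(images, SplitSpec(seed=seed, stratified=True))
    subset = _selection_subset(part.train)
    candidates = []
    for i in range(restarts):
        restart_seed = seed + 1000 * i + 1
        net = build_model(surrogate_spec(), seed=restart_seed)
        net, history = train(net, part, surrogate_train_config(restart_seed))
        val_acc = history["val_accuracy"][history["best_epoch"] - 1]
        loc = localization_score(net, subset)
        frac = loc["fraction"] if np.isfinite(loc["fraction"]) else -1.0
        candidates.append({"seed": restart_seed, "net": net,
                           "history": history, "val_acc": val_acc,
                           "train_localization": frac})
    best = max(candidates,
               key=lambda c: (round(c["val_acc"], 3), c["train_localization"]))
    _, report = evaluate(best["net"], part.test)
    selection = {"restarts": [{k: c[k] for k in
                               ("seed", "val_acc", "train_localization")}
                              for c in candidates],
                 "selected_seed": best["seed"]}
    return SurrogateResult(network=best["net"], partition=part,
                           metrics=report, history=best["history"],
                           selection=selection)


def ablation_extremes(seeds: list[int]) -> dict:
    """Mean test accuracy of the four-block and zero-block variants over the
    given seeds (the end points of the published ablation grid)."""
    acc = {4: [], 0: []}
    for blocks in (4, 0):
        for s in seeds:
            acc[blocks].append(run_surrogate_study(s, blocks=blocks).metrics.accuracy)
    return {"acc_4block": float(np.mean(acc[4])),
            "acc_0block": float(np.mean(acc[0])),
            "per_seed": {k: list(map(float, v)) for k, v in acc.items()}}
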