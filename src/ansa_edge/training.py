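"""Training loop, evaluation protocols, and the high-level classifier API.

Training uses Adam on categorical cross-entropy with early stopping on
validation loss (best-epoch weights restored).  The published operating
point is Adam at lr = 1e-5, batch size 64, up to 200 epochs with patience
20 on 256x256 inputs; the defaults here mirror that, and the small-scale
synthetic runs in the tests and scripts pass an explicitly faster schedule.

Protocols: repeated holdout ("Monte Carlo", fresh 70-10-20 split and fresh
initialization per run, mean +- std reported), five-fold cross-validation
(every sample tested exactly once), cross-dataset head adaptation (replace
and train only the final layer when the class counts differ), and the
5 x 2 attention-ablation grid.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .architecture import (ModelSpec, Network, ablation_variants, build_model,
                           count_parameters)
from .data import (HoldoutPartition, KFoldPartition, LabeledImage, SplitSpec,
                   split, to_arrays)
from .metrics import (ConfusionMatrix, MetricsReport, evaluate_predictions)
from .nn import Adam, Dense, Tensor, softmax_cross_entropy

__all__ = [
    "TrainConfig", "EarlyStopper", "train", "evaluate",
    "inference_time_per_image", "RunSummary", "monte_carlo", "five_fold_cv",
    "adapt_head_and_eval", "ablation_run", "ANSAClassifier", "ClassifierResults",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 20
    seed: int = 0
    average: str = "macro"
    calibrate_init: bool = False
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class EarlyStopper:
    """Stop when the monitored loss has not improved for `patience`
    consecutive epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self._since = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            self._since = 0
        else:
            self._since += 1
        return self._since >= self.patience


def calibrate_activation_scale(net: Network, x_probe: np.ndarray) -> None:
    """Data-dependent initialization: set each stage's fixed output gain so
    the stage output (after attention) has unit standard deviation under a
    probe batch.

    The stacked attention gates attenuate activations by orders of magnitude
    at initialization (every spatial gate starts near 1/2); without
    compensation, short training budgets are spent climbing out of a flat
    region of the loss.  The compensation is folded into a constant
    per-stage gain rather than into the conv weights: inflating the weights
    would leave training in a lazy, random-feature regime (Adam's relative
    weight updates shrink as the weights grow), whereas a fixed gain keeps
    the weights at their small initial scale so feature learning proceeds
    normally.  The attention gates are scale-invariant (pooled maps are
    l2-normalized and channel contexts are standardized), so one pass per
    stage calibrates exactly.
    """
    x = Tensor(x_probe)
    for stage in net.stages:
        stage.gain = 1.0
        out = stage(x)
        std = float(out.data.std())
        if std > 0:
            stage.gain = 1.0 / std
            out = Tensor(out.data / std)
        x = out


def _batch_iter(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _dataset_loss(net: Network, x: np.ndarray, y: np.ndarray,
                  batch_size: int) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) without building gradient state."""
    losses, correct = [], 0
    for start in range(0, x.shape[0], batch_size):
        xb, yb = x[start:start + batch_size], y[start:start + batch_size]
        logits = net.forward(Tensor(xb))
        losses.append(softmax_cross_entropy(logits, yb).item() * len(yb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return float(np.sum(losses)) / x.shape[0], correct / x.shape[0]


def train(net: Network, partition: HoldoutPartition | tuple, cfg: TrainConfig,
          ) -> tuple[Network, dict]:
    """Minimize cross-entropy with Adam; early-stop on validation loss and
    restore the best-validation weights.  Returns the trained network and a
    per-epoch history dict."""
    if isinstance(partition, HoldoutPartition):
        train_imgs, val_imgs = partition.train, partition.val
    else:
        train_imgs, val_imgs = partition[0], partition[1]
    if not train_imgs:
        raise ValueError("training set is empty")
    x_tr, y_tr = to_arrays(train_imgs)
    x_va, y_va = to_arrays(val_imgs)
    if cfg.calibrate_init and isinstance(net, Network):
        calibrate_activation_scale(net, x_tr[:min(64, x_tr.shape[0])])
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.early_stop_patience)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_state = net.state_dict()
    for _epoch in range(cfg.max_epochs):
        epoch_losses = []
        for idx in _batch_iter(x_tr.shape[0], cfg.batch_size, rng):
            net.zero_grad()
            loss = softmax_cross_entropy(net.forward(Tensor(x_tr[idx])), y_tr[idx])
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val_loss, val_acc = _dataset_loss(net, x_va, y_va, cfg.batch_size)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if val_loss <= min(history["val_loss"]):
            best_state = net.state_dict()
        if stopper.update(val_loss):
            break
    net.load_state_dict(best_state)
    history["best_epoch"] = stopper.best_epoch
    return net, history


def evaluate(net: Network, images: list[LabeledImage], batch_size: int = 64,
             average: str = "macro") -> tuple[ConfusionMatrix, MetricsReport]:
    if not images:
        raise ValueError("evaluation set is empty")
    x, y = to_arrays(images)
    preds = np.concatenate([net.predict(x[s:s + batch_size])
                            for s in range(0, x.shape[0], batch_size)])
    return evaluate_predictions(y, preds, net.spec.num_classes, average=average)


def inference_time_per_image(net: Network, images: list[LabeledImage],
                             repeats: int = 5, batch_size: int = 16,
                             warmup_batches: int = 10) -> float:
    """Median over `repeats` of the mean wall-clock milliseconds per image.
    Hardware-dependent; reported, never asserted against published values."""
    x, _ = to_arrays(images)
    xb = x[:batch_size]
    for _ in range(warmup_batches):
        net.forward(Tensor(xb))
    means = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        for s in range(0, x.shape[0], batch_size):
            net.forward(Tensor(x[s:s + batch_size]))
        means.append((time.perf_counter() - t0) * 1e3 / x.shape[0])
    return float(np.median(means))


@dataclass
class RunSummary:
    reports: list            # one MetricsReport per run
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)

    @classmethod
    def from_reports(cls, reports: list) -> "RunSummary":
        keys = ("accuracy", "precision", "recall", "f1", "specificity")
        vals = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
        return cls(reports=reports,
                   mean={k: float(v.mean()) for k, v in vals.items()},
                   std={k: float(v.std(ddof=0)) for k, v in vals.items()})


def _train_once(spec: ModelSpec, images: list[LabeledImage], cfg: TrainConfig,
                seed: int, stratified: bool = True) -> tuple[Network, MetricsReport]:
    part = split(images, SplitSpec(mode="holdout_70_10_20", seed=seed,
                                   stratified=stratified))
    net = build_model(spec, seed=seed)
    net, _ = train(net, part, replace(cfg, seed=seed))
    _, report = evaluate(net, part.test, average=cfg.average)
    return net, report


def monte_carlo(spec: ModelSpec, images: list[LabeledImage], cfg: TrainConfig,
                runs: int = 10, seeds: list[int] | None = None) -> RunSummary:
    """Repeat the full split/train/test cycle and report mean +- std."""
    seeds = list(seeds) if seeds is not None else [cfg.seed + i for i in range(runs)]
    if len(seeds) != runs:
        raise ValueError("need one seed per run")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds across Monte Carlo runs")
    reports = [_train_once(spec, images, cfg, s)[1] for s in seeds]
    return RunSummary.from_reports(reports)


def five_fold_cv(spec: ModelSpec, images: list[LabeledImage], cfg: TrainConfig,
                 seed: int | None = None) -> RunSummary:
    """Five folds; each serves as the test set once.  A tenth of each
    training portion is held out as the early-stopping validation set."""
    seed = cfg.seed if seed is None else seed
    part: KFoldPartition = split(images, SplitSpec(mode="kfold_5", seed=seed))
    reports = []
    for i, (train_imgs, test_imgs) in enumerate(part.iterate()):
        n_val = max(1, len(train_imgs) // 10)
        net = build_model(spec, seed=seed + i)
        net, _ = train(net, (train_imgs[n_val:], train_imgs[:n_val]),
                       replace(cfg, seed=seed + i))
        _, report = evaluate(net, test_imgs, average=cfg.average)
        reports.append(report)
    return RunSummary.from_reports(reports)


def adapt_head_and_eval(net: Network, target_images: list[LabeledImage],
                        num_classes_target: int, cfg: TrainConfig,
                        ) -> tuple[MetricsReport, Network]:
    """Cross-dataset evaluation.  If the class counts differ, the final
    dense layer is replaced (fresh, `num_classes_target` outputs) and is the
    only layer trained; every other weight stays bit-identical.  With equal
    class counts the network is evaluated directly, with zero training."""
    labels = {im.label for im in target_images}
    if labels and max(labels) >= num_classes_target:
        raise ValueError(f"labels {sorted(labels)} incompatible with "
                         f"{num_classes_target} classes")
    if num_classes_target == net.spec.num_classes:
        _, report = evaluate(net, target_images, average=cfg.average)
        return report, net
    adapted = build_model(net.spec, seed=cfg.seed)
    adapted.load_state_dict(net.state_dict())
    for p in adapted.parameters():
        p.requires_grad = False
    adapted.fc2 = Dense(net.spec.head_hidden, num_classes_target,
                        rng=np.random.default_rng(cfg.seed))
    adapted.spec = replace(net.spec, num_classes=num_classes_target)
    part = split(target_images, SplitSpec(mode="holdout_70_10_20", seed=cfg.seed,
                                          stratified=True))
    adapted, _ = train(adapted, part, cfg)
    _, report = evaluate(adapted, part.test, average=cfg.average)
    return report, adapted


def ablation_run(spec: ModelSpec, images: list[LabeledImage], cfg: TrainConfig,
                 seeds: list[int]) -> list[dict]:
    """Train every cell of the {0..4 blocks} x {GCT on, off} grid once per
    seed; returns 10 rows with per-seed reports and seed-mean metrics."""
    rows = []
    for variant in ablation_variants(spec):
        reports = [_train_once(variant, images, cfg, s)[1] for s in seeds]
        summary = RunSummary.from_reports(reports)
        rows.append({
            "blocks": len(variant.attention_blocks),
            "use_gct": variant.use_gct,
            "reports": reports,
            "mean": summary.mean,
            "std": summary.std,
        })
    return rows


# ---------------------------------------------------------------------------
# estimator-style wrapper
# ---------------------------------------------------------------------------

@dataclass
class ClassifierResults:
    """Fitted-model container: the trained network, training history, and
    held-out test metrics."""
    network: Network
    history: dict
    confusion: ConfusionMatrix
    metrics: MetricsReport
    n_train: int
    n_val: int
    n_test: int

    def summary(self) -> str:
        lines = [
            "Shallow attention-guided CNN - fit summary",
            "=" * 46,
            f"parameters:        {count_parameters(self.network):,}",
            f"train/val/test:    {self.n_train}/{self.n_val}/{self.n_test}",
            f"epochs run:        {len(self.history['train_loss'])} "
            f"(best: {self.history['best_epoch']})",
            "",
            self.metrics.summary(),
        ]
        return "\n".join(lines)


class ANSAClassifier:
    """High-level fit/evaluate interface over a model spec.

    >>> spec = ansa_ensemble_spec(num_classes=3, input_size=64)
    >>> results = ANSAClassifier(spec, cfg).fit(images)
    >>> print(results.summary())
    """

    def __init__(self, spec: ModelSpec, cfg: TrainConfig | None = None):
        self.spec = spec
        self.cfg = cfg or TrainConfig()

    def fit(self, images: list[LabeledImage], seed: int | None = None,
            stratified: bool = True) -> ClassifierResults:
        seed = self.cfg.seed if seed is None else seed
        part = split(images, SplitSpec(mode="holdout_70_10_20", seed=seed,
                                       stratified=stratified))
        net = build_model(self.spec, seed=seed)
        net, history = train(net, part, replace(self.cfg, seed=seed))
        cm, report = evaluate(net, part.test, average=self.cfg.average)
        return ClassifierResults(network=net, history=history, confusion=cm,
                                 metrics=report, n_train=len(part.train),
                                 n_val=len(part.val), n_test=len(part.test))
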