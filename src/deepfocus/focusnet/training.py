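"""SGD training with on-the-fly augmentation, early stopping and
exhaustive grid search over the hyperparameter space."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..tileset import TileDataset, augment_batch
from . import layers as L
from .model import CLASS_ORDER, ArchitectureSpec, FocusNet, build_model

#: The explored hyperparameter grid (bold = selected defaults:
#: 5x5 / 3x3 / lr 0.01 / batch 64).
DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "conv1_kernel": (3, 5, 7, 9),
    "conv2_kernel": (3, 5, 7),
    "learning_rate": (0.01, 0.06, 0.12, 0.22),
    "batch_size": (32, 64, 128),
}


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and regularization settings (plain SGD, cross-entropy)."""

    learning_rate: float = 0.01
    batch_size: int = 64
    max_epochs: int = 20
    dropout_p: float = 0.2
    early_stop_patience: int = 3
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 2 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainHistory:
    """Per-epoch trace of a training run."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int = 0  # 1-based epoch whose parameters were returned

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch - 1]


def _labels_to_index(ds: TileDataset) -> np.ndarray:
    return np.asarray([CLASS_ORDER.index(lab) for lab in ds.labels], dtype=np.int64)


def evaluate_accuracy(model: FocusNet, ds: TileDataset, batch_size: int = 256) -> float:
    """Fraction of tiles whose thresholded prediction matches the label."""
    p = model.predict_proba(ds.pixels, batch_size=batch_size)
    pred = (p > 0.5).astype(np.int64)  # 1 = in-focus
    return float((pred == _labels_to_index(ds)).mean())


def train(
    model: FocusNet,
    train_set: TileDataset,
    val_set: TileDataset,
    config: TrainingConfig,
) -> tuple[FocusNet, TrainHistory]:
    """Mini-batch SGD with on-the-fly dihedral augmentation.

    Stops at ``max_epochs`` or when validation accuracy has not improved
    for ``early_stop_patience`` consecutive epochs; the parameters of the
    best-validation epoch are restored before returning.  Deterministic
    given ``config.seed``.
    """
    if train_set.pixels is None or len(train_set) == 0:
        raise ValueError("training set must be non-empty and rendered")
    if val_set.pixels is None or len(val_set) == 0:
        raise ValueError("validation set must be non-empty and rendered")
    if len(set(val_set.labels)) < 2:
        raise ValueError("validation set must contain both classes")

    rng = np.random.default_rng(config.seed)
    x = train_set.pixels.astype(np.float32)
    y = _labels_to_index(train_set)
    n = len(x)
    history = TrainHistory()
    best_state = model.get_state()
    best_val = -np.inf
    epochs_without_improvement = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # BN needs at least two samples
            batch = x[idx]
            if config.augment:
                batch = augment_batch(batch, rng)
            logits = model.forward(batch, mode="train", rng=rng)
            loss, dlogits = L.cross_entropy_loss(logits, y[idx])
            model.backward(dlogits)
            model.sgd_step(config.learning_rate)
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == y[idx]).sum())
            seen += len(idx)
        history.train_loss.append(sum(losses) / seen)
        history.train_accuracy.append(hits / seen)
        val_acc = evaluate_accuracy(model, val_set)
        history.val_accuracy.append(val_acc)

        if val_acc > best_val:
            best_val = val_acc
            best_state = model.get_state()
            history.best_epoch = epoch
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
        if epochs_without_improvement >= config.early_stop_patience:
            history.stop_epoch = epoch
            history.stop_reason = (
                f"validation accuracy stopped increasing "
                f"({config.early_stop_patience} epochs without improvement)"
            )
            break
    else:
        history.stop_epoch = config.max_epochs
        history.stop_reason = "reached max_epochs"

    model.set_state(best_state)
    return model, history


def grid_search(
    train_set: TileDataset,
    val_set: TileDataset,
    search_space: dict[str, tuple] | None = None,
    base_spec: ArchitectureSpec | None = None,
    base_config: TrainingConfig | None = None,
) -> tuple[ArchitectureSpec, TrainingConfig, pd.DataFrame]:
    """Exhaustively evaluate the Cartesian hyperparameter grid.

    Recognized axes: ``conv1_kernel``, ``conv2_kernel``, ``learning_rate``,
    ``batch_size``.  Returns the configuration maximizing validation
    accuracy (ties broken toward smaller learning rate, then smaller
    first-layer kernel) and a result table of all evaluated points.
    """
    space = dict(search_space or DEFAULT_SEARCH_SPACE)
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must be non-empty on every axis")
    unknown = set(space) - {"conv1_kernel", "conv2_kernel", "learning_rate", "batch_size"}
    if unknown:
        raise ValueError(f"unknown search axes: {sorted(unknown)}")
    base_spec = base_spec or ArchitectureSpec()
    base_config = base_config or TrainingConfig()

    rows = []
    keys = sorted(space)
    for values in itertools.product(*(space[k] for k in keys)):
        point = dict(zip(keys, values))
        kernels = list(base_spec.conv_kernels)
        if "conv1_kernel" in point:
            kernels[0] = point["conv1_kernel"]
        if "conv2_kernel" in point:
            kernels[1] = point["conv2_kernel"]
        spec = replace(base_spec, conv_kernels=tuple(kernels))
        config = replace(
            base_config,
            learning_rate=point.get("learning_rate", base_config.learning_rate),
            batch_size=point.get("batch_size", base_config.batch_size),
        )
        model = build_model(spec, rng_seed=config.seed, dropout_p=config.dropout_p)
        _, hist = train(model, train_set, val_set, config)
        rows.append(
            {
                **point,
                "val_accuracy": hist.best_val_accuracy,
                "spec": spec,
                "config": config,
            }
        )
    table = pd.DataFrame(rows)
    sort_cols, ascending = ["val_accuracy"], [False]
    for col in ("learning_rate", "conv1_kernel"):  # tie-break order
        if col in table.columns:
            sort_cols.append(col)
            ascending.append(True)
    ranked = table.sort_values(by=sort_cols, ascending=ascending, kind="mergesort")
    best = ranked.iloc[0]
    return best["spec"], best["config"], table.drop(columns=["spec", "config"])
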