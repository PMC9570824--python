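"""Subject-wise cross-validation and the optimization schedule.

Models are developed under five-fold cross-validation with the *participant*
as the unit of splitting, so no recording contributes segments to both the
training and validation side of a fold.  Each fold trains with Adam
(initial learning rate 1e-3, batch 64); the learning rate halves when the
validation loss fails to improve for 10 epochs, training stops early after
25 epochs without improvement, runs at most 100 epochs, and the weights
from the best validation epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_crnn import (
    Adam,
    CRNN,
    ModelConfig,
    build_model,
    loss_and_logit_grad,
    loss_ce_dice,
    one_hot,
)
from .preprocessing import SegmentSet

N_FOLDS = 5


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class CVPlan:
    """Participant -> fold assignment for subject-wise cross-validation."""

    fold_assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.fold_assignments.items() if f == fold)


def make_folds(ids: list[str], seed: int, n_folds: int = N_FOLDS) -> CVPlan:
    """Randomly partition participants into folds of near-equal size.

    Deterministic given ``seed``; fold sizes differ by at most one.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise TrainingError("duplicate participant ids")
    if len(ids) < n_folds:
        raise TrainingError(f"need >= {n_folds} participants, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    return CVPlan(
        fold_assignments={pid: k % n_folds for k, pid in enumerate(order)},
        seed=seed,
    )


@dataclass(frozen=True)
class TrainConfig:
    """The optimization schedule."""

    initial_lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    lr_patience: int = 10
    lr_factor: float = 0.5
    early_stop_patience: int = 25
    min_delta: float = 1e-4
    seed: int = 0


class PlateauScheduler:
    """Validation-loss plateau tracking: LR halving, early stop, best epoch.

    An epoch "improves" when its validation loss undercuts the best seen by
    more than ``min_delta``.  The LR and early-stop counters run
    independently on the same improvement signal; the LR counter resets
    after each halving.
    """

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.best_loss = np.inf
        self.best_epoch = -1
        self.lr_wait = 0
        self.stop_wait = 0
        self.lr = cfg.initial_lr
        self.should_stop = False

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch; returns True when this epoch is the new best."""
        improved = val_loss < self.best_loss - self.cfg.min_delta
        if improved:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.lr_wait = 0
            self.stop_wait = 0
        else:
            self.lr_wait += 1
            self.stop_wait += 1
            if self.lr_wait >= self.cfg.lr_patience:
                self.lr *= self.cfg.lr_factor
                self.lr_wait = 0
            if self.stop_wait >= self.cfg.early_stop_patience:
                self.should_stop = True
        return improved


def _epoch_losses(model: CRNN, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, x.shape[0], batch):
        probs = model.forward(x[i : i + batch], train=False)
        targets = one_hot(y[i : i + batch], model.cfg.n_classes)
        total += loss_ce_dice(probs, targets) * (probs.shape[0])
        n += probs.shape[0]
    return total / max(n, 1)


def train_fold(
    train_set: SegmentSet,
    val_set: SegmentSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> tuple[CRNN, pd.DataFrame]:
    """Train one fold; returns the best-validation-loss model and a history
    table (epoch, train_loss, val_loss, lr).

    Raises if the training set is empty or if any participant appears on
    both sides of the split (leakage guard).
    """
    if len(train_set) == 0:
        raise TrainingError("empty training set")
    train_cfg = train_cfg or TrainConfig()
    overlap = set(train_set.recording_ids) & set(val_set.recording_ids)
    if overlap:
        raise TrainingError(f"participant(s) in both train and validation: {overlap}")

    if model_cfg.n_classes == 2:
        y_train = train_set.binary_frame_labels
        y_val = val_set.binary_frame_labels
    else:
        y_train = train_set.frame_labels
        y_val = val_set.frame_labels
    x_train = train_set.segments
    x_val = val_set.segments

    model = build_model(model_cfg)
    opt = Adam(model.params(), lr=train_cfg.initial_lr)
    sched = PlateauScheduler(train_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    best_weights = model.get_weights()
    rows = []
    for epoch in range(train_cfg.max_epochs):
        opt.lr = sched.lr
        order = rng.permutation(x_train.shape[0])
        total, n = 0.0, 0
        for i in range(0, order.size, train_cfg.batch_size):
            idx = order[i : i + train_cfg.batch_size]
            probs = model.forward(x_train[idx], train=True)
            targets = one_hot(y_train[idx], model_cfg.n_classes)
            loss, dlogits = loss_and_logit_grad(probs, targets)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            total += loss * idx.size
            n += idx.size
        train_loss = total / max(n, 1)
        val_loss = (
            _epoch_losses(model, x_val, y_val, train_cfg.batch_size)
            if len(val_set)
            else train_loss
        )
        if sched.update(epoch, val_loss):
            best_weights = model.get_weights()
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "lr": opt.lr}
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}  "
                f"lr {opt.lr:.2e}"
            )
        if sched.should_stop:
            break
    model.set_weights(best_weights)
    return model, pd.DataFrame(rows)
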