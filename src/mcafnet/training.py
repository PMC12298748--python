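"""Training protocol: AdamW, early stopping, subject-wise k-fold splits.

The optimizer is AdamW with decoupled weight decay: the decay shrinks
parameters multiplicatively by lr * wd each step, independent of the
gradient moment terms. Default hyperparameters follow the published
protocol (lr 5e-6, weight decay 1e-2, betas 0.9/0.999, eps 1e-2, batch
size 64, patience 20); note the unusually large Adam epsilon is
deliberate and configurable.

Epochs are shuffled every pass — the model is one-to-one and no
inter-epoch context is used. Early stopping keeps the parameters of the
pass with the best validation accuracy (strict improvement, earliest
pass wins ties) and stops once ``patience`` consecutive passes fail to
improve it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, cross_entropy, no_grad
from .model_assembly import MCAFNet, StagePrediction

__all__ = ["TrainConfig", "FoldPlan", "AdamW", "EarlyStopper",
           "split_subjects_kfold", "train_fold", "predict_dataset",
           "evaluate_accuracy"]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-6
    weight_decay: float = 1e-2
    beta1: float = 0.9
    beta2: float = 0.999
    adam_epsilon: float = 1e-2
    batch_size: int = 64
    patience: int = 20
    max_epochs: int = 200
    seed: int = 0
    k_folds: int = 20

    def validate(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2,
               self.adam_epsilon) <= 0:
            raise ValueError("rates must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be nonnegative")
        if self.patience < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("patience, batch_size, max_epochs must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldPlan:
    """Subject-wise cross-validation assignment.

    ``groups[f]`` is the list of subjects whose test fold is f; per fold,
    the validation group is the next group cyclically and training uses
    the remainder, so validation and test always have (near-)equal size
    and no subject appears in two roles.
    """

    groups: list[list[str]]

    @property
    def k(self) -> int:
        return len(self.groups)

    def assignments(self) -> dict[str, int]:
        return {s: f for f, grp in enumerate(self.groups) for s in grp}

    def fold(self, f: int) -> tuple[set[str], set[str], set[str]]:
        """(train, val, test) subject sets for fold ``f``."""
        if not 0 <= f < self.k:
            raise ValueError(f"fold {f} out of range for k={self.k}")
        test = set(self.groups[f])
        val = set(self.groups[(f + 1) % self.k])
        train = {s for g, grp in enumerate(self.groups)
                 for s in grp if g not in (f, (f + 1) % self.k)}
        return train, val, test


def split_subjects_kfold(subject_ids, k: int, seed: int = 0) -> FoldPlan:
    """Seeded partition of subjects into k near-equal groups."""
    unique = sorted(set(map(str, subject_ids)))
    if k > len(unique):
        raise ValueError(f"k={k} exceeds {len(unique)} subjects")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    groups = [list(g) for g in np.array_split(np.asarray(order, dtype=object), k)]
    return FoldPlan(groups=groups)


class AdamW:
    """Adam with decoupled weight decay.

    Per step t, with gradient g: moments m and v are updated with betas,
    bias-corrected, the parameter is first shrunk by ``lr * wd`` and then
    moved by ``lr * m_hat / (sqrt(v_hat) + eps)``.
    """

    def __init__(self, params: list[Tensor], lr: float = 5e-6,
                 weight_decay: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-2):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data *= 1.0 - self.lr * self.wd
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class EarlyStopper:
    """Best-validation-accuracy tracking with a patience budget.

    ``update`` returns True when training should stop. Strict improvement
    is required; on ties the earliest pass keeps the crown.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_value = -np.inf
        self.best_pass = -1
        self.stale = 0

    def update(self, pass_index: int, value: float) -> bool:
        if value > self.best_value:
            self.best_value = value
            self.best_pass = pass_index
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _iter_batches(n: int, batch_size: int,
                  rng: np.random.Generator | None = None):
    idx = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def evaluate_accuracy(model: MCAFNet, X: np.ndarray, y: np.ndarray,
                      batch_size: int = 64) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) of ``model`` on (X, y), eval mode."""
    was_training = model.training
    model.eval()
    losses, hits = [], 0
    with no_grad():
        for batch in _iter_batches(len(X), batch_size):
            logits = model.forward_logits(X[batch])
            losses.append(cross_entropy(logits, y[batch]).data * len(batch))
            hits += int((np.argmax(logits.data, axis=1) == y[batch]).sum())
    if was_training:
        model.train()
    return float(np.sum(losses) / len(X)), hits / len(X)


def train_fold(model: MCAFNet,
               train_data: tuple[np.ndarray, np.ndarray],
               val_data: tuple[np.ndarray, np.ndarray],
               cfg: TrainConfig | None = None,
               log=None) -> tuple[MCAFNet, list[dict]]:
    """Train one fold; returns the best-validation model and history.

    ``train_data``/``val_data`` are (X, y) pairs of preprocessed tensors
    [N, C, L, D] and integer labels. History rows carry per-pass train
    and validation loss/accuracy (the learning curves).
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    X_tr, y_tr = train_data
    X_va, y_va = val_data
    if len(X_tr) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay, beta1=cfg.beta1,
                beta2=cfg.beta2, eps=cfg.adam_epsilon)
    stopper = EarlyStopper(cfg.patience)
    best_state: list[np.ndarray] | None = None
    history: list[dict] = []
    for pass_index in range(cfg.max_epochs):
        model.train()
        losses, hits, seen = [], 0, 0
        for batch in _iter_batches(len(X_tr), cfg.batch_size, rng):
            logits = model.forward_logits(X_tr[batch])
            loss = cross_entropy(logits, y_tr[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at pass {pass_index}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.data * len(batch))
            hits += int((np.argmax(logits.data, axis=1) == y_tr[batch]).sum())
            seen += len(batch)
        val_loss, val_acc = evaluate_accuracy(model, X_va, y_va,
                                              cfg.batch_size)
        row = {
            "pass": pass_index,
            "train_loss": float(np.sum(losses) / seen),
            "train_acc": hits / seen,
            "val_loss": val_loss,
            "val_acc": val_acc,
        }
        history.append(row)
        if log is not None:
            log(row)
        if val_acc > stopper.best_value:
            best_state = [a.copy() for a in model.state_arrays()]
        if stopper.update(pass_index, val_acc):
            break
    if best_state is not None:
        for tgt, src in zip(model.state_arrays(), best_state):
            tgt[...] = src
    model.eval()
    return model, history


def predict_dataset(model: MCAFNet, X: np.ndarray,
                    batch_size: int = 64) -> list[StagePrediction]:
    """Order-preserving batched inference."""
    model.eval()
    out: list[StagePrediction] = []
    for batch in _iter_batches(len(X), batch_size):
        out.extend(model.predict(X[batch]))
    return out
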