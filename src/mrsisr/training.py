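"""Training loop: log-cosh loss, augmentation, subject-level split, Adam.

The loss is the log hyperbolic cosine of the residual, averaged over
pixels: close to L2/2 for small residuals, close to |x| - log 2 for large
ones, smooth everywhere.  Augmentation applies a random 90-degree rotation
and horizontal/vertical flips identically to input channels and target.
The train/validation split is at the subject level so no subject's slices
leak across the split.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .network import SRNet
from .nn import Adam
from .synthesis import TrainingExample

_LOG2 = float(np.log(2.0))


@dataclass
class TrainConfig:
    batch_size: int = 24
    learning_rate: float = 1e-5
    epochs: int = 100
    val_fraction: float = 0.30
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def logcosh_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over pixels of log(cosh(pred - target)), numerically stable."""
    if pred.shape != target.shape:
        raise ValueError("prediction and target shapes disagree")
    x = np.abs(np.asarray(pred, dtype=np.float64) - target)
    # log(cosh(x)) = |x| + log1p(exp(-2|x|)) - log 2, stable for large |x|
    return float(np.mean(x + np.log1p(np.exp(-2.0 * x)) - _LOG2))


def logcosh_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d/dpred of the mean log-cosh loss: tanh(residual) / n."""
    return (np.tanh(pred - target) / pred.size).astype(np.float32)


def augment(example: TrainingExample, seed: int | None = None, *,
            k: int | None = None, flip_h: bool | None = None,
            flip_v: bool | None = None) -> TrainingExample:
    """90-degree rotation and flips, identical on input and target.

    Parameters left as None are drawn from the seeded generator; passing all
    three makes the transform explicit (k=0 and no flips is the identity).
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(4)) if k is None else int(k) % 4
    flip_h = bool(rng.integers(2)) if flip_h is None else flip_h
    flip_v = bool(rng.integers(2)) if flip_v is None else flip_v

    def apply(planes: np.ndarray) -> np.ndarray:
        out = np.rot90(planes, k=k, axes=(1, 2))
        if flip_h:
            out = out[:, :, ::-1]
        if flip_v:
            out = out[:, ::-1, :]
        return np.ascontiguousarray(out)

    return replace(example, lr_input=apply(example.lr_input),
                   hr_target=apply(example.hr_target))


def split_train_val(dataset: list[TrainingExample], val_fraction: float = 0.30,
                    seed: int = 0) -> tuple[list[TrainingExample], list[TrainingExample]]:
    """Split at the subject level; the validation side gets
    ``round(val_fraction * n_subjects)`` subjects (at least one each side)."""
    subjects = sorted({ex.subject_id for ex in dataset})
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n_val = int(round(val_fraction * len(subjects)))
    n_val = min(max(n_val, 1), len(subjects) - 1)
    val_ids = set(order[:n_val])
    train = [ex for ex in dataset if ex.subject_id not in val_ids]
    val = [ex for ex in dataset if ex.subject_id in val_ids]
    return train, val


def _stack(batch: list[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([ex.lr_input for ex in batch]).astype(np.float32)
    y = np.stack([ex.hr_target for ex in batch]).astype(np.float32)
    return x, y


def evaluate_loss(model: SRNet, dataset: list[TrainingExample],
                  batch_size: int = 32) -> float:
    """Mean log-cosh loss over a dataset in inference mode."""
    total, n = 0.0, 0
    for i in range(0, len(dataset), batch_size):
        x, y = _stack(dataset[i:i + batch_size])
        pred = model.forward(x, train=False)
        total += logcosh_loss(pred, y) * len(y)
        n += len(y)
    return total / max(n, 1)


def train(model: SRNet, dataset: list[TrainingExample],
          config: TrainConfig | None = None,
          callback=None) -> tuple[SRNet, dict]:
    """Train with Adam; returns the best-validation model and the history.

    History is a dict with per-epoch ``train_loss`` and ``val_loss`` lists.
    Aborts with a RuntimeError if the loss goes non-finite.
    """
    config = config or TrainConfig()
    if not dataset:
        raise ValueError("dataset is empty")
    train_set, val_set = split_train_val(dataset, config.val_fraction,
                                         seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            if config.augment:
                batch = [augment(ex, seed=int(rng.integers(2 ** 31))) for ex in batch]
            x, y = _stack(batch)
            pred = model.forward(x, train=True)
            loss = logcosh_loss(pred, y)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(logcosh_grad(pred, y))
            opt.step()
            epoch_loss += loss * len(batch)
            n_seen += len(batch)
        val_loss = evaluate_loss(model, val_set)
        history["train_loss"].append(epoch_loss / max(n_seen, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
        if callback is not None:
            callback(epoch, history)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
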