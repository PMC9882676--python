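"""Training protocol: MSE objective, Adam at 2e-4, periodic checkpoints,
patience-based convergence, best-weights retention, seeded splitting.

The optimizer minimizes the mean-squared error between predicted and
ground-truth normalized volumes. Weights are checkpointed every
``checkpoint_every`` epochs (default 10); training stops at ``max_epochs`` or
once the validation loss has not improved for ``patience`` epochs, and the
weights of the best validation epoch are returned.
"""

from __future__ import annotations

import copy
import csv
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .volume import NormalizedVolume


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    batch_size: int = 4
    max_epochs: int = 100
    checkpoint_every: int = 10
    patience: int = 20
    seed: int = 0
    #: (train_fraction, val_fraction, test_count)
    split: tuple[float, float, int] = (0.9, 0.1, 2)
    #: optional early exit once the epoch train loss drops below this value
    target_train_loss: float | None = None
    #: optional step decay (step_epochs, gamma); none by default
    lr_decay: tuple[int, float] | None = None

    def validate(self) -> list[str]:
        errors = []
        if self.learning_rate <= 0:
            errors.append(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            errors.append("batch_size must be >= 1")
        if self.max_epochs < 1:
            errors.append("max_epochs must be >= 1")
        if self.checkpoint_every < 1:
            errors.append("checkpoint_every must be >= 1")
        if self.patience < 1:
            errors.append("patience must be >= 1")
        tf, vf, tc = self.split
        if tf < 0 or vf < 0 or abs(tf + vf - 1.0) > 1e-9:
            errors.append(f"train/val fractions must be >= 0 and sum to 1, got ({tf}, {vf})")
        if int(tc) < 0:
            errors.append("test_count must be >= 0")
        return errors

    def require_valid(self) -> "TrainConfig":
        errors = self.validate()
        if errors:
            raise ValueError("invalid TrainConfig: " + "; ".join(errors))
        return self


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    wall_time_s: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["epoch", "train_loss", "val_loss", "wall_time_s"])
            for i, (t, v, s) in enumerate(zip(self.train_loss, self.val_loss, self.wall_time_s), 1):
                w.writerow([i, f"{t:.8f}", f"{v:.8f}", f"{s:.3f}"])


def _as_array(v) -> np.ndarray:
    return v.voxels if isinstance(v, NormalizedVolume) else np.asarray(v)


def mse_loss(pred, truth) -> float:
    """Mean over all voxels of the squared difference."""
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    d = p.astype(np.float64) - t.astype(np.float64)
    return float(np.mean(d * d))


def split_dataset(samples: list, config: TrainConfig):
    """Seeded disjoint, exhaustive (train, val, test) partition.

    The test set takes ``test_count`` samples; the remainder is split by the
    train/val fractions. Identical seeds give identical partitions.
    """
    config.require_valid()
    n = len(samples)
    test_count = int(config.split[2])
    if test_count >= n:
        raise ValueError(f"test_count {test_count} must be < dataset size {n}")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    test_idx = perm[:test_count]
    rest = perm[test_count:]
    n_val = int(round(config.split[1] * len(rest)))
    if len(rest) - n_val < 1:
        n_val = len(rest) - 1
    val_idx, train_idx = rest[:n_val], rest[n_val:]
    pick = lambda idx: [samples[i] for i in sorted(idx)]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def _stack_batch(samples: list[dict], idx) -> tuple[list[np.ndarray], np.ndarray]:
    inputs = [np.stack([samples[i]["inputs"][v] for i in idx]) for v in range(len(samples[0]["inputs"]))]
    targets = np.stack([samples[i]["target"] for i in idx])
    return inputs, targets


def _epoch_eval(model, samples: list[dict], batch_size: int) -> float:
    total, count = 0.0, 0
    for start in range(0, len(samples), batch_size):
        idx = range(start, min(start + batch_size, len(samples)))
        inputs, targets = _stack_batch(samples, idx)
        pred = model.forward(*inputs, training=False)
        d = pred.astype(np.float64) - targets
        total += float(np.sum(d * d))
        count += targets.size
    return total / count


def train(
    model,
    dataset: list[dict],
    config: TrainConfig,
    *,
    val_data: list[dict] | None = None,
    out_dir: str | os.PathLike | None = None,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Train ``model`` on ``dataset`` and return (best_weights, history).

    Each dataset entry is ``{"inputs": (topogram arrays (1, H, W), ...),
    "target": (1, D, D, D) normalized volume}``. When ``val_data`` is omitted
    the validation fraction of ``config.split`` is carved from ``dataset``;
    with a single-sample dataset the train loss doubles as the validation
    loss. Raises ``RuntimeError`` on a non-finite loss (divergence).
    """
    config.require_valid()
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    if val_data is None:
        n_val = int(round(config.split[1] * len(dataset)))
        if len(dataset) - n_val < 1:
            n_val = 0
        if n_val > 0:
            perm = rng.permutation(len(dataset))
            val_data = [dataset[i] for i in perm[:n_val]]
            dataset = [dataset[i] for i in perm[n_val:]]
        else:
            val_data = []

    layers = model.layers()
    opt = nn.Adam(layers, lr=config.learning_rate)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] = {k: v.copy() for k, v in model.state_dict().items()}
    epochs_since_best = 0
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        if config.lr_decay is not None:
            step, gamma = config.lr_decay
            opt.lr = config.learning_rate * gamma ** ((epoch - 1) // int(step))
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            inputs, targets = _stack_batch(dataset, idx)
            pred = model.forward(*inputs, training=True)
            diff = pred - targets.astype(np.float32)
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch} (divergence)")
            losses.append(loss)
            model.backward((2.0 / diff.size) * diff.astype(np.float32))
            opt.step()
        train_loss = float(np.mean(losses))
        val_loss = _epoch_eval(model, val_data, config.batch_size) if val_data else train_loss
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch} (divergence)")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.wall_time_s.append(time.perf_counter() - t0)

        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1

        if out_dir is not None and epoch % config.checkpoint_every == 0:
            model.save(os.path.join(out_dir, f"epoch_{epoch}.ckpt.npz"))

        if config.target_train_loss is not None and train_loss < config.target_train_loss:
            break
        if epochs_since_best >= config.patience:
            break

    if out_dir is not None:
        state_backup = {k: v.copy() for k, v in model.state_dict().items()}
        model.load_state_dict(best_state)
        model.save(os.path.join(out_dir, "best.ckpt.npz"))
        model.load_state_dict(state_backup)
    return best_state, history
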