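"""Emulator fitting: mean-squared-error training with batch/time-subset schedules.

The loss over a batch X̄ of (conductances, AP) pairs and a time subset T is

    L = 1 / (2|T|) * sum_{(x, V̂m) in X̄} sum_{t in T} (Vm(x, t) - V̂m(t))^2,

minimized with Adam.  Batch size and the fraction of the canonical time grid
seen per step both grow linearly over the epochs between configured
endpoints; time subsets are drawn uniformly without replacement each step.
Validation trace RMSE is logged periodically and the best-validation
checkpoint is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .dataset import Dataset
from .emulator import EmulatorWeights, backward, forward
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyperparameters; the defaults mirror the full-scale recipe.

    Desk-scale runs should lower ``epochs`` and the batch endpoints (see
    ``desk_scale``) so that enough optimizer steps happen within a CPU
    budget.
    """

    epochs: int = 5000
    batch_start: int = 1250
    batch_end: int = 1800
    time_frac_start: float = 1.0 / 16.0
    time_frac_end: float = 1.0
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    lr_decay: float = 1.0          # final lr = lr * lr_decay (linear schedule)
    clip_norm: float = 25.0        # global gradient-norm clip (0 disables)
    seed: int = 0
    val_every: int = 50
    val_time_stride: int = 8       # grid stride for validation RMSE
    dtype: str = "float32"

    def __post_init__(self):
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.batch_end < self.batch_start or self.time_frac_end < self.time_frac_start:
            raise ValidationError("schedules must be non-decreasing")
        if not 0.0 < self.time_frac_start <= self.time_frac_end <= 1.0:
            raise ValidationError("time fractions must lie in (0, 1]")

    @classmethod
    def desk_scale(cls, epochs: int = 400, seed: int = 0, **kw) -> "TrainingConfig":
        """Reduced-scale recipe: small batches, many steps, decaying lr."""
        return cls(epochs=epochs, batch_start=96, batch_end=192,
                   lr=2e-3, lr_decay=0.05, seed=seed, **kw)


def mse_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Batch MSE loss: 1/(2|T|) * sum over samples and times of squared error."""
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if predicted.shape != target.shape:
        raise ValidationError(
            f"shape mismatch: {predicted.shape} vs {target.shape}")
    n_times = predicted.shape[-1]
    return float(np.sum((predicted - target) ** 2) / (2.0 * n_times))


@dataclass
class TrainingLog:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_epochs: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    best_val_rmse: float = np.inf
    best_epoch: int = -1
    aborted: bool = False

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({"epoch": self.epochs, "train_loss": self.train_loss})
        val = pd.DataFrame({"epoch": self.val_epochs, "val_rmse": self.val_rmse})
        df.merge(val, on="epoch", how="left").to_csv(path, index=False)


def _validation_rmse(w: EmulatorWeights, x_val, vm_val, stride: int,
                     chunk: int = 64) -> float:
    """Mean per-trace RMSE over the validation set on a strided grid."""
    if x_val.shape[0] == 0:
        return np.nan
    t = w.meta["_grid"][::stride]
    tgt = vm_val[:, ::stride]
    rmses = []
    for i in range(0, x_val.shape[0], chunk):
        pred = forward(w, x_val[i:i + chunk], t)
        rmses.append(np.sqrt(np.mean((pred - tgt[i:i + chunk]) ** 2, axis=1)))
    return float(np.mean(np.concatenate(rmses)))


def train(dataset: Dataset, config: TrainingConfig = TrainingConfig(),
          initial_weights: EmulatorWeights | None = None):
    """Fit emulator weights to a dataset.

    Returns (weights, TrainingLog); the weights are the best-validation
    checkpoint (final weights if no validation samples exist).  Training is
    deterministic for a fixed config and dataset.
    """
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    dtype = np.dtype(config.dtype)
    w = (initial_weights.astype(dtype) if initial_weights is not None
         else EmulatorWeights.initialize(seed=config.seed, dtype=dtype))
    w.meta["_grid"] = dataset.grid  # transient, for validation; stripped on save

    train_mask = dataset.split == "train"
    x_all = (dataset.conductances / 2.0 - 0.5).astype(dtype)
    vm_all = dataset.vm.astype(dtype)
    x_tr, vm_tr = x_all[train_mask], vm_all[train_mask]
    x_val, vm_val = x_all[~train_mask], vm_all[~train_mask]
    n_train, n_times = vm_tr.shape
    grid = dataset.grid

    params = w.params()
    opt = Adam(params, lr=config.lr, betas=config.betas)
    rng = np.random.default_rng(config.seed)
    logbook = TrainingLog()
    best = w.copy()

    if config.epochs == 0:
        del w.meta["_grid"]
        return w, logbook

    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        bs = int(round(config.batch_start + frac * (config.batch_end - config.batch_start)))
        bs = min(max(bs, 1), n_train)
        tfrac = config.time_frac_start + frac * (config.time_frac_end - config.time_frac_start)
        n_t = max(1, int(round(tfrac * n_times)))
        opt.lr = config.lr * (1.0 + frac * (config.lr_decay - 1.0))

        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train - bs + 1, bs):
            idx = order[start:start + bs]
            t_idx = (rng.permutation(n_times)[:n_t] if n_t < n_times
                     else np.arange(n_times))
            vm_pred, cache = forward(w, x_tr[idx], grid[t_idx], with_cache=True)
            target = vm_tr[idx][:, t_idx]
            diff = vm_pred - target
            loss = float(np.sum(diff.astype(np.float64) ** 2) / (2.0 * n_t))
            if not np.isfinite(loss):
                log.warning("divergence at epoch %d; returning last checkpoint", epoch)
                logbook.aborted = True
                del best.meta["_grid"]
                return best, logbook
            epoch_losses.append(loss)
            grads = backward(w, cache, (diff / n_t).astype(dtype))
            flat = []
            for lg in (grads["theta1"], grads["theta2"]):
                for dW, db in lg:
                    flat.extend((dW, db))
            if config.clip_norm > 0:
                gnorm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                    for g in flat))
                if gnorm > config.clip_norm:
                    scale = config.clip_norm / gnorm
                    flat = [g * scale for g in flat]
            opt.step(flat)

        logbook.epochs.append(epoch)
        logbook.train_loss.append(float(np.mean(epoch_losses)))

        if (epoch % config.val_every == 0 or epoch == config.epochs - 1):
            vr = _validation_rmse(w, x_val, vm_val, config.val_time_stride)
            logbook.val_epochs.append(epoch)
            logbook.val_rmse.append(vr)
            if np.isnan(vr) or vr < logbook.best_val_rmse:
                logbook.best_val_rmse = vr
                logbook.best_epoch = epoch
                best = w.copy()
            log.info("epoch %d loss %.4f val RMSE %.3f mV", epoch,
                     logbook.train_loss[-1], vr)

    result = best if x_val.shape[0] else w
    del result.meta["_grid"]
    result.meta.update(epochs=config.epochs, seed=config.seed,
                       best_val_rmse=float(logbook.best_val_rmse))
    return result, logbook
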