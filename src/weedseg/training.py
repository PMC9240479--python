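"""Two-phase freeze/unfreeze training loop.

Training runs 500 epochs at batch size 8 with Adam (beta1 = 0.9) on
per-pixel cross-entropy over the three predicted classes. The learning
rate decays along a cosine from 0.01 at the first epoch to a floor of
0.001 at the last. For the first 50 epochs the encoder (the feature
extraction backbone) is frozen — its parameters and batch-norm
statistics are bit-identical across steps and only the decoder trains;
afterwards every parameter is trainable. Adam state is reset at the
unfreeze boundary since the parameter set changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .metrics import confusion, miou
from .nn import Adam, Tensor
from .unet import ImprovedUNet, predict_mask


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 500
    freeze_epochs: int = 50
    batch_size: int = 8
    lr_init: float = 0.01
    lr_min: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.freeze_epochs < self.epochs:
            raise TrainingError("freeze_epochs must satisfy 0 <= freeze < epochs")
        if self.lr_min > self.lr_init:
            raise TrainingError("lr_min must be <= lr_init")
        if self.batch_size < 1:
            raise TrainingError("batch_size must be >= 1")


@dataclass
class TrainLog:
    records: list = field(default_factory=list)

    def append(self, **kw):
        self.records.append(kw)

    @property
    def losses(self):
        return [r["loss"] for r in self.records]

    def write_csv(self, path):
        cols = ["epoch", "phase", "lr", "loss", "pixel_accuracy", "steps", "val_miou"]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for r in self.records:
                w.writerow({c: r.get(c, "") for c in cols})


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Cosine decay from lr_init (epoch 1) to lr_min (final epoch)."""
    if not 1 <= epoch <= config.epochs:
        raise TrainingError(f"epoch {epoch} outside [1, {config.epochs}]")
    if config.epochs == 1:
        return config.lr_init
    t = (epoch - 1) / (config.epochs - 1)
    lr = config.lr_min + 0.5 * (config.lr_init - config.lr_min) * (1 + np.cos(np.pi * t))
    return float(np.clip(lr, config.lr_min, config.lr_init))


def _to_batch(pairs, idx):
    imgs = np.stack([np.asarray(pairs[i][0], dtype=np.float32).transpose(2, 0, 1) / 255.0
                     for i in idx])
    masks = np.stack([np.asarray(pairs[i][1]) for i in idx])
    return imgs, masks


def train(model: ImprovedUNet, dataset, config: TrainConfig = TrainConfig(),
          val_pairs=None, stop_accuracy: float | None = None,
          log_every: int = 0, on_epoch=None) -> tuple:
    """Run the freeze/unfreeze loop; returns (model, TrainLog).

    ``dataset`` is a sequence of (H x W x 3 uint8 image, H x W mask with
    values in {0, 1, 2}) pairs. If ``stop_accuracy`` is set, training
    stops early once the epoch's training pixel accuracy exceeds it
    (used by the tiny-overfit capability check). When ``val_pairs`` is
    given, validation mIoU is computed each epoch and the best-scoring
    parameter state is restored at the end. ``on_epoch(epoch, model)``
    is invoked after every epoch (checkpointing, inspection).
    """
    if len(dataset) == 0:
        raise TrainingError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    optimizer = Adam(model.decoder_parameters(), lr=config.lr_init,
                     betas=(config.beta1, config.beta2))
    frozen = True
    best = (-1.0, None)
    log = TrainLog()
    for epoch in range(1, config.epochs + 1):
        if frozen and epoch > config.freeze_epochs:
            frozen = False
            optimizer = Adam(model.parameters(), lr=config.lr_init,
                             betas=(config.beta1, config.beta2))
        optimizer.lr = lr_schedule(epoch, config)
        model.train()
        if frozen:
            model.encoder.eval()  # freeze batch-norm statistics too
        order = rng.permutation(n)
        losses, correct, total = [], 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = _to_batch(dataset, idx)
            logits = model(Tensor(x))
            loss = nn.softmax_cross_entropy(logits, y)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            pred = predict_mask(logits)
            correct += int((pred == y).sum())
            total += y.size
        acc = correct / total
        rec = {"epoch": epoch, "phase": "frozen" if frozen else "unfrozen",
               "lr": optimizer.lr, "loss": float(np.mean(losses)),
               "pixel_accuracy": acc, "steps": len(losses)}
        if val_pairs is not None:
            rec["val_miou"] = _validation_miou(model, val_pairs)
            if rec["val_miou"] > best[0]:
                best = (rec["val_miou"], model.state_dict())
        log.append(**rec)
        if on_epoch is not None:
            on_epoch(epoch, model)
        if log_every and epoch % log_every == 0:
            print(f"epoch {epoch:4d} [{rec['phase']:8s}] lr={rec['lr']:.4g} "
                  f"loss={rec['loss']:.4f} acc={acc:.4f}")
        if stop_accuracy is not None and acc > stop_accuracy:
            break
    if val_pairs is not None and best[1] is not None:
        model.load_state_dict(best[1])
    recalibrate_batchnorm(model, dataset, config.batch_size)
    return model, log


def recalibrate_batchnorm(model, dataset, batch_size=8):
    """Refresh batch-norm running statistics under the final weights.

    Running means/variances accumulated while the weights were still
    moving lag behind the converged network; one cumulative-average pass
    over the data (momentum 1/t) replaces them with the exact activation
    statistics of the final model, so eval-mode inference matches
    train-mode behavior.
    """
    bns = [m for _, m in _walk_modules(model) if hasattr(m, "momentum")
           and "running_mean" in getattr(m, "_buffers", {})]
    saved = [bn.momentum for bn in bns]
    model.train()
    n = len(dataset)
    with nn.no_grad():
        for i, start in enumerate(range(0, n, batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            x, _ = _to_batch(dataset, range(start, min(start + batch_size, n)))
            model(Tensor(x))
    for bn, m in zip(bns, saved):
        bn.momentum = m
    model.eval()


def _walk_modules(module, prefix=""):
    yield prefix, module
    for name, sub in module._modules.items():
        yield from _walk_modules(sub, prefix + name + ".")


def _validation_miou(model, pairs):
    model.eval()
    cm = np.zeros((3, 3), dtype=np.int64)
    with nn.no_grad():
        for img, mask in pairs:
            x = np.asarray(img, dtype=np.float32).transpose(2, 0, 1)[None] / 255.0
            pred = predict_mask(model(Tensor(x)))[0]
            cm += confusion(pred, np.asarray(mask), 3)
    return miou(cm)


def moving_average(values, window: int = 10) -> np.ndarray:
    """Trailing moving average used to judge monotone loss descent."""
    v = np.asarray(values, dtype=np.float64)
    if len(v) < window:
        window = max(1, len(v))
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="valid")
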