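"""Training regimen, checkpointing, best-model selection and slice-level
prediction.

The published regimen is 40 epochs, batch size 64, Adam at lr 3e-5 with a
step decay of gamma 0.7 every epoch; the best model is the checkpoint with
the highest validation accuracy (slice level, earliest epoch on ties).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .models import ViTConfig, VisionTransformer, build_model
from .nn import Adam, cross_entropy

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "SlicePrediction",
    "SliceDataset",
    "train_model",
    "select_best_checkpoint",
    "predict_slices",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 64
    optimizer: str = "adam"
    lr: float = 3e-5
    lr_decay_gamma: float = 0.7
    lr_step: int = 1
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not 0 < self.lr_decay_gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.lr_step < 1:
            raise ValueError("lr_step must be >= 1")

    def lr_at(self, epoch: int) -> float:
        """Step-decayed learning rate used during ``epoch`` (0-based)."""
        return self.lr * self.lr_decay_gamma ** (epoch // self.lr_step)


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        self.epochs.append(record)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def val_accuracies(self) -> list[float]:
        return [e["val_acc"] for e in self.epochs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


@dataclass(frozen=True)
class SlicePrediction:
    subject_id: str
    z: int
    t: int
    true_label: str
    predicted_label: str
    probabilities: np.ndarray
    labels: tuple[str, ...]


class SliceDataset:
    """In-memory dataset of resized, 3-channel slice images.

    Grayscale PNGs are rescaled to [0, 1], bilinearly resized to the model
    input resolution and replicated to three channels at load time.
    """

    def __init__(self, manifest: pd.DataFrame, image_size: int,
                 labels: tuple[str, ...], label_column: str = "label"):
        self.manifest = manifest.reset_index(drop=True)
        self.labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(self.labels)}
        images = np.empty((len(self.manifest), 1, image_size, image_size), dtype=np.float32)
        targets = np.empty(len(self.manifest), dtype=np.int64)
        for i, row in enumerate(self.manifest.itertuples()):
            path = Path(row.path)
            if not path.exists():
                raise FileNotFoundError(f"slice image not found: {path}")
            with Image.open(path) as img:
                arr = np.asarray(img, dtype=np.float32)
            peak = 255.0 if arr.max() <= 255 else 65535.0
            im = Image.fromarray(arr / peak)
            im = im.resize((image_size, image_size), Image.BILINEAR)
            images[i, 0] = np.asarray(im, dtype=np.float32)
            targets[i] = index[getattr(row, label_column)]
        self.images = images
        self.targets = targets

    def __len__(self) -> int:
        return len(self.manifest)

    def batch(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.images[idx].astype(np.float64)
        x = np.repeat(x, 3, axis=1)  # grayscale -> 3 channels
        return (x - 0.5) / 0.5, self.targets[idx]


def _evaluate(model: VisionTransformer, dataset: SliceDataset,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        x, y = dataset.batch(idx)
        logits = model.forward(x).logits
        losses.append(cross_entropy(logits, y).data.item() * len(idx))
        correct += int((logits.data.argmax(axis=1) == y).sum())
    return sum(losses) / len(dataset), correct / len(dataset)


def save_checkpoint(path: str | Path, model: VisionTransformer,
                    labels: tuple[str, ...], seed: int, epoch: int) -> None:
    weights = {name: p.data for name, p in model.named_parameters()}
    meta = json.dumps({"config": model.config.to_dict(), "labels": list(labels),
                       "seed": seed, "epoch": epoch})
    np.savez(path, __meta__=meta, **weights)


def load_checkpoint(path: str | Path) -> tuple[VisionTransformer, tuple[str, ...], dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        model = build_model(ViTConfig.from_dict(meta["config"]))
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    for name, p in model.named_parameters():
        p.data = np.asarray(weights[name], dtype=np.float64)
    return model, tuple(meta["labels"]), meta


def train_model(model: VisionTransformer, manifest: pd.DataFrame,
                config: TrainConfig, out_dir: str | Path,
                label_column: str = "label",
                val_fallback_to_train: bool = False,
                ) -> tuple[TrainHistory, dict[int, Path]]:
    """Train under the configured regimen.

    Mini-batches are reshuffled every epoch; the learning rate decays by
    gamma every ``lr_step`` epochs; a checkpoint is written whenever the
    validation accuracy improves. ``val_fallback_to_train`` permits
    desk-scale cohorts whose floor-based split leaves validation empty by
    scoring model selection on the training rows instead.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = tuple(sorted(manifest[label_column].unique()))
    if len(labels) != model.config.num_classes:
        raise ValueError(
            f"manifest has {len(labels)} labels {labels} but the model expects "
            f"{model.config.num_classes} classes"
        )
    train_rows = manifest[manifest["split"] == "train"]
    val_rows = manifest[manifest["split"] == "val"]
    if val_rows.empty and val_fallback_to_train:
        logger.warning("validation split empty; falling back to training rows "
                       "for model selection")
        val_rows = train_rows
    if train_rows.empty or val_rows.empty:
        raise ValueError("manifest must contain nonempty train and val splits")

    image_size = model.config.image_size
    train_ds = SliceDataset(train_rows, image_size, labels, label_column)
    # validation is always scored against the true labels
    val_ds = SliceDataset(val_rows, image_size, labels, "label")

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.lr)
    history = TrainHistory()
    checkpoints: dict[int, Path] = {}
    best_val = -math.inf
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        optimizer.lr = lr
        order = rng.permutation(len(train_ds))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = train_ds.batch(idx)
            optimizer.zero_grad()
            result = model.forward(x, train=True, rng=rng)
            loss = cross_entropy(result.logits, y)
            loss.backward()
            optimizer.step()
            epoch_loss += loss.data.item() * len(idx)
            correct += int((result.logits.data.argmax(axis=1) == y).sum())
        train_loss = epoch_loss / len(train_ds)
        train_acc = correct / len(train_ds)
        val_loss, val_acc = _evaluate(model, val_ds, config.batch_size)
        history.append(epoch=epoch, train_loss=train_loss, train_acc=train_acc,
                       val_loss=val_loss, val_acc=val_acc, lr=lr)
        logger.info("epoch=%d train_loss=%.4f train_acc=%.4f val_loss=%.4f "
                    "val_acc=%.4f lr=%.3g", epoch, train_loss, train_acc,
                    val_loss, val_acc, lr)
        if val_acc > best_val:
            best_val = val_acc
            path = out_dir / f"checkpoint_epoch{epoch:03d}.npz"
            save_checkpoint(path, model, labels, config.seed, epoch)
            checkpoints[epoch] = path
    return history, checkpoints


def select_best_checkpoint(history: TrainHistory,
                           checkpoints: dict[int, Path]) -> Path:
    """Checkpoint of the epoch with maximal validation accuracy; ties are
    broken toward the earliest epoch."""
    if len(history) == 0:
        raise ValueError("history is empty")
    accs = history.val_accuracies
    best_epoch = int(np.argmax(accs))  # argmax returns the first maximum
    candidates = [e for e in checkpoints if e <= best_epoch]
    if not candidates:
        raise ValueError("no checkpoint at or before the best epoch")
    return checkpoints[max(candidates)]


def predict_slices(checkpoint: str | Path | VisionTransformer,
                   manifest_subset: pd.DataFrame,
                   labels: tuple[str, ...] | None = None,
                   batch_size: int = 64) -> list[SlicePrediction]:
    """Deterministic slice-level predictions with probability scores."""
    if isinstance(checkpoint, VisionTransformer):
        model = checkpoint
        if labels is None:
            raise ValueError("labels required when passing a bare model")
    else:
        model, labels, _ = load_checkpoint(checkpoint)
    dataset = SliceDataset(manifest_subset, model.config.image_size, labels)
    preds: list[SlicePrediction] = []
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        x, _ = dataset.batch(idx)
        logits = model.forward(x).logits.data
        shifted = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        for row_i, i in enumerate(idx):
            row = dataset.manifest.iloc[i]
            k = int(probs[row_i].argmax())
            preds.append(SlicePrediction(
                subject_id=row["subject_id"], z=int(row["z"]), t=int(row["t"]),
                true_label=row["label"], predicted_label=labels[k],
                probabilities=probs[row_i].copy(), labels=tuple(labels)))
    return preds
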