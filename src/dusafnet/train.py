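"""Training protocol, dataset plumbing and the end-to-end pipeline.

Training follows a fixed-seed protocol: Adam at 1e-3 with a
reduce-on-plateau schedule (factor 0.1, patience 10, floor 1e-6), batch
size 64, up to 150 epochs, cross-entropy over the fused margin logits,
SpecAugment + image-level augmentation on the training stream, and
best-validation-loss weight selection.  Per-epoch progress is logged as
structured lines.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, cross_entropy
from .features import AugmentConfig, image_augment, segment_logmel, segment_to_image, spec_augment
from .metrics import MetricsReport, evaluate
from .model import DuSAFNet, save_checkpoint
from .segment import Segment, balance_corpus, extract_segments, split_dataset

logger = logging.getLogger("dusafnet")

__all__ = [
    "TrainConfig",
    "SpectrogramDataset",
    "prepare_corpus",
    "build_dataset",
    "train",
    "evaluate_model",
    "export_embeddings",
    "mean_logmel_features",
    "logistic_baseline_accuracy",
]


@dataclass(frozen=True)
class TrainConfig:
    seed: int = 1337
    batch_size: int = 64
    epochs: int = 150
    lr: float = 1e-3
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    min_lr: float = 1e-6
    augment: bool = True
    stop_acc: float | None = None  # optional early stop on validation accuracy

    def __post_init__(self):
        if not (0 < self.min_lr < self.lr):
            raise ValueError("need 0 < min_lr < lr")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class SpectrogramDataset:
    """Rendered spectrogram images (N, 224, 224) uint8 with integer labels."""

    images: np.ndarray
    labels: np.ndarray
    classes: list[str]

    def __len__(self):
        return len(self.labels)


def prepare_corpus(
    manifest: str | Path, cap: int = 1000, train_frac: float = 0.7, seed: int = 1337
) -> tuple[list[Segment], list[Segment]]:
    """Manifest -> VAD-extracted 3-s segments -> balance -> stratified split."""
    segments: list[Segment] = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            segments.extend(extract_segments(row["path"], label=str(row["species"])))
    segments = balance_corpus(segments, cap=cap)
    return split_dataset(segments, train_frac=train_frac, seed=seed)


def build_dataset(segments: list[Segment], classes: list[str] | None = None) -> SpectrogramDataset:
    """Render every segment to its 224x224 spectrogram image."""
    if classes is None:
        classes = sorted({s.label for s in segments})
    lut = {c: i for i, c in enumerate(classes)}
    images = np.stack([segment_to_image(s.samples) for s in segments])
    labels = np.array([lut[s.label] for s in segments], dtype=np.int64)
    return SpectrogramDataset(images=images, labels=labels, classes=classes)


def _train_batch(
    images: np.ndarray, aug_cfg: AugmentConfig, rng: np.random.Generator, augment: bool
) -> np.ndarray:
    out = np.empty((len(images), 3, 224, 224), dtype=np.float32)
    for i, img in enumerate(images):
        if augment:
            img = spec_augment(img, aug_cfg, rng)
            out[i] = image_augment(img, aug_cfg, rng, train=True)
        else:
            out[i] = image_augment(img, aug_cfg, train=False)
    return out


def _eval_batchify(images: np.ndarray) -> np.ndarray:
    x = images.astype(np.float32) / 255.0 * 2.0 - 1.0
    return np.repeat(x[:, None], 3, axis=1)


def _val_pass(model: DuSAFNet, ds: SpectrogramDataset, batch: int) -> tuple[float, float]:
    """(validation loss, validation accuracy) with inference-mode logits."""
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(ds), batch):
        x = _eval_batchify(ds.images[i : i + batch])
        y = ds.labels[i : i + batch]
        logits = model(Tensor(x))
        losses.append(float(cross_entropy(logits, y).data) * len(y))
        correct += int((logits.data.argmax(axis=1) == y).sum())
    return sum(losses) / len(ds), correct / len(ds)


def train(
    model: DuSAFNet,
    train_ds: SpectrogramDataset,
    val_ds: SpectrogramDataset,
    cfg: TrainConfig = TrainConfig(),
    aug_cfg: AugmentConfig = AugmentConfig(),
    checkpoint_path: str | Path | None = None,
) -> dict:
    """Seeded training loop returning the best-validation-loss weights.

    The returned history dict holds per-epoch lr / losses / accuracy and
    the best epoch; the model is left loaded with the best weights, and
    ``checkpoint_path`` (if given) receives them as a versioned file.
    Training aborts with a diagnostic on a non-finite loss and stops
    early once ``cfg.stop_acc`` validation accuracy is reached.
    """
    from .autodiff import Adam, ReduceLROnPlateau

    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    sched = ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience, cfg.min_lr)
    best = {"val_loss": np.inf, "epoch": -1, "state": None}
    history = {"epoch": [], "lr": [], "train_loss": [], "val_loss": [], "val_acc": []}

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_ds))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            x = _train_batch(train_ds.images[idx], aug_cfg, rng, cfg.augment)
            y = train_ds.labels[idx]
            opt.zero_grad()
            logits = model(Tensor(x), labels=y)
            loss = cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= len(train_ds)

        val_loss, val_acc = _val_pass(model, val_ds, cfg.batch_size)
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        logger.info(
            "epoch=%d lr=%.2e train_loss=%.4f val_loss=%.4f val_acc=%.4f",
            epoch, opt.lr, epoch_loss, val_loss, val_acc,
        )
        if val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "epoch": epoch, "state": model.state_dict()}
        sched.step(val_loss)
        if cfg.stop_acc is not None and val_acc >= cfg.stop_acc:
            break

    if best["state"] is not None:
        model.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, extra={"best_epoch": best["epoch"]})
    return history


def evaluate_model(model: DuSAFNet, ds: SpectrogramDataset, batch: int = 32) -> MetricsReport:
    """Inference over a dataset and a full metrics report (with AUCs)."""
    scores = model.predict_scores(_eval_batchify(ds.images), batch=batch)
    preds = scores.argmax(axis=1)
    names = np.asarray(ds.classes)
    return evaluate(names[ds.labels], names[preds], classes=list(ds.classes), scores=scores)


def export_embeddings(model: DuSAFNet, ds: SpectrogramDataset, path: str | Path, batch: int = 32):
    """Flattened pre-pool embedding per sample (eval mode) -> .npz file."""
    embs = []
    for i in range(0, len(ds), batch):
        x = _eval_batchify(ds.images[i : i + batch])
        embs.append(model.backbone.embed(Tensor(x)))
    embs = np.concatenate(embs, axis=0)
    np.savez_compressed(path, embeddings=embs, labels=ds.labels, classes=np.asarray(ds.classes))
    return embs


def mean_logmel_features(segments: list[Segment]) -> np.ndarray:
    """Time-averaged 128-dim log-Mel vector per segment (baseline features)."""
    return np.stack([segment_logmel(s.samples).mean(axis=1) for s in segments])


def logistic_baseline_accuracy(
    train_segs: list[Segment], test_segs: list[Segment], seed: int = 0
) -> float:
    """Accuracy of multinomial logistic regression on mean log-Mel vectors."""
    from sklearn.linear_model import LogisticRegression

    xtr, xte = mean_logmel_features(train_segs), mean_logmel_features(test_segs)
    ytr = [s.label for s in train_segs]
    yte = np.asarray([s.label for s in test_segs])
    clf = LogisticRegression(max_iter=2000, random_state=seed).fit(xtr, ytr)
    return float((clf.predict(xte) == yte).mean())
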