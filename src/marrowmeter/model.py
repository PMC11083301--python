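"""Fully convolutional segmentation of hematopoietic vs. adipose tissue.

The network maps an RGB tile to per-pixel probabilities over the two tissue
classes; IGNORE exists only in the labels, where it masks pixels out of the
categorical cross-entropy, never as a prediction target. Two backbones are
available:

``SMALL_CNN``
    Three conv blocks with overall stride-2 downsampling x4 and a mirrored
    transposed-conv decoder. Small enough to train on a desk CPU in
    minutes; the default everywhere.

``INCEPTIONV3_MIXED7``
    A deeper inception-style trunk (parallel 1x1 / 3x3 / double-3x3
    branches, x16 downsampling) truncated at mixed-block depth, followed by
    a nine-stage conv/deconv decoder and a 1x1 softmax head. Weights are
    randomly initialised; no pretrained trunk is downloaded.

Training uses Adam on masked categorical cross-entropy and is exactly
reproducible given the config seed (pure numpy, single-threaded math).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import nn
from .annotations import ADIPOSE, HEMATO, IGNORE, DatasetManifest, LabelMask


class Backbone(str, Enum):
    SMALL_CNN = "small_cnn"
    INCEPTIONV3_MIXED7 = "inceptionv3_mixed7"


_STRIDE_FACTOR = {Backbone.SMALL_CNN: 4, Backbone.INCEPTIONV3_MIXED7: 16}


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``decoder_layers`` records the number of conv/deconv stages in the
    inception decoder (nine by default); the small backbone uses its fixed
    mirrored decoder.

    The three jitter fields enable scanner-style training augmentation
    (all default off): ``color_jitter`` is the amplitude of per-image
    random channel offsets in intensity units on the 0-255 scale,
    ``gain_jitter`` the fractional amplitude of per-channel multiplicative
    gain, and ``blur_jitter`` the maximum sigma (px) of a per-image
    Gaussian blur. Together they span the same perturbation family a
    second slide scanner introduces.
    """

    backbone: Backbone = Backbone.SMALL_CNN
    decoder_layers: int = 9
    n_classes: int = 2
    input_size: int = 256
    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 8
    color_jitter: float = 0.0
    gain_jitter: float = 0.0
    blur_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.backbone = Backbone(self.backbone)
        if self.n_classes != 2:
            raise ValueError(f"n_classes: must be 2 (HEMATO, ADIPOSE), got {self.n_classes}")
        if self.epochs < 1:
            raise ValueError(f"epochs: must be >= 1, got {self.epochs}")
        if self.decoder_layers < 1:
            raise ValueError(f"decoder_layers: must be >= 1, got {self.decoder_layers}")
        factor = _STRIDE_FACTOR[self.backbone]
        if self.input_size % factor != 0 or self.input_size < factor:
            raise ValueError(
                f"input_size: {self.input_size} not divisible by the "
                f"{self.backbone.value} downsampling factor {factor}"
            )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = self.__dict__.copy()
        d["backbone"] = self.backbone.value
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TrainingHistory:
    """Per-epoch loss and masked pixel accuracy for train and validation."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        ).to_csv(path, index=False)
        return path

    def plot(self, path: str | Path) -> Path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        path = Path(path)
        epochs = np.arange(1, len(self.train_loss) + 1)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        ax1.plot(epochs, self.train_loss, label="train")
        if any(np.isfinite(self.val_loss)):
            ax1.plot(epochs, self.val_loss, label="validation")
        ax1.set_xlabel("epoch"), ax1.set_ylabel("masked cross-entropy"), ax1.legend()
        ax2.plot(epochs, self.train_acc, label="train")
        if any(np.isfinite(self.val_acc)):
            ax2.plot(epochs, self.val_acc, label="validation")
        ax2.set_xlabel("epoch"), ax2.set_ylabel("masked pixel accuracy"), ax2.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


class SegmentationModel:
    """A built network plus its config; use :func:`build_model` to create."""

    def __init__(self, config: ModelConfig, net: nn.Sequential) -> None:
        self.config = config
        self.net = net

    # -- inference ----------------------------------------------------------

    def _normalise(self, batch: np.ndarray) -> np.ndarray:
        return (batch.astype(np.float32) / 255.0) - 0.5

    def forward_logits(self, batch: np.ndarray) -> np.ndarray:
        """(N, s, s, 3) uint8/float -> (N, s, s, 2) raw scores."""
        s = self.config.input_size
        if batch.ndim != 4 or batch.shape[1:] != (s, s, 3):
            raise ValueError(
                f"batch: expected (N, {s}, {s}, 3), got {batch.shape}"
            )
        return self.net.forward(self._normalise(batch))

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities; rows sum to 1 per pixel."""
        return nn.softmax(self.forward_logits(batch))

    def predict_tile(self, rgb_tile: np.ndarray) -> LabelMask:
        """Argmax segmentation of one tile (HEMATO/ADIPOSE only).

        Ties go to the lowest class index, i.e. HEMATO.
        """
        s = self.config.input_size
        rgb_tile = np.asarray(rgb_tile)
        if rgb_tile.shape != (s, s, 3):
            raise ValueError(
                f"rgb_tile: expected ({s}, {s}, 3), got {rgb_tile.shape}"
            )
        probs = self.predict_proba(rgb_tile[None])[0]
        return LabelMask(probs.argmax(axis=-1).astype(np.uint8))

    def n_params(self) -> int:
        return self.net.n_params()

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write weights (.npz) plus a JSON config sidecar."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez(path, **self.net.state_dict())
        self.config.to_json(path.with_suffix(".json"))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        path = Path(path)
        config = ModelConfig.from_json(path.with_suffix(".json"))
        model = build_model(config)
        with np.load(path) as data:
            model.net.load_state_dict({k: data[k] for k in data.files})
        return model


def build_model(config: ModelConfig) -> SegmentationModel:
    """Construct the FCN for ``config``; weights seeded from ``config.seed``."""
    rng = np.random.default_rng([config.seed, 0xC0FFEE % 2**16])
    C, T, R = nn.Conv2d, nn.ConvTranspose2d, nn.ReLU
    if config.backbone is Backbone.SMALL_CNN:
        layers = [
            C(3, 16, 3, 1, rng), R(),
            C(16, 32, 3, 2, rng), R(),
            C(32, 48, 3, 2, rng), R(),
            C(48, 48, 3, 1, rng), R(),
            T(48, 32, rng), R(),
            C(32, 32, 3, 1, rng), R(),
            T(32, 16, rng), R(),
            C(16, 16, 3, 1, rng), R(),
            C(16, 2, 1, 1, rng),
        ]
    else:
        layers = [
            # inception-style trunk, x16 downsampling
            C(3, 32, 3, 2, rng), R(),
            C(32, 32, 3, 1, rng), R(),
            C(32, 64, 3, 2, rng), R(),
            C(64, 96, 3, 2, rng), R(),
            nn.InceptionBlock(96, 32, 48, 32, rng),
            C(112, 128, 3, 2, rng), R(),
            nn.InceptionBlock(128, 48, 64, 48, rng),
            # nine-stage conv/deconv decoder + softmax head
            C(160, 128, 3, 1, rng), R(),
            T(128, 96, rng), R(),
            C(96, 96, 3, 1, rng), R(),
            T(96, 64, rng), R(),
            C(64, 64, 3, 1, rng), R(),
            T(64, 32, rng), R(),
            T(32, 16, rng), R(),
            C(16, 16, 3, 1, rng), R(),
            C(16, 2, 1, 1, rng),
        ]
    return SegmentationModel(config, nn.Sequential(layers))


# ---------------------------------------------------------------------------
# masked loss


def _one_hot_and_valid(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    valid = labels != IGNORE
    onehot = np.zeros(labels.shape + (2,), dtype=np.float32)
    onehot[..., HEMATO] = (labels == HEMATO) & valid
    onehot[..., ADIPOSE] = (labels == ADIPOSE) & valid
    return onehot, valid


def masked_loss(probabilities: np.ndarray, label_mask: LabelMask | np.ndarray) -> float:
    """Mean categorical cross-entropy over non-IGNORE pixels only.

    If every pixel is IGNORE the loss is defined as 0 and a warning is
    emitted. Relabelling IGNORE pixels leaves the value unchanged.
    """
    labels = label_mask.classes if isinstance(label_mask, LabelMask) else np.asarray(label_mask)
    probs = np.asarray(probabilities)
    if probs.shape[:-1] != labels.shape or probs.shape[-1] != 2:
        raise ValueError(
            f"shape mismatch: probabilities {probs.shape} vs labels {labels.shape}"
        )
    valid = labels != IGNORE
    n_valid = int(valid.sum())
    if n_valid == 0:
        warnings.warn("all pixels IGNORE; masked loss defined as 0", stacklevel=2)
        return 0.0
    p_true = np.take_along_axis(
        probs, np.where(valid, labels, 0)[..., None].astype(np.int64), axis=-1
    )[..., 0]
    logp = np.log(np.clip(p_true, 1e-12, None))
    return float(-(logp * valid).sum() / n_valid)


def masked_accuracy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of non-IGNORE pixels whose argmax matches the label."""
    valid = labels != IGNORE
    if not valid.any():
        return float("nan")
    pred = np.asarray(probabilities).argmax(axis=-1)
    return float((pred == labels)[valid].mean())


# ---------------------------------------------------------------------------
# training


def _load_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    images, labels = [], []
    for pair in pairs:
        img, mask = pair.load()
        images.append(img)
        labels.append(mask.classes)
    return np.stack(images), np.stack(labels)


def train_on_arrays(
    model: SegmentationModel,
    images: np.ndarray,
    labels: np.ndarray,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[SegmentationModel, TrainingHistory]:
    """Train in-place on in-memory arrays; returns (model, history).

    ``images``: (N, s, s, 3) uint8; ``labels``: (N, s, s) class codes with
    IGNORE pixels masked out of loss and gradients. Deterministic given the
    model config's seed.
    """
    cfg = model.config
    n = len(images)
    if n == 0:
        raise ValueError("empty training set")
    if images.shape[:1] != labels.shape[:1] or images.shape[1:3] != labels.shape[1:3]:
        raise ValueError(
            f"shape mismatch: images {images.shape} vs labels {labels.shape}"
        )
    shuffle_rng = np.random.default_rng([cfg.seed, 7])
    jitter_rng = np.random.default_rng([cfg.seed, 11])
    opt = nn.Adam(model.net, lr=cfg.learning_rate)
    history = TrainingHistory()

    for _epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, epoch_correct, epoch_valid = 0.0, 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = images[idx].astype(np.float32)
            if cfg.color_jitter > 0 or cfg.gain_jitter > 0 or cfg.blur_jitter > 0:
                if cfg.blur_jitter > 0:
                    from scipy import ndimage

                    sigmas = jitter_rng.uniform(0, cfg.blur_jitter, len(idx))
                    xb = np.stack(
                        [
                            ndimage.gaussian_filter(img, (s, s, 0)) if s > 0.05 else img
                            for img, s in zip(xb, sigmas)
                        ]
                    )
                if cfg.gain_jitter > 0:
                    xb = xb * jitter_rng.uniform(
                        1 - cfg.gain_jitter, 1 + cfg.gain_jitter, (len(idx), 1, 1, 3)
                    ).astype(np.float32)
                if cfg.color_jitter > 0:
                    xb = xb + jitter_rng.uniform(
                        -cfg.color_jitter, cfg.color_jitter, (len(idx), 1, 1, 3)
                    ).astype(np.float32)
                xb = np.clip(xb, 0, 255)
            yb = labels[idx]
            logits = model.forward_logits(xb)
            probs = nn.softmax(logits)
            onehot, valid = _one_hot_and_valid(yb)
            n_valid = int(valid.sum())
            if n_valid == 0:
                continue
            p_true = (probs * onehot).sum(axis=-1)
            batch_loss = float(
                -(np.log(np.clip(p_true, 1e-12, None)) * valid).sum() / n_valid
            )
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {_epoch + 1}; aborting "
                    f"(learning rate {cfg.learning_rate}, batch {start // cfg.batch_size})"
                )
            dlogits = (probs - onehot) * valid[..., None] / n_valid
            model.net.backward(dlogits.astype(np.float32))
            opt.step()
            epoch_loss += batch_loss * n_valid
            epoch_correct += int(((probs.argmax(-1) == yb) & valid).sum())
            epoch_valid += n_valid

        history.train_loss.append(epoch_loss / max(epoch_valid, 1))
        history.train_acc.append(epoch_correct / max(epoch_valid, 1))
        if val_images is not None and len(val_images):
            vloss, vacc = evaluate(model, val_images, val_labels)
            history.val_loss.append(vloss)
            history.val_acc.append(vacc)
        else:
            history.val_loss.append(float("nan"))
            history.val_acc.append(float("nan"))
    return model, history


def evaluate(
    model: SegmentationModel, images: np.ndarray, labels: np.ndarray, batch_size: int = 8
) -> tuple[float, float]:
    """Masked loss and pixel accuracy over a dataset."""
    total_loss, total_correct, total_valid = 0.0, 0, 0
    for start in range(0, len(images), batch_size):
        xb = images[start : start + batch_size]
        yb = labels[start : start + batch_size]
        probs = model.predict_proba(xb)
        valid = yb != IGNORE
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue
        onehot, _ = _one_hot_and_valid(yb)
        p_true = (probs * onehot).sum(axis=-1)
        total_loss += float(-(np.log(np.clip(p_true, 1e-12, None)) * valid).sum())
        total_correct += int(((probs.argmax(-1) == yb) & valid).sum())
        total_valid += n_valid
    if total_valid == 0:
        return float("nan"), float("nan")
    return total_loss / total_valid, total_correct / total_valid


def train(
    model: SegmentationModel, manifest: DatasetManifest
) -> tuple[SegmentationModel, TrainingHistory]:
    """Train from a dataset manifest (decodes all pairs into memory)."""
    if not manifest.train_idx:
        raise ValueError("manifest has an empty training split")
    images, labels = _load_pairs(manifest.train_pairs)
    if manifest.val_idx:
        val_images, val_labels = _load_pairs(manifest.val_pairs)
    else:
        val_images = val_labels = None
    return train_on_arrays(model, images, labels, val_images, val_labels)
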