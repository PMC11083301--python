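"""Reading and writing training pairs in the QuPath-export convention.

Training data consists of RGB tiles paired with colour-coded label PNGs:
black marks hematopoietic tissue, yellow adipose tissue, and white the
regions (bone, erythrocytes, artifacts) that the training loss must ignore.
This module owns the palette, the integer class codes, and the dataset
manifest used to drive training.

Class codes are stable public API::

    HEMATO = 0   black  (0, 0, 0)
    ADIPOSE = 1  yellow (255, 255, 0)
    IGNORE = 2   white  (255, 255, 255)

Pixel coordinates are row-major, origin top-left, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

HEMATO = 0
ADIPOSE = 1
IGNORE = 2

#: RGB palette indexed by class code.
PALETTE = np.array(
    [
        [0, 0, 0],  # HEMATO
        [255, 255, 0],  # ADIPOSE
        [255, 255, 255],  # IGNORE
    ],
    dtype=np.uint8,
)

CLASS_NAMES = ("HEMATO", "ADIPOSE", "IGNORE")

#: Default per-channel (Chebyshev) tolerance when snapping off-palette pixels.
#: Absorbs anti-aliasing/interpolation artifacts at exported region borders.
DEFAULT_TOLERANCE = 16


class LabelDecodeError(ValueError):
    """A label PNG contains a pixel too far from every palette colour."""


@dataclass
class LabelMask:
    """Per-pixel class map over {HEMATO, ADIPOSE, IGNORE}.

    Parameters
    ----------
    classes
        2-D uint8 array of class codes.
    """

    classes: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.classes)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"classes: expected non-empty 2-D array, got shape {arr.shape}")
        if not np.isin(arr, (HEMATO, ADIPOSE, IGNORE)).all():
            bad = np.setdiff1d(np.unique(arr), [HEMATO, ADIPOSE, IGNORE])
            raise ValueError(f"classes: values outside {{0,1,2}} present: {bad.tolist()}")
        self.classes = arr.astype(np.uint8, copy=False)

    @property
    def height(self) -> int:
        return self.classes.shape[0]

    @property
    def width(self) -> int:
        return self.classes.shape[1]

    def class_counts(self) -> dict[str, int]:
        """Pixel count per class; counts always partition height*width."""
        return {
            name: int((self.classes == code).sum())
            for code, name in enumerate(CLASS_NAMES)
        }

    def cellularity(self) -> float:
        """Mask-derived cellularity: % HEMATO among non-IGNORE pixels."""
        h = float((self.classes == HEMATO).sum())
        a = float((self.classes == ADIPOSE).sum())
        if h + a == 0:
            raise ValueError("cellularity undefined: mask has no tissue pixels")
        return 100.0 * h / (h + a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMask):
            return NotImplemented
        return self.classes.shape == other.classes.shape and bool(
            (self.classes == other.classes).all()
        )


def _load_rgb(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def decode_label_png(path: str | Path, tolerance: int = DEFAULT_TOLERANCE) -> LabelMask:
    """Decode a colour-coded label PNG into a :class:`LabelMask`.

    Each pixel is assigned the palette colour nearest in max-channel
    (Chebyshev) distance. Alpha channels are dropped. A pixel farther than
    ``tolerance`` from every palette colour raises :class:`LabelDecodeError`
    reporting its coordinate and RGB value.
    """
    rgb = _load_rgb(path).astype(np.int16)
    # (H, W, n_classes) Chebyshev distance to each palette colour
    dist = np.abs(rgb[:, :, None, :] - PALETTE[None, None, :, :].astype(np.int16)).max(axis=3)
    nearest = dist.argmin(axis=2)
    mindist = dist.min(axis=2)
    bad = mindist > tolerance
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise LabelDecodeError(
            f"{path}: pixel (row={r}, col={c}) with RGB {tuple(int(v) for v in rgb[r, c])} "
            f"is farther than tolerance {tolerance} from every palette colour"
        )
    return LabelMask(nearest.astype(np.uint8))


def encode_label_png(mask: LabelMask, path: str | Path) -> Path:
    """Write a mask as a colour-coded PNG using exact palette colours.

    ``decode_label_png(encode_label_png(m)) == m`` for every valid mask.
    """
    path = Path(path)
    rgb = PALETTE[mask.classes]
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return path


@dataclass
class TrainingPair:
    """An image tile and its label mask, matched by filename stem."""

    image_path: Path
    label_path: Path
    tile_size: int
    magnification_tag: str = "20x"

    def load(self) -> tuple[np.ndarray, LabelMask]:
        return _load_rgb(self.image_path), decode_label_png(self.label_path)


@dataclass
class DatasetManifest:
    """Train/validation assignment over a directory of training pairs."""

    pairs: list[TrainingPair]
    train_idx: list[int]
    val_idx: list[int]
    seed: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.val_idx):
            raise ValueError("train/validation splits overlap")
        if sorted(self.train_idx + self.val_idx) != list(range(len(self.pairs))):
            raise ValueError("splits do not cover all pairs exactly once")

    @property
    def train_pairs(self) -> list[TrainingPair]:
        return [self.pairs[i] for i in self.train_idx]

    @property
    def val_pairs(self) -> list[TrainingPair]:
        return [self.pairs[i] for i in self.val_idx]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "warnings": self.warnings,
            "train_idx": self.train_idx,
            "val_idx": self.val_idx,
            "pairs": [
                {
                    "image_path": str(p.image_path),
                    "label_path": str(p.label_path),
                    "tile_size": p.tile_size,
                    "magnification_tag": p.magnification_tag,
                }
                for p in self.pairs
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        pairs = [
            TrainingPair(
                image_path=Path(d["image_path"]),
                label_path=Path(d["label_path"]),
                tile_size=d["tile_size"],
                magnification_tag=d.get("magnification_tag", "20x"),
            )
            for d in payload["pairs"]
        ]
        return cls(
            pairs=pairs,
            train_idx=payload["train_idx"],
            val_idx=payload["val_idx"],
            seed=payload["seed"],
            warnings=payload.get("warnings", []),
        )


_IMAGE_SUFFIXES = (".tiff", ".tif", ".png")


def build_manifest(
    directory: str | Path, val_fraction: float = 0.2, seed: int = 0
) -> DatasetManifest:
    """Pair images with labels by filename stem and split train/validation.

    Expects ``<directory>/images/<stem>.{tiff,tif,png}`` paired with
    ``<directory>/labels/<stem>.png``. Orphan files are reported in the
    manifest's ``warnings`` and excluded. An image whose decoded shape does
    not match its label raises ``ValueError``. The split is a seeded shuffle,
    deterministic across runs.
    """
    directory = Path(directory)
    if not 0 <= val_fraction <= 1:
        raise ValueError(f"val_fraction: must be in [0,1], got {val_fraction}")
    img_dir, lbl_dir = directory / "images", directory / "labels"
    if not img_dir.is_dir() or not lbl_dir.is_dir():
        raise FileNotFoundError(f"{directory} must contain images/ and labels/ subdirectories")

    images = {p.stem: p for p in sorted(img_dir.iterdir()) if p.suffix.lower() in _IMAGE_SUFFIXES}
    labels = {p.stem: p for p in sorted(lbl_dir.iterdir()) if p.suffix.lower() == ".png"}

    warnings = []
    for stem in sorted(set(images) - set(labels)):
        warnings.append(f"orphan image with no label: {images[stem].name}")
    for stem in sorted(set(labels) - set(images)):
        warnings.append(f"orphan label with no image: {labels[stem].name}")

    pairs = []
    for stem in sorted(set(images) & set(labels)):
        img = _load_rgb(images[stem])
        mask = decode_label_png(labels[stem])
        if img.shape[:2] != mask.classes.shape:
            raise ValueError(
                f"shape mismatch for stem '{stem}': image {img.shape[:2]} "
                f"vs label {mask.classes.shape}"
            )
        pairs.append(
            TrainingPair(
                image_path=images[stem], label_path=labels[stem], tile_size=img.shape[0]
            )
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs)).tolist()
    n_val = int(round(val_fraction * len(pairs)))
    return DatasetManifest(
        pairs=pairs,
        train_idx=sorted(order[n_val:]),
        val_idx=sorted(order[:n_val]),
        seed=seed,
        warnings=warnings,
    )
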