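"""Seeded synthetic H&E-like marrow imagery with known ground truth.

Real bone-marrow sections show two chromatically distinct compartments:
hematopoietic tissue (densely packed basophilic nuclei on pink stroma) and
adipose tissue (near-white fat vacuoles with thin eosinophilic rims).
This module draws caricatures of both — separable by a small conv net yet
non-trivial (overlapping vacuoles, colour jitter, texture noise) — plus the
structures a training loss must ignore: pale trabecular bone bands inside
tiles and the white glass margin around a slide's tissue core.

Every generator takes a single explicit seed; no global RNG state is used,
and identical specs yield bit-identical images and masks.

Not modelled (out of scope): staining physics, megakaryocyte or fibrosis
morphology, photorealistic chromatin texture.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .annotations import ADIPOSE, HEMATO, IGNORE, LabelMask

# ---------------------------------------------------------------------------
# colour constants (RGB, uint8 scale)

_STROMA = np.array([231.0, 178.0, 191.0])  # eosinophilic pink
_NUCLEUS = np.array([72.0, 48.0, 122.0])  # basophilic blue-purple
_ADIPOSE_FILL = np.array([228.0, 220.0, 232.0])  # near-white vacuole
_ADIPOSE_RIM = np.array([213.0, 148.0, 168.0])  # thin pink rim
_BONE = np.array([233.0, 221.0, 158.0])  # pale-yellow trabecula
_GLASS = np.array([250.0, 250.0, 250.0])  # slide background


class ScannerProfile(str, Enum):
    """Colour/blur perturbation family emulating a second slide scanner."""

    REFERENCE = "reference"
    ALT = "alt"


@dataclass
class TileSpec:
    """Parameters of one synthetic training tile.

    ``nuclei_density`` is nuclei per 1000 px^2 of hematopoietic area;
    ``ignore_fraction`` is the fraction of pixels given to bone bands.
    """

    tile_size: int = 256
    target_cellularity: float = 50.0
    adipocyte_radius_range: tuple[int, int] = (4, 12)
    nuclei_density: float = 30.0
    ignore_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_size < 32:
            raise ValueError(f"tile_size: must be >= 32, got {self.tile_size}")
        if not 0 <= self.target_cellularity <= 100:
            raise ValueError(
                f"target_cellularity: must be in [0,100], got {self.target_cellularity}"
            )
        rmin, rmax = self.adipocyte_radius_range
        if not (1 <= rmin <= rmax):
            raise ValueError(
                f"adipocyte_radius_range: need 1 <= min <= max, got {self.adipocyte_radius_range}"
            )
        if not 0 <= self.ignore_fraction <= 0.3:
            raise ValueError(
                f"ignore_fraction: must be in [0,0.3], got {self.ignore_fraction}"
            )
        if self.nuclei_density < 0:
            raise ValueError(f"nuclei_density: must be >= 0, got {self.nuclei_density}")


@dataclass
class SlideSpec:
    """Parameters of one synthetic pseudo-WSI (tissue core on glass)."""

    width: int = 1024
    height: int = 1024
    target_cellularity: float = 50.0
    scanner_profile: ScannerProfile = ScannerProfile.REFERENCE
    margin: int = 12
    adipocyte_radius_range: tuple[int, int] = (4, 12)
    nuclei_density: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height) < 64:
            raise ValueError(
                f"width/height: slide must be at least 64 px per side, "
                f"got {self.width}x{self.height}"
            )
        if not 0 <= self.target_cellularity <= 100:
            raise ValueError(
                f"target_cellularity: must be in [0,100], got {self.target_cellularity}"
            )
        if self.margin < 0 or 2 * self.margin >= min(self.width, self.height):
            raise ValueError(f"margin: must leave a tissue core, got {self.margin}")
        self.scanner_profile = ScannerProfile(self.scanner_profile)


@dataclass
class RaterProfile:
    """A simulated human observer reading cellularity off a slide.

    Pathologists conventionally report cellularity in 5% increments; the
    profile adds a systematic bias, zero-mean Gaussian noise, then rounds
    half-up to the nearest increment and clamps to [0, 100].
    """

    bias: float = 0.0
    noise_sd: float = 5.0
    rounding_increment: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounding_increment <= 0:
            raise ValueError(
                f"rounding_increment: must be > 0, got {self.rounding_increment}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0, got {self.noise_sd}")


# ---------------------------------------------------------------------------
# geometry helpers


def _paint_bands(rng: np.random.Generator, classes: np.ndarray, fraction: float) -> None:
    """Overwrite ~``fraction`` of pixels with IGNORE as elongated bands."""
    h, w = classes.shape
    total = h * w
    target = int(round(fraction * total))
    guard = 0
    while (classes == IGNORE).sum() < target and guard < 200:
        guard += 1
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        theta = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 0.9) * min(h, w)
        half_w = rng.uniform(2.0, max(2.5, 0.02 * min(h, w) + 2))
        dy, dx = np.sin(theta), np.cos(theta)
        yy, xx = np.mgrid[0:h, 0:w]
        # distance from pixel to the band's centre segment
        py, px = yy - cy, xx - cx
        t = np.clip(py * dy + px * dx, -length / 2, length / 2)
        dist = np.hypot(py - t * dy, px - t * dx)
        classes[dist <= half_w] = IGNORE


def _place_adipocytes(
    rng: np.random.Generator,
    classes: np.ndarray,
    target_cellularity: float,
    radius_range: tuple[int, int],
) -> list[tuple[int, int, int]]:
    """Paint ADIPOSE discs until the non-IGNORE HEMATO fraction hits target.

    Returns the disc list (row, col, radius) for rim rendering.
    """
    h, w = classes.shape
    non_ignore = classes != IGNORE
    n_tissue = int(non_ignore.sum())
    target_adipose = int(round((1.0 - target_cellularity / 100.0) * n_tissue))
    rmin, rmax = radius_range
    discs: list[tuple[int, int, int]] = []

    if target_adipose >= n_tissue:  # degenerate all-fat field
        classes[non_ignore] = ADIPOSE
        return discs

    tol = max(1, int(0.002 * n_tissue))
    current = 0
    for _ in range(50_000):
        if current >= target_adipose - tol:
            break
        cy = int(rng.integers(0, h))
        cx = int(rng.integers(0, w))
        r = int(rng.integers(rmin, rmax + 1))
        # shrink the disc if it would overshoot the target area
        painted = False
        for rr in range(r, rmin - 1, -1):
            rrows, rcols = skdraw.disk((cy, cx), rr, shape=(h, w))
            gain_mask = non_ignore[rrows, rcols] & (classes[rrows, rcols] != ADIPOSE)
            gain = int(gain_mask.sum())
            if current + gain <= target_adipose + tol:
                classes[rrows[gain_mask], rcols[gain_mask]] = ADIPOSE
                current += gain
                discs.append((cy, cx, rr))
                painted = True
                break
        if not painted:
            # even the smallest disc overshoots; paint it only if that lands
            # closer to the target than stopping short would
            rrows, rcols = skdraw.disk((cy, cx), rmin, shape=(h, w))
            gain_mask = non_ignore[rrows, rcols] & (classes[rrows, rcols] != ADIPOSE)
            gain = int(gain_mask.sum())
            if abs(current + gain - target_adipose) < abs(current - target_adipose):
                classes[rrows[gain_mask], rcols[gain_mask]] = ADIPOSE
                current += gain
                discs.append((cy, cx, rmin))
            break
    return discs


def _scatter_nuclei(
    rng: np.random.Generator, rgb: np.ndarray, classes: np.ndarray, density: float
) -> None:
    """Draw elliptical nuclei on the hematopoietic compartment.

    Placement is random with a coarse occupancy-grid rejection so nuclei do
    not pile onto one spot (a cheap Poisson-disc stand-in).
    """
    hemato = classes == HEMATO
    n_hemato = int(hemato.sum())
    n_nuclei = int(round(density * n_hemato / 1000.0))
    if n_nuclei == 0:
        return
    h, w = classes.shape
    coords = np.argwhere(hemato)
    occupied = np.zeros((h // 2 + 1, w // 2 + 1), dtype=bool)
    picks = rng.integers(0, len(coords), size=3 * n_nuclei)
    placed = 0
    for idx in picks:
        if placed >= n_nuclei:
            break
        cy, cx = coords[idx]
        gy, gx = cy // 2, cx // 2
        if occupied[gy, gx]:
            continue
        occupied[gy, gx] = True
        a = rng.uniform(1.4, 2.8)
        b = rng.uniform(1.0, 1.8)
        theta = rng.uniform(0, np.pi)
        rrows, rcols = skdraw.ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        keep = classes[rrows, rcols] == HEMATO
        colour = _NUCLEUS + rng.normal(0, 10, 3)
        rgb[rrows[keep], rcols[keep]] = colour
        placed += 1


def _render_field(
    rng: np.random.Generator,
    classes: np.ndarray,
    discs: list[tuple[int, int, int]],
    nuclei_density: float,
) -> np.ndarray:
    """Render an RGB image for a finished class layout."""
    h, w = classes.shape
    rgb = np.empty((h, w, 3), dtype=np.float64)
    rgb[:] = _STROMA
    rgb += rng.normal(0, 6, (h, w, 3))
    # low-frequency eosin blotch
    blotch = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=max(4, h // 16))
    rgb += 40.0 * blotch[:, :, None] * np.array([0.3, 1.0, 0.6])

    adipose = classes == ADIPOSE
    rgb[adipose] = _ADIPOSE_FILL + rng.normal(0, 3, (int(adipose.sum()), 3))
    for cy, cx, r in discs:
        for rr in (r, max(1, r - 1)):
            prow, pcol = skdraw.circle_perimeter(cy, cx, rr, shape=(h, w))
            keep = classes[prow, pcol] == ADIPOSE
            rgb[prow[keep], pcol[keep]] = _ADIPOSE_RIM

    _scatter_nuclei(rng, rgb, classes, nuclei_density)

    bone = classes == IGNORE
    if bone.any():
        rgb[bone] = _BONE + rng.normal(0, 4, (int(bone.sum()), 3))

    rgb += rng.uniform(-4, 4, 3)  # per-field scanner colour jitter
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _generate_field(
    rng: np.random.Generator,
    height: int,
    width: int,
    target_cellularity: float,
    radius_range: tuple[int, int],
    nuclei_density: float,
    ignore_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    classes = np.full((height, width), HEMATO, dtype=np.uint8)
    if ignore_fraction > 0:
        _paint_bands(rng, classes, ignore_fraction)
    discs = _place_adipocytes(rng, classes, target_cellularity, radius_range)
    rgb = _render_field(rng, classes, discs, nuclei_density)
    return rgb, classes


# ---------------------------------------------------------------------------
# public generators


def generate_tile(spec: TileSpec) -> tuple[np.ndarray, LabelMask]:
    """Generate one training tile and its label mask.

    Among non-IGNORE pixels the HEMATO fraction lands within a few
    percentage points of ``spec.target_cellularity``; the emitted mask is
    the ground truth, bit-identical across runs with the same spec.
    """
    rng = np.random.default_rng(spec.seed)
    rgb, classes = _generate_field(
        rng,
        spec.tile_size,
        spec.tile_size,
        spec.target_cellularity,
        spec.adipocyte_radius_range,
        spec.nuclei_density,
        spec.ignore_fraction,
    )
    return rgb, LabelMask(classes)


def generate_slide(spec: SlideSpec) -> tuple[np.ndarray, LabelMask, float]:
    """Generate a pseudo-WSI: a tissue core surrounded by white glass margin.

    The glass margin is IGNORE in the mask. ``true_cellularity`` is
    recomputed exactly from the emitted mask (HEMATO / (HEMATO+ADIPOSE)),
    not echoed from the target, so downstream recovery is measured against
    mask-derived truth.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, m = spec.height, spec.width, spec.margin
    classes = np.full((h, w), IGNORE, dtype=np.uint8)
    core_rgb, core_classes = _generate_field(
        rng,
        h - 2 * m,
        w - 2 * m,
        spec.target_cellularity,
        spec.adipocyte_radius_range,
        spec.nuclei_density,
        ignore_fraction=0.0,
    )
    rgb = np.empty((h, w, 3), dtype=np.float64)
    rgb[:] = _GLASS
    rgb += rng.normal(0, 1.5, (h, w, 3))
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    if m > 0:
        rgb[m:-m, m:-m] = core_rgb
        classes[m:-m, m:-m] = core_classes
    else:
        rgb, classes = core_rgb, core_classes

    if spec.scanner_profile is ScannerProfile.ALT:
        rgb = rescan_variant(rgb, ScannerProfile.ALT, seed=spec.seed)

    mask = LabelMask(classes)
    return rgb, mask, mask.cellularity()


def rescan_variant(
    rgb: np.ndarray, profile: ScannerProfile, seed: int = 0
) -> np.ndarray:
    """Simulate digitising the same glass slide on a different scanner.

    The ALT profile applies a bounded per-channel gain/offset shift (mean
    shift at most ~15 intensity units) and a mild Gaussian blur; geometry is
    unchanged, so the ground-truth mask still applies. REFERENCE returns the
    image unchanged. Deterministic given the seed.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"rgb: expected (H, W, 3) image, got shape {rgb.shape}")
    profile = ScannerProfile(profile)
    if profile is ScannerProfile.REFERENCE:
        return rgb.copy()
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-8, 8, 3)
    gains = rng.uniform(0.97, 1.03, 3)
    sigma = rng.uniform(0.3, 0.7)
    out = rgb.astype(np.float64)
    out = ndimage.gaussian_filter(out, sigma=(sigma, sigma, 0))
    out = out * gains + offsets
    return np.clip(out, 0, 255).astype(np.uint8)


def simulate_rater(
    true_values: "np.ndarray | list[float]", profile: RaterProfile
) -> np.ndarray:
    """Turn true cellularities into one observer's reported percentages.

    rating = clamp(round_half_up(true + bias + N(0, noise_sd), increment), 0, 100)
    """
    values = np.asarray(true_values, dtype=np.float64)
    if values.size and (values.min() < 0 or values.max() > 100):
        bad = values[(values < 0) | (values > 100)][0]
        raise ValueError(f"true_values: {bad} outside [0, 100]")
    rng = np.random.default_rng(profile.seed)
    raw = values + profile.bias + rng.normal(0, profile.noise_sd, values.shape)
    inc = profile.rounding_increment
    rounded = np.floor(raw / inc + 0.5) * inc  # round half up
    return np.clip(rounded, 0.0, 100.0)


# ---------------------------------------------------------------------------
# disk output helpers (CLI surface)


def save_tile(
    outdir: str | Path, stem: str, spec: TileSpec, image_format: str = "png"
) -> dict[str, str]:
    """Generate a tile and write image + label PNG + JSON sidecar."""
    import json

    from . import annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rgb, mask = generate_tile(spec)
    if image_format == "tiff":
        import tifffile

        img_path = outdir / f"{stem}.tiff"
        tifffile.imwrite(img_path, rgb)
    else:
        from PIL import Image

        img_path = outdir / f"{stem}.png"
        Image.fromarray(rgb).save(img_path)
    lbl_path = annotations.encode_label_png(mask, outdir / f"{stem}_label.png")
    sidecar = {
        "stem": stem,
        "seed": spec.seed,
        "target_cellularity": spec.target_cellularity,
        "mask_cellularity": mask.cellularity()
        if spec.target_cellularity not in (None,)
        else None,
        "tile_size": spec.tile_size,
        "ignore_fraction": spec.ignore_fraction,
    }
    side_path = outdir / f"{stem}.json"
    side_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": str(img_path), "label": str(lbl_path), "sidecar": str(side_path)}
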