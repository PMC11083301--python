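"""Slide-level inference: tile, segment, stitch, overlay, cellularity.

A slide image is cut into non-overlapping ``tile_size`` patches (edge tiles
padded with white; padded pixels are flagged and excluded from all area
counts), each patch is segmented, and the per-tile label maps are stitched
back to slide geometry. Cellularity is the percentage of the combined
tissue area occupied by hematopoietic tissue:

    cellularity = 100 * area_hemato / (area_hemato + area_adipose)

Near-white pixels (all channels above a configurable threshold, default
235) are treated as slide glass/background and excluded from both areas
before the ratio is formed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import ADIPOSE, HEMATO, LabelMask
from .model import SegmentationModel

#: Stitched-map code for pixels excluded from both areas (padding/background).
EXCLUDED = 2

#: Default all-channel background (slide glass) threshold.
DEFAULT_BACKGROUND_THRESHOLD = 235

_OVERLAY_COLOURS = {
    HEMATO: np.array([0, 255, 0], dtype=np.float64),  # green
    ADIPOSE: np.array([0, 0, 255], dtype=np.float64),  # blue
}


@dataclass
class TileGrid:
    """Non-overlapping tiling of a slide; tiles cover every pixel once."""

    tile_size: int
    slide_height: int
    slide_width: int
    origins: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return -(-self.slide_height // self.tile_size)

    @property
    def n_cols(self) -> int:
        return -(-self.slide_width // self.tile_size)


@dataclass
class SegmentationResult:
    """Stitched class map plus per-class areas and the cellularity percent.

    ``class_map`` holds HEMATO (0) / ADIPOSE (1) / EXCLUDED (2) at slide
    geometry; excluded pixels (background or padding) count toward neither
    area.
    """

    class_map: np.ndarray
    area_hemato: int
    area_adipose: int
    cellularity: float

    def to_json(self, path: str | Path, slide_id: str = "") -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "slide_id": slide_id,
                    "area_hemato": self.area_hemato,
                    "area_adipose": self.area_adipose,
                    "cellularity": self.cellularity,
                },
                indent=2,
            )
        )
        return path


def compute_cellularity(area_hemato: float, area_adipose: float) -> float:
    """Hematopoietic share of the total tissue area, in percent.

    Scale-invariant: multiplying both areas by k > 0 leaves it unchanged.
    Raises if both areas are zero (no tissue -> cellularity undefined).
    """
    if area_hemato < 0 or area_adipose < 0:
        raise ValueError(
            f"areas must be >= 0, got ({area_hemato}, {area_adipose})"
        )
    total = area_hemato + area_adipose
    if total == 0:
        raise ValueError("cellularity undefined: both tissue areas are zero")
    return 100.0 * area_hemato / total


def tile_slide(
    slide_image: np.ndarray, tile_size: int = 256
) -> tuple[TileGrid, np.ndarray, np.ndarray]:
    """Cut a slide into padded tiles.

    Returns ``(grid, tiles, validity)`` where ``tiles`` is
    (n_tiles, tile_size, tile_size, 3) with edge tiles padded white, and
    ``validity`` is the matching boolean array flagging real (non-padded)
    pixels. Tiles are ordered row-major by grid position.
    """
    slide_image = np.asarray(slide_image)
    if slide_image.ndim != 3 or slide_image.shape[2] != 3 or slide_image.size == 0:
        raise ValueError(
            f"slide_image: expected non-empty (H, W, 3), got {slide_image.shape}"
        )
    h, w = slide_image.shape[:2]
    grid = TileGrid(tile_size=tile_size, slide_height=h, slide_width=w)
    tiles, valids = [], []
    for r0 in range(0, h, tile_size):
        for c0 in range(0, w, tile_size):
            grid.origins.append((r0, c0))
            tile = np.full((tile_size, tile_size, 3), 255, dtype=slide_image.dtype)
            valid = np.zeros((tile_size, tile_size), dtype=bool)
            rh = min(tile_size, h - r0)
            cw = min(tile_size, w - c0)
            tile[:rh, :cw] = slide_image[r0 : r0 + rh, c0 : c0 + cw]
            valid[:rh, :cw] = True
            tiles.append(tile)
            valids.append(valid)
    return grid, np.stack(tiles), np.stack(valids)


def stitch_tiles(grid: TileGrid, tile_maps: np.ndarray) -> np.ndarray:
    """Reassemble per-tile maps to slide geometry, discarding padding."""
    out = np.empty((grid.slide_height, grid.slide_width), dtype=tile_maps.dtype)
    ts = grid.tile_size
    for (r0, c0), tmap in zip(grid.origins, tile_maps):
        rh = min(ts, grid.slide_height - r0)
        cw = min(ts, grid.slide_width - c0)
        out[r0 : r0 + rh, c0 : c0 + cw] = tmap[:rh, :cw]
    return out


def segment_slide(
    model: SegmentationModel,
    slide_image: np.ndarray,
    background_threshold: int = DEFAULT_BACKGROUND_THRESHOLD,
    batch_size: int = 16,
) -> SegmentationResult:
    """Tile, segment, and stitch a slide; compute areas and cellularity.

    Pixels whose channels all exceed ``background_threshold`` in the input
    are marked EXCLUDED (slide glass is neither tissue), as are padded edge
    pixels. Stitched areas equal the sums over tiles by construction.
    """
    slide_image = np.asarray(slide_image)
    ts = model.config.input_size
    grid, tiles, valids = tile_slide(slide_image, tile_size=ts)
    tile_maps = np.empty(tiles.shape[:3], dtype=np.uint8)
    for start in range(0, len(tiles), batch_size):
        probs = model.predict_proba(tiles[start : start + batch_size])
        tile_maps[start : start + batch_size] = probs.argmax(axis=-1).astype(np.uint8)
    class_map = stitch_tiles(grid, tile_maps)
    background = (slide_image >= background_threshold + 1).all(axis=2)
    class_map[background] = EXCLUDED
    area_h = int((class_map == HEMATO).sum())
    area_a = int((class_map == ADIPOSE).sum())
    return SegmentationResult(
        class_map=class_map,
        area_hemato=area_h,
        area_adipose=area_a,
        cellularity=compute_cellularity(area_h, area_a),
    )


def render_overlay(
    slide_image: np.ndarray, class_map: np.ndarray, alpha: float = 0.4
) -> np.ndarray:
    """Alpha-blend the segmentation over the slide.

    Green marks hematopoietic tissue, blue adipose; EXCLUDED pixels are
    left untouched. ``alpha = 0`` returns the original image.
    """
    slide_image = np.asarray(slide_image)
    class_map = np.asarray(class_map)
    if slide_image.shape[:2] != class_map.shape:
        raise ValueError(
            f"shape mismatch: slide {slide_image.shape[:2]} vs map {class_map.shape}"
        )
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha: must be in [0,1], got {alpha}")
    out = slide_image.astype(np.float64).copy()
    for code, colour in _OVERLAY_COLOURS.items():
        sel = class_map == code
        out[sel] = (1 - alpha) * out[sel] + alpha * colour
    return np.clip(out, 0, 255).astype(np.uint8)


def segment_to_files(
    model: SegmentationModel,
    slide_image: np.ndarray,
    outdir: str | Path,
    slide_id: str,
    alpha: float = 0.4,
    background_threshold: int = DEFAULT_BACKGROUND_THRESHOLD,
) -> SegmentationResult:
    """Segment a slide and write class map, overlay, and JSON report."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = segment_slide(model, slide_image, background_threshold)
    palette = np.array(
        [[0, 255, 0], [0, 0, 255], [255, 255, 255]], dtype=np.uint8
    )  # green / blue / excluded-white
    Image.fromarray(palette[result.class_map]).save(outdir / f"{slide_id}_map.png")
    overlay = render_overlay(slide_image, result.class_map, alpha)
    Image.fromarray(overlay).save(outdir / f"{slide_id}_overlay.png")
    result.to_json(outdir / f"{slide_id}_report.json", slide_id=slide_id)
    return result
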