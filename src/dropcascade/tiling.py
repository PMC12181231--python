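"""Cut large frames into a bounded tile grid and merge predictions back.

Very large microscopy frames are cut into at most a 3x3 grid (at most two
cuts per axis — more cuts amplify seam artifacts when the per-tile
segmentations are merged) and each tile is resized to the network input
size.  Tiles partition the frame exactly: no overlap, no gap, no blending
at reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

MAX_CUTS_PER_AXIS = 2


@dataclass(frozen=True)
class Tile:
    image: np.ndarray
    rect: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass(frozen=True)
class TileSet:
    source_shape: tuple[int, int]
    grid: tuple[int, int]  # (row cuts, col cuts)
    target_hw: tuple[int, int]
    tiles: list[Tile]


def _axis_bounds(extent: int, n_cuts: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, extent, n_cuts + 2).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_cuts + 1)]


def _resize_to(img: np.ndarray, hw: tuple[int, int], is_mask: bool) -> np.ndarray:
    if img.shape[:2] == tuple(hw):
        return img.copy()
    order = 0 if is_mask else 1  # nearest for masks, bilinear for images
    out = resize(img, hw, order=order, preserve_range=True, anti_aliasing=False)
    return out.astype(img.dtype)


def cut_and_resize(
    image: np.ndarray,
    grid: tuple[int, int],
    target_hw: tuple[int, int],
    is_mask: bool = False,
    divisor: int | None = None,
) -> TileSet:
    """Partition ``image`` by ``grid`` cuts per axis and resize each tile.

    ``grid = (row_cuts, col_cuts)`` with at most two cuts per axis, yielding
    ``(row_cuts+1) * (col_cuts+1)`` tiles whose source rectangles tile the
    frame exactly.  ``divisor``, when given, enforces that ``target_hw`` is
    divisible by the downstream network's pooling factor.
    """
    rc, cc = grid
    if not (0 <= rc <= MAX_CUTS_PER_AXIS and 0 <= cc <= MAX_CUTS_PER_AXIS):
        raise ValueError(
            f"grid {grid} exceeds the maximum of {MAX_CUTS_PER_AXIS} cuts per axis"
        )
    th, tw = target_hw
    if th <= 0 or tw <= 0:
        raise ValueError("target size must be positive")
    if divisor is not None and (th % divisor or tw % divisor):
        raise ValueError(
            f"target size {target_hw} must be divisible by {divisor} "
            "(network pooling factor 2^(n_encoders-1))"
        )
    h, w = image.shape[:2]
    tiles = []
    for r0, r1 in _axis_bounds(h, rc):
        for c0, c1 in _axis_bounds(w, cc):
            sub = image[r0:r1, c0:c1]
            tiles.append(Tile(_resize_to(sub, (th, tw), is_mask), (r0, c0, r1, c1)))
    return TileSet(source_shape=(h, w), grid=(rc, cc), target_hw=(th, tw),
                   tiles=tiles)


def reconstruct(
    tileset: TileSet,
    predicted_tiles: list[np.ndarray] | None = None,
    is_mask: bool = True,
) -> np.ndarray:
    """Resize tiles back to their source rectangles and reassemble the frame.

    ``predicted_tiles`` must align one-to-one with ``tileset.tiles``; when
    omitted the tileset's own tiles are used (round trip).  Nearest-neighbor
    resizing is used for masks so labels stay binary.
    """
    imgs = (
        [t.image for t in tileset.tiles] if predicted_tiles is None else predicted_tiles
    )
    if len(imgs) != len(tileset.tiles):
        missing = abs(len(imgs) - len(tileset.tiles))
        raise ValueError(
            f"expected {len(tileset.tiles)} predicted tiles, got {len(imgs)} "
            f"({missing} rectangles unmatched: "
            f"{[t.rect for t in tileset.tiles[len(imgs):]] or 'extras'})"
        )
    h, w = tileset.source_shape
    sample = imgs[0]
    shape = (h, w) if sample.ndim == 2 else (h, w, sample.shape[2])
    out = np.zeros(shape, dtype=sample.dtype)
    covered = np.zeros((h, w), dtype=bool)
    for tile, img in zip(tileset.tiles, imgs):
        r0, c0, r1, c1 = tile.rect
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"tile rectangle {tile.rect} lies outside the frame")
        out[r0:r1, c0:c1] = _resize_to(img, (r1 - r0, c1 - c0), is_mask)
        covered[r0:r1, c0:c1] = True
    if not covered.all():
        raise ValueError("tile rectangles do not cover the full frame")
    return out
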