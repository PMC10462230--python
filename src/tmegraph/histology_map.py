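"""Spatial assembly of tile predictions into a histology classification map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classes import EMPTY_CELL, default_palette

TILE_SIZE = 224


@dataclass
class HistologyMap:
    """Grid of class ids; cell (r, c) covers pixels [c*224, (c+1)*224) x
    [r*224, (r+1)*224). Unoccupied cells hold the EMPTY_CELL sentinel."""

    slide_id: str
    grid: np.ndarray  # int array, EMPTY_CELL where no tile

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def occupied(self) -> np.ndarray:
        return self.grid != EMPTY_CELL


def assemble_map(
    labels: dict[str, int],
    manifest: dict[str, tuple[int, int]],
    slide_id: str = "slide",
) -> HistologyMap:
    """Place per-tile class labels on the stride-224 grid.

    ``labels`` maps tile_id -> class id; ``manifest`` maps tile_id ->
    (x, y) tile origin in pixels. Two tiles on one cell is an error.
    """
    cells: dict[tuple[int, int], tuple[str, int]] = {}
    for tile_id, cls in labels.items():
        x, y = manifest[tile_id]
        if x % TILE_SIZE or y % TILE_SIZE:
            raise ValueError(f"tile {tile_id}: origin ({x}, {y}) off the stride-{TILE_SIZE} grid")
        rc = (y // TILE_SIZE, x // TILE_SIZE)
        if rc in cells:
            raise ValueError(
                f"grid cell {rc} claimed by tiles {cells[rc][0]!r} and {tile_id!r}"
            )
        cells[rc] = (tile_id, cls)
    if not cells:
        return HistologyMap(slide_id, np.full((0, 0), EMPTY_CELL, dtype=int))
    n_rows = max(r for r, _ in cells) + 1
    n_cols = max(c for _, c in cells) + 1
    grid = np.full((n_rows, n_cols), EMPTY_CELL, dtype=int)
    for (r, c), (_, cls) in cells.items():
        grid[r, c] = cls
    return HistologyMap(slide_id, grid)


def render_map(
    hmap: HistologyMap,
    palette: dict[int, tuple[int, int, int]] | None = None,
    cell_px: int = 1,
    empty_color: tuple[int, int, int] = (255, 255, 255),
) -> np.ndarray:
    """Render the class grid as an RGB raster, one ``cell_px`` block per cell.

    The palette must cover every class present; empty cells render white.
    """
    if palette is None:
        palette = default_palette()
    present = set(np.unique(hmap.grid)) - {EMPTY_CELL}
    missing = present - set(palette)
    if missing:
        raise KeyError(f"palette missing classes {sorted(missing)}")
    n_rows, n_cols = hmap.grid.shape
    img = np.empty((n_rows, n_cols, 3), dtype=np.uint8)
    img[:] = empty_color
    for cls in present:
        img[hmap.grid == cls] = palette[cls]
    if cell_px > 1:
        img = np.kron(img, np.ones((cell_px, cell_px, 1), dtype=np.uint8))
    return img


def decode_map(img: np.ndarray, palette: dict[int, tuple[int, int, int]] | None = None,
               cell_px: int = 1) -> np.ndarray:
    """Invert :func:`render_map` (the palette is a bijection)."""
    if palette is None:
        palette = default_palette()
    inverse = {tuple(v): k for k, v in palette.items()}
    cells = img[::cell_px, ::cell_px]
    grid = np.full(cells.shape[:2], EMPTY_CELL, dtype=int)
    for r in range(cells.shape[0]):
        for c in range(cells.shape[1]):
            grid[r, c] = inverse.get(tuple(int(v) for v in cells[r, c]), EMPTY_CELL)
    return grid
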