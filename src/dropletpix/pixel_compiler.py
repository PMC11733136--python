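"""Image-to-droplet compiler: palette quantization, tiling, and sort order.

An input raster is block-averaged down to the target grid, each cell is
snapped to the nearest of the 8 droplet colors, the grid is decomposed into
non-overlapping 5x5 tiles, and each tile is compiled into the droplet sort
order that reproduces it on a serpentine anchor array.  The array behaves
as a displacement FIFO: every newly sorted droplet enters at the first
anchor and knocks all current occupants one anchor further in, so the tile
must be emitted farthest-anchor first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .classification import PALETTE

__all__ = [
    "PixelGrid",
    "AnchorArray",
    "serpentine_map",
    "quantize",
    "decompose",
    "compile_instructions",
    "replay_instructions",
    "stitch",
    "render",
]

TILE_SIZE = 5  # anchors per row/column of one pixel-array device

#: palette display colors as a (8, 3) uint8 array for vectorized lookups
_PALETTE_RGB = np.array([c.display_rgb for c in PALETTE], dtype=float)

EMPTY = -1  # cell value for an unoccupied anchor (simulator output only)


@dataclass(frozen=True)
class PixelGrid:
    """A width x height grid of palette indices.

    ``cells`` is (height, width), row-major from the top-left.  Values are
    palette indices 0-7; ``allow_empty`` additionally admits -1 for
    unoccupied anchors in simulator output.
    """

    cells: np.ndarray
    allow_empty: bool = False

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int64)
        if cells.ndim != 2 or cells.size == 0:
            raise ValueError("cells must be a non-empty 2-D array")
        lo = EMPTY if self.allow_empty else 0
        if cells.min() < lo or cells.max() > 7:
            raise ValueError(
                f"cell values must be palette indices in [{lo}, 7]"
            )
        cells.setflags(write=False)
        object.__setattr__(self, "cells", cells)

    @property
    def height(self) -> int:
        return self.cells.shape[0]

    @property
    def width(self) -> int:
        return self.cells.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PixelGrid):
            return NotImplemented
        return self.cells.shape == other.cells.shape and bool(
            np.array_equal(self.cells, other.cells)
        )

    def __hash__(self) -> int:
        return hash((self.cells.shape, self.cells.tobytes()))


def serpentine_map(height: int = TILE_SIZE, width: int = TILE_SIZE) -> list[tuple[int, int]]:
    """Anchor positions 1..N in boustrophedon order from the entrance.

    Entrance at the top-left; row 0 runs left-to-right, row 1 right-to-left,
    and so on.  Returns the (row, col) of positions 1..N, so
    ``serpentine_map(h, w)[i]`` is the cell of anchor position ``i + 1``.
    """
    out = []
    for row in range(height):
        cols = range(width) if row % 2 == 0 else range(width - 1, -1, -1)
        out.extend((row, col) for col in cols)
    return out


class AnchorArrayOverflowError(RuntimeError):
    pass


@dataclass
class AnchorArray:
    """Serpentine anchor chain with displacement-FIFO occupancy.

    ``occupancy[i]`` is the droplet at anchor position ``i + 1`` counted
    from the entrance; occupancy is always contiguous from the entrance.
    """

    n_anchors: int = TILE_SIZE * TILE_SIZE
    height: int = TILE_SIZE
    width: int = TILE_SIZE
    occupancy: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.height * self.width != self.n_anchors:
            raise ValueError("n_anchors must equal height * width")
        if len(self.occupancy) > self.n_anchors:
            raise ValueError("occupancy exceeds array capacity")

    @property
    def is_full(self) -> bool:
        return len(self.occupancy) >= self.n_anchors

    def push(self, droplet) -> None:
        """Insert a droplet at the entrance, knocking occupants one anchor in."""
        if self.is_full:
            raise AnchorArrayOverflowError(
                f"anchor array is full ({self.n_anchors} anchors)"
            )
        self.occupancy.insert(0, droplet)

    def to_grid(self, key=lambda droplet: droplet) -> PixelGrid:
        """Current occupancy as a grid; unoccupied anchors are EMPTY."""
        cells = np.full((self.height, self.width), EMPTY, dtype=np.int64)
        for pos0, (row, col) in enumerate(serpentine_map(self.height, self.width)):
            if pos0 < len(self.occupancy):
                cells[row, col] = key(self.occupancy[pos0])
        return PixelGrid(cells, allow_empty=True)


# --------------------------------------------------------------------------
# Quantization
# --------------------------------------------------------------------------

def _block_average(image: np.ndarray, grid_h: int, grid_w: int) -> np.ndarray:
    h, w = image.shape[:2]
    if h % grid_h == 0 and w % grid_w == 0:
        bh, bw = h // grid_h, w // grid_w
        return image.reshape(grid_h, bh, grid_w, bw, 3).mean(axis=(1, 3))
    # non-integer block sizes: Pillow BOX filter does area averaging
    im = Image.fromarray(np.clip(image, 0, 255).astype(np.uint8), mode="RGB")
    return np.asarray(
        im.resize((grid_w, grid_h), resample=Image.Resampling.BOX), dtype=float
    )


def quantize(image: np.ndarray, grid_height: int, grid_width: int) -> PixelGrid:
    """Dropletize a raster: block-average to the grid, snap to the palette.

    Each averaged cell takes the palette color nearest in Euclidean RGB
    distance; exact ties go to the lowest palette index.  Quantizing the
    rendering of a grid returns the grid (idempotence).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("image must be HxWx3 (RGB)")
    image = image[:, :, :3]
    if image.shape[0] < grid_height or image.shape[1] < grid_width:
        raise ValueError(
            f"image {image.shape[:2]} smaller than target grid "
            f"({grid_height}, {grid_width})"
        )
    averaged = _block_average(image, grid_height, grid_width)
    # (H, W, 8) distances to all palette colors; argmin takes the lowest
    # index among ties by construction
    d2 = ((averaged[:, :, None, :] - _PALETTE_RGB[None, None, :, :]) ** 2).sum(axis=-1)
    return PixelGrid(np.argmin(d2, axis=-1))


# --------------------------------------------------------------------------
# Tiling
# --------------------------------------------------------------------------

def decompose(
    grid: PixelGrid, tile_size: int = TILE_SIZE
) -> tuple[list[PixelGrid], list[PixelGrid], list[int]]:
    """Split a grid into non-overlapping row-major tiles and deduplicate.

    Returns ``(tiles, unique_patterns, tile_to_pattern)`` where
    ``tile_to_pattern[i]`` indexes ``unique_patterns`` for tile ``i``.
    Grid dimensions must divide evenly — no padding is invented.
    """
    if grid.height % tile_size or grid.width % tile_size:
        raise ValueError(
            f"grid {grid.height}x{grid.width} not divisible into "
            f"{tile_size}x{tile_size} tiles"
        )
    tiles: list[PixelGrid] = []
    unique: list[PixelGrid] = []
    seen: dict[bytes, int] = {}
    mapping: list[int] = []
    for r in range(0, grid.height, tile_size):
        for c in range(0, grid.width, tile_size):
            tile = PixelGrid(grid.cells[r : r + tile_size, c : c + tile_size])
            tiles.append(tile)
            key = tile.cells.tobytes()
            if key not in seen:
                seen[key] = len(unique)
                unique.append(tile)
            mapping.append(seen[key])
    return tiles, unique, mapping


# --------------------------------------------------------------------------
# Instruction compilation
# --------------------------------------------------------------------------

def compile_instructions(tile: PixelGrid, array: AnchorArray | None = None) -> list[int]:
    """Sort order (palette indices) that reproduces ``tile`` on the array.

    The FIFO pushes each new droplet to position 1 and shifts everyone else
    inward, so after N pushes the first-sorted droplet sits at the farthest
    anchor.  The instruction list therefore reads the tile along the
    serpentine from the farthest anchor back to the entrance; the last
    instruction emitted is the entrance-anchor color.
    """
    array = array or AnchorArray(
        n_anchors=tile.height * tile.width, height=tile.height, width=tile.width
    )
    if (array.height, array.width) != (tile.height, tile.width):
        raise ValueError(
            f"tile {tile.height}x{tile.width} does not match array "
            f"{array.height}x{array.width}"
        )
    serp = serpentine_map(tile.height, tile.width)
    return [int(tile.cells[serp[pos0]]) for pos0 in range(len(serp) - 1, -1, -1)]


def replay_instructions(
    instructions: list[int], height: int = TILE_SIZE, width: int = TILE_SIZE
) -> PixelGrid:
    """Push an instruction list through a fresh array and read off the grid."""
    array = AnchorArray(n_anchors=height * width, height=height, width=width)
    for color in instructions:
        array.push(int(color))
    grid = array.to_grid()
    if len(instructions) == height * width:
        return PixelGrid(grid.cells)  # fully occupied: drop the EMPTY allowance
    return grid


# --------------------------------------------------------------------------
# Mosaic stitching and rendering
# --------------------------------------------------------------------------

def stitch(
    tiles: list[PixelGrid],
    positions: list[tuple[int, int]],
    tile_size: int = TILE_SIZE,
) -> PixelGrid:
    """Reassemble tiles into a mosaic; inverse of :func:`decompose`.

    ``positions`` are (tile_row, tile_col) indices.  Every position in the
    bounding mosaic must be covered exactly once.
    """
    if len(tiles) != len(positions):
        raise ValueError("tiles and positions must have equal length")
    if not tiles:
        raise ValueError("cannot stitch zero tiles")
    seen = set()
    for pos in positions:
        if pos in seen:
            raise ValueError(f"duplicate tile position {pos}")
        seen.add(pos)
    n_rows = max(r for r, _ in positions) + 1
    n_cols = max(c for _, c in positions) + 1
    missing = [
        (r, c) for r in range(n_rows) for c in range(n_cols) if (r, c) not in seen
    ]
    if missing:
        raise ValueError(f"missing tile positions: {missing}")
    cells = np.empty((n_rows * tile_size, n_cols * tile_size), dtype=np.int64)
    for tile, (r, c) in zip(tiles, positions):
        if tile.cells.shape != (tile_size, tile_size):
            raise ValueError(
                f"tile at {(r, c)} has shape {tile.cells.shape}, "
                f"expected ({tile_size}, {tile_size})"
            )
        cells[
            r * tile_size : (r + 1) * tile_size,
            c * tile_size : (c + 1) * tile_size,
        ] = tile.cells
    return PixelGrid(cells)


def render(grid: PixelGrid, scale: int = 1) -> np.ndarray:
    """Paint a grid as an RGB raster, ``scale`` pixels per droplet.

    Empty anchors render as mid-gray so they stand out against both the
    all-low and all-high palette members.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    rgb = np.empty((grid.height, grid.width, 3), dtype=np.uint8)
    for idx, color in enumerate(PALETTE):
        rgb[grid.cells == idx] = color.display_rgb
    rgb[grid.cells == EMPTY] = (128, 128, 128)
    return np.repeat(np.repeat(rgb, scale, axis=0), scale, axis=1)
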