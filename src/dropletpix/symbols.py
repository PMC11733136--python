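"""Built-in 5x5 black/white alphanumeric glyphs for pixel-array runs.

Each glyph is five strings of ``.`` (background / all-low droplet) and
``#`` (foreground / all-high droplet).  ``O`` and ``0`` share one shape at
this resolution, so the 36 glyphs yield 35 unique patterns.
"""

from __future__ import annotations

import numpy as np

from .pixel_compiler import PixelGrid

__all__ = ["GLYPHS", "glyph_grid", "symbol_library"]

# foreground/background palette indices: all-high (white) on all-low (black)
FOREGROUND = 7
BACKGROUND = 0

GLYPHS: dict[str, tuple[str, str, str, str, str]] = {
    "A": (".###.", "#...#", "#####", "#...#", "#...#"),
    "B": ("####.", "#...#", "####.", "#...#", "####."),
    "C": (".####", "#....", "#....", "#....", ".####"),
    "D": ("####.", "#...#", "#...#", "#...#", "####."),
    "E": ("#####", "#....", "####.", "#....", "#####"),
    "F": ("#####", "#....", "####.", "#....", "#...."),
    "G": (".####", "#....", "#..##", "#...#", ".###."),
    "H": ("#...#", "#...#", "#####", "#...#", "#...#"),
    "I": ("#####", "..#..", "..#..", "..#..", "#####"),
    "J": ("..###", "...#.", "...#.", "#..#.", ".##.."),
    "K": ("#...#", "#..#.", "###..", "#..#.", "#...#"),
    "L": ("#....", "#....", "#....", "#....", "#####"),
    "M": ("#...#", "##.##", "#.#.#", "#...#", "#...#"),
    "N": ("#...#", "##..#", "#.#.#", "#..##", "#...#"),
    "O": (".###.", "#...#", "#...#", "#...#", ".###."),
    "P": ("####.", "#...#", "####.", "#....", "#...."),
    "Q": (".###.", "#...#", "#.#.#", "#..#.", ".##.#"),
    "R": ("####.", "#...#", "####.", "#..#.", "#...#"),
    "S": (".####", "#....", ".###.", "....#", "####."),
    "T": ("#####", "..#..", "..#..", "..#..", "..#.."),
    "U": ("#...#", "#...#", "#...#", "#...#", ".###."),
    "V": ("#...#", "#...#", "#...#", ".#.#.", "..#.."),
    "W": ("#...#", "#...#", "#.#.#", "##.##", "#...#"),
    "X": ("#...#", ".#.#.", "..#..", ".#.#.", "#...#"),
    "Y": ("#...#", ".#.#.", "..#..", "..#..", "..#.."),
    "Z": ("#####", "...#.", "..#..", ".#...", "#####"),
    "0": (".###.", "#...#", "#...#", "#...#", ".###."),
    "1": ("..#..", ".##..", "..#..", "..#..", "#####"),
    "2": (".###.", "#...#", "..##.", ".#...", "#####"),
    "3": ("####.", "....#", ".###.", "....#", "####."),
    "4": ("#...#", "#...#", "#####", "....#", "....#"),
    "5": ("#####", "#....", "####.", "....#", "####."),
    "6": (".###.", "#....", "####.", "#...#", ".###."),
    "7": ("#####", "....#", "...#.", "..#..", ".#..."),
    "8": (".###.", "#...#", ".###.", "#...#", ".###."),
    "9": (".###.", "#...#", ".####", "....#", ".###."),
}


def glyph_grid(symbol: str) -> PixelGrid:
    """The 5x5 two-color grid for one glyph."""
    try:
        rows = GLYPHS[symbol.upper()]
    except KeyError:
        raise ValueError(f"no glyph for {symbol!r}") from None
    cells = np.array(
        [[FOREGROUND if ch == "#" else BACKGROUND for ch in row] for row in rows],
        dtype=np.int64,
    )
    return PixelGrid(cells)


def symbol_library() -> dict[str, PixelGrid]:
    """All unique glyph patterns keyed by symbol (duplicates collapsed).

    ``O`` and ``0`` collapse to one entry, giving 35 unique patterns.
    """
    out: dict[str, PixelGrid] = {}
    seen: set[bytes] = set()
    for symbol in GLYPHS:
        grid = glyph_grid(symbol)
        key = grid.cells.tobytes()
        if key not in seen:
            seen.add(key)
            out[symbol] = grid
    return out
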