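"""Packaged synthetic 5x7 monospaced bitmap font for the geometry panel.

The original vendor font cannot be redistributed; panels rendered by the
phantom simulator and layouts calibrated for real systems both carry their
glyph bitmaps in the :class:`~xrnav.panel.PanelLayout`, so this set only has
to be self-consistent (every glyph distinct), not vendor-accurate.
"""

from __future__ import annotations

import numpy as np

GLYPH_W = 5
GLYPH_H = 7

_RAW = {
    "0": """
.###.
#...#
#..##
#.#.#
##..#
#...#
.###.
""",
    "1": """
..#..
.##..
..#..
..#..
..#..
..#..
.###.
""",
    "2": """
.###.
#...#
....#
...#.
..#..
.#...
#####
""",
    "3": """
.###.
#...#
....#
..##.
....#
#...#
.###.
""",
    "4": """
...#.
..##.
.#.#.
#..#.
#####
...#.
...#.
""",
    "5": """
#####
#....
####.
....#
....#
#...#
.###.
""",
    "6": """
..##.
.#...
#....
####.
#...#
#...#
.###.
""",
    "7": """
#####
....#
...#.
..#..
..#..
..#..
..#..
""",
    "8": """
.###.
#...#
#...#
.###.
#...#
#...#
.###.
""",
    "9": """
.###.
#...#
#...#
.####
....#
...#.
.##..
""",
    "+": """
.....
..#..
..#..
#####
..#..
..#..
.....
""",
    "-": """
.....
.....
.....
#####
.....
.....
.....
""",
    " ": """
.....
.....
.....
.....
.....
.....
.....
""",
    "L": """
#....
#....
#....
#....
#....
#....
#####
""",
    "R": """
####.
#...#
#...#
####.
#.#..
#..#.
#...#
""",
    "A": """
.###.
#...#
#...#
#####
#...#
#...#
#...#
""",
    "O": """
.###.
#...#
#...#
#...#
#...#
#...#
.###.
""",
    "C": """
.###.
#...#
#....
#....
#....
#...#
.###.
""",
    "U": """
#...#
#...#
#...#
#...#
#...#
#...#
.###.
""",
    "D": """
####.
#...#
#...#
#...#
#...#
#...#
####.
""",
    "N": """
#...#
##..#
#.#.#
#..##
#...#
#...#
#...#
""",
}

#: Small ring used as the degree sign / page discriminator mark.
DEGREE_MARK_RAW = """
.##.
#..#
#..#
.##.
"""


def _parse(raw: str) -> np.ndarray:
    rows = [line for line in raw.strip("\n").split("\n")]
    return np.array([[c == "#" for c in row] for row in rows], dtype=bool)


def glyph_bitmaps() -> dict[str, np.ndarray]:
    """All glyphs (digits, signs, blank, letters) as boolean (7, 5) arrays."""
    return {ch: _parse(raw) for ch, raw in _RAW.items()}


def value_glyphs() -> dict[str, np.ndarray]:
    """The 13 value-cell characters: digits 0-9, '+', '-', blank."""
    bm = glyph_bitmaps()
    return {ch: bm[ch] for ch in "0123456789+- "}


def letter_glyphs() -> dict[str, np.ndarray]:
    bm = glyph_bitmaps()
    return {ch: bm[ch] for ch in "LRAOCUDN"}


def degree_mark() -> np.ndarray:
    return _parse(DEGREE_MARK_RAW)
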