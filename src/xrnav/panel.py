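"""Character recognition of the live-video geometry panel.

The live video output of the X-ray system (1280 x 1024 px) carries the
fluoroscopic image in a fixed 1000 x 1000 px region plus a configuration
panel showing the current imaging geometry: primary/secondary angulation in
whole degrees (with LAO/RAO and CRAN/CAUD orientation words), longitudinal/
lateral/vertical table position, SID and FD in whole centimeters.

Recognition is template matching of binarized single-character cells: each
analyzed cell is thresholded at the midpoint between its own minimum and
maximum intensity (removing any luminance/contrast dependence), then
assigned the glyph (digits 0-9, '+', '-', blank) minimizing the Frobenius
norm of the element-wise difference matrix.  A few discriminator probes
resolve what the glyph cells cannot: the degree-sign mark distinguishes the
angulation page from the table page (the vendor panel shows the two at the
same positions), and letter cells of the orientation words carry the
angulation signs.

The panel shows either the angulation page (angles + SID, degree mark
visible) or the table page (table + FD, no mark); 13 character cells are
analyzed per frame.  A full :class:`GeometryReading` is assembled from one
frame of each page via :meth:`GeometryReading.merge`.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _font
from .geometry import CArmConfig, CArmGeometry

__all__ = [
    "GeometryReading",
    "PanelLayout",
    "binarize_cell",
    "classify_glyph",
    "default_layout",
    "display_reading",
    "read_geometry",
    "render_panel",
    "round_half_away",
    "to_carm_geometry",
]

PAGES = ("angulation", "table")

#: Fields shown on each page.
PAGE_FIELDS = {
    "angulation": ("primary_deg", "secondary_deg", "sid_cm"),
    "table": ("table_long_cm", "table_lat_cm", "table_vert_cm", "fd_cm"),
}
ALL_FIELDS = PAGE_FIELDS["angulation"] + PAGE_FIELDS["table"]


def round_half_away(x: float) -> int:
    """Display rounding: nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _b64_bitmap(a: np.ndarray) -> dict:
    return {
        "shape": list(a.shape),
        "data": base64.b64encode(np.packbits(a.astype(np.uint8))).decode(),
    }


def _bitmap_b64(d: dict) -> np.ndarray:
    shape = tuple(d["shape"])
    bits = np.unpackbits(np.frombuffer(base64.b64decode(d["data"]), dtype=np.uint8))
    return bits[: shape[0] * shape[1]].reshape(shape).astype(bool)


@dataclass(frozen=True)
class PanelLayout:
    """Geometry-panel geometry: cell positions, glyphs and discriminators.

    ``cells`` are the (u, v) upper-left corners of the 13 analyzed
    single-character matrices, all sharing ``cell size = glyph size``.
    ``field_cells`` maps each displayed field to its cell indices per page
    (values are rendered right-aligned, blank-padded).  Discriminators:
    ``degree_mark_pos`` locates the degree-sign probe (mark present =
    angulation page) and ``sign_cells`` the orientation-word letter cells
    with their candidate letters and signs.
    """

    cells: tuple[tuple[int, int], ...]
    glyphs: dict[str, np.ndarray]
    letter_glyphs: dict[str, np.ndarray]
    field_cells: dict[str, dict[str, tuple[int, ...]]]
    degree_mark_pos: tuple[int, int]
    degree_mark: np.ndarray
    sign_cells: dict[str, tuple[tuple[int, int], dict[str, int]]]
    word_positions: dict[str, tuple[tuple[int, int], ...]]
    frame_size: tuple[int, int] = (1280, 1024)
    image_rect: tuple[int, int, int, int] = (280, 12, 1000, 1000)
    panel_rect: tuple[int, int, int, int] = (0, 0, 280, 1024)
    max_mismatch: int = 0

    def __post_init__(self):
        if len(self.cells) != 13:
            raise ValueError(f"layout must define exactly 13 cells, got {len(self.cells)}")
        shapes = {g.shape for g in self.glyphs.values()}
        if len(shapes) != 1:
            raise ValueError("all glyph bitmaps must share one cell size")
        fw, fh = self.frame_size
        gh, gw = self.cell_shape
        for u, v in self.cells:
            if not (0 <= u and u + gw <= fw and 0 <= v and v + gh <= fh):
                raise ValueError("cell rectangle outside the frame")
        for rect in (self.image_rect, self.panel_rect):
            x, y, w, h = rect
            if not (0 <= x and x + w <= fw and 0 <= y and y + h <= fh):
                raise ValueError("layout rectangle outside the frame")

    @property
    def cell_shape(self) -> tuple[int, int]:
        return next(iter(self.glyphs.values())).shape

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "cells": [list(c) for c in self.cells],
            "glyphs": {ch: _b64_bitmap(g) for ch, g in self.glyphs.items()},
            "letter_glyphs": {ch: _b64_bitmap(g) for ch, g in self.letter_glyphs.items()},
            "field_cells": {p: {f: list(v) for f, v in m.items()} for p, m in self.field_cells.items()},
            "degree_mark_pos": list(self.degree_mark_pos),
            "degree_mark": _b64_bitmap(self.degree_mark),
            "sign_cells": {
                k: [list(pos), cand] for k, (pos, cand) in self.sign_cells.items()
            },
            "word_positions": {k: [list(p) for p in v] for k, v in self.word_positions.items()},
            "frame_size": list(self.frame_size),
            "image_rect": list(self.image_rect),
            "panel_rect": list(self.panel_rect),
            "max_mismatch": self.max_mismatch,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PanelLayout":
        d = json.loads(text)
        return cls(
            cells=tuple(tuple(c) for c in d["cells"]),
            glyphs={ch: _bitmap_b64(g) for ch, g in d["glyphs"].items()},
            letter_glyphs={ch: _bitmap_b64(g) for ch, g in d["letter_glyphs"].items()},
            field_cells={p: {f: tuple(v) for f, v in m.items()} for p, m in d["field_cells"].items()},
            degree_mark_pos=tuple(d["degree_mark_pos"]),
            degree_mark=_bitmap_b64(d["degree_mark"]),
            sign_cells={k: (tuple(v[0]), {c: int(s) for c, s in v[1].items()}) for k, v in d["sign_cells"].items()},
            word_positions={k: tuple(tuple(p) for p in v) for k, v in d["word_positions"].items()},
            frame_size=tuple(d["frame_size"]),
            image_rect=tuple(d["image_rect"]),
            panel_rect=tuple(d["panel_rect"]),
            max_mismatch=int(d["max_mismatch"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "PanelLayout":
        return cls.from_json(Path(path).read_text())


def default_layout() -> PanelLayout:
    """The shipped synthetic layout with the packaged 5x7 font.

    Thirteen analyzed cells: nine in three groups of three shared between the
    table page (signed long/lat/vert) and the angulation page (primary and
    secondary magnitudes, third group blank), plus four distance cells shared
    between SID (angulation page) and FD (table page).
    """
    gw, gh = _font.GLYPH_W, _font.GLYPH_H
    step = gw + 2
    cells = []
    for gx in (30, 60, 90):  # three shared groups at y=340
        cells += [(gx + i * step, 340) for i in range(3)]
    cells += [(30 + i * step, 370) for i in range(4)]  # distance cells
    word_u = 30
    return PanelLayout(
        cells=tuple(cells),
        glyphs=_font.value_glyphs(),
        letter_glyphs=_font.letter_glyphs(),
        field_cells={
            "angulation": {
                "primary_deg": (0, 1, 2),
                "secondary_deg": (3, 4, 5),
                "sid_cm": (9, 10, 11, 12),
            },
            "table": {
                "table_long_cm": (0, 1, 2),
                "table_lat_cm": (3, 4, 5),
                "table_vert_cm": (6, 7, 8),
                "fd_cm": (9, 10, 11, 12),
            },
        },
        degree_mark_pos=(120, 340),
        degree_mark=_font.degree_mark(),
        sign_cells={
            # first letter distinguishes LAO/RAO; second letter CRAN/CAUD
            "primary": ((word_u, 300), {"L": +1, "R": -1}),
            "secondary": ((word_u + step, 315), {"R": +1, "A": -1}),
        },
        word_positions={
            "primary": tuple((word_u + i * step, 300) for i in range(3)),
            "secondary": tuple((word_u + i * step, 315) for i in range(4)),
        },
    )


# ---------------------------------------------------------------------------
# recognition primitives
# ---------------------------------------------------------------------------

def binarize_cell(cell) -> np.ndarray:
    """Threshold a cell at the midpoint between its min and max intensity.

    A constant cell (nothing rendered) maps to all zeros, i.e. blank.  The
    midpoint rule makes the result exactly invariant to positive affine
    intensity changes of the frame.
    """
    cell = np.asarray(cell, dtype=float)
    if cell.size == 0:
        raise ValueError("empty cell")
    lo, hi = cell.min(), cell.max()
    if lo == hi:
        return np.zeros(cell.shape, dtype=bool)
    return cell > (lo + hi) / 2.0


def classify_glyph(
    binary_cell: np.ndarray, glyphs: dict[str, np.ndarray]
) -> tuple[str, float, bool]:
    """Nearest-template classification of a binarized cell.

    Returns ``(character, distance, ambiguous)`` where distance is the
    Frobenius norm of the difference matrix to the winning glyph and
    ``ambiguous`` flags a second glyph within 1e-9 of the winner (the winner
    is then the lowest codepoint).
    """
    cell = np.asarray(binary_cell, dtype=float)
    dists = []
    for ch in sorted(glyphs):
        g = glyphs[ch]
        if g.shape != cell.shape:
            raise ValueError(f"cell shape {cell.shape} != glyph shape {g.shape}")
        dists.append((float(np.linalg.norm(cell - g.astype(float))), ch))
    dists.sort()
    best_d, best_ch = dists[0]
    ambiguous = len(dists) > 1 and dists[1][0] - best_d <= 1e-9
    return best_ch, best_d, ambiguous


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryReading:
    """Integer-precision geometry parameters recognized from a panel.

    Fields not shown on the recognized page (or unreadable) are ``None``
    with ``valid[field] = False``.
    """

    primary_deg: int | None = None
    secondary_deg: int | None = None
    table_long_cm: int | None = None
    table_lat_cm: int | None = None
    table_vert_cm: int | None = None
    sid_cm: int | None = None
    fd_cm: int | None = None
    valid: dict[str, bool] = field(default_factory=dict)
    page: str | None = None

    @property
    def complete(self) -> bool:
        return all(self.valid.get(f, False) for f in ALL_FIELDS)

    def merge(self, other: "GeometryReading") -> "GeometryReading":
        """Combine readings of complementary pages (self takes precedence)."""
        kwargs = {}
        valid = {}
        for f in ALL_FIELDS:
            if self.valid.get(f, False):
                kwargs[f] = getattr(self, f)
                valid[f] = True
            elif other.valid.get(f, False):
                kwargs[f] = getattr(other, f)
                valid[f] = True
            else:
                kwargs[f] = None
                valid[f] = False
        return GeometryReading(valid=valid, page="merged", **kwargs)

    def to_json(self) -> str:
        d = {f: getattr(self, f) for f in ALL_FIELDS}
        d["valid"] = {f: bool(self.valid.get(f, False)) for f in ALL_FIELDS}
        d["page"] = self.page
        return json.dumps(d, indent=2)


def _cell_at(frame: np.ndarray, pos: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    u, v = pos
    h, w = shape
    return frame[v : v + h, u : u + w]


def _parse_cells(chars: list[str], signed: bool) -> int | None:
    """Right-aligned glyph cells -> integer; None when malformed."""
    s = "".join(chars)
    stripped = s.lstrip(" ")
    if not stripped or " " in stripped:
        return None
    sign = 1
    if stripped[0] in "+-":
        if not signed:
            return None
        sign = 1 if stripped[0] == "+" else -1
        stripped = stripped[1:]
    if not stripped or not stripped.isdigit():
        return None
    return sign * int(stripped)


def read_geometry(frame, layout: PanelLayout) -> GeometryReading:
    """Recognize the geometry parameters shown in a live-video frame.

    Reads all 13 analyzed cells, resolves the degree-sign page discriminator
    and the orientation-word letter cells, and assembles signed integers.
    Unreadable fields are returned with ``valid=False`` rather than raising.
    """
    frame = np.asarray(frame, dtype=float)
    fw, fh = layout.frame_size
    if frame.shape != (fh, fw):
        raise ValueError(f"frame shape {frame.shape} does not match layout {(fh, fw)}")

    # page discriminator: degree mark rendered only on the angulation page
    mark = binarize_cell(_cell_at(frame, layout.degree_mark_pos, layout.degree_mark.shape))
    page = "angulation" if mark.any() else "table"

    cell_shape = layout.cell_shape
    chars: list[str | None] = []
    for pos in layout.cells:
        ch, dist, ambiguous = classify_glyph(
            binarize_cell(_cell_at(frame, pos, cell_shape)), layout.glyphs
        )
        ok = dist <= np.sqrt(layout.max_mismatch) + 1e-12 and not ambiguous
        chars.append(ch if ok else None)

    values: dict[str, int | None] = {f: None for f in ALL_FIELDS}
    valid: dict[str, bool] = {f: False for f in ALL_FIELDS}
    signed_fields = {"table_long_cm", "table_lat_cm", "table_vert_cm"}
    for fieldname, idxs in layout.field_cells[page].items():
        cell_chars = [chars[i] for i in idxs]
        if any(c is None for c in cell_chars):
            continue
        val = _parse_cells(cell_chars, signed=fieldname in signed_fields)
        if val is None:
            continue
        values[fieldname] = val
        valid[fieldname] = True

    if page == "angulation":
        for which, fieldname in (("primary", "primary_deg"), ("secondary", "secondary_deg")):
            if not valid[fieldname]:
                continue
            pos, candidates = layout.sign_cells[which]
            letter_set = {c: layout.letter_glyphs[c] for c in candidates}
            ch, dist, ambiguous = classify_glyph(
                binarize_cell(_cell_at(frame, pos, cell_shape)), letter_set
            )
            if dist > np.sqrt(layout.max_mismatch) + 1e-12 or ambiguous:
                values[fieldname] = None
                valid[fieldname] = False
            else:
                values[fieldname] = candidates[ch] * values[fieldname]

    return GeometryReading(valid=valid, page=page, **values)


# ---------------------------------------------------------------------------
# rendering (used by the phantom simulator's frame composer)
# ---------------------------------------------------------------------------

def display_reading(
    geom: CArmGeometry,
    table_axis_map: dict[str, str] | None = None,
) -> GeometryReading:
    """The rounded, display-precision reading a panel would show for ``geom``."""
    amap = table_axis_map or {"long": "z", "lat": "x", "vert": "y"}
    axis_idx = {"x": 0, "y": 1, "z": 2}
    table_cm = {
        k: round_half_away(geom.table[axis_idx[amap[k]]] / 10.0) for k in ("long", "lat", "vert")
    }
    return GeometryReading(
        primary_deg=round_half_away(geom.primary_angle),
        secondary_deg=round_half_away(geom.secondary_angle),
        table_long_cm=table_cm["long"],
        table_lat_cm=table_cm["lat"],
        table_vert_cm=table_cm["vert"],
        sid_cm=round_half_away(geom.sid / 10.0),
        fd_cm=round_half_away(geom.fd / 10.0),
        valid={f: True for f in ALL_FIELDS},
        page="truth",
    )


def _draw_bitmap(canvas: np.ndarray, bitmap: np.ndarray, pos: tuple[int, int], fg: float) -> None:
    u, v = pos
    h, w = bitmap.shape
    region = canvas[v : v + h, u : u + w]
    region[bitmap] = fg


def render_panel(
    canvas: np.ndarray,
    layout: PanelLayout,
    reading: GeometryReading,
    page: str,
    fg: float = 200.0,
) -> None:
    """Draw one page of the geometry panel into a frame canvas, in place."""
    if page not in PAGES:
        raise ValueError(f"unknown page {page!r}")
    cell_shape = layout.cell_shape
    signed_fields = {"table_long_cm", "table_lat_cm", "table_vert_cm"}

    def put(text: str, idxs: tuple[int, ...]) -> None:
        if len(text) > len(idxs):
            raise ValueError(f"value {text!r} does not fit in {len(idxs)} cells")
        text = text.rjust(len(idxs))
        for ch, i in zip(text, idxs):
            _draw_bitmap(canvas, layout.glyphs[ch], layout.cells[i], fg)

    for fieldname, idxs in layout.field_cells[page].items():
        val = getattr(reading, fieldname)
        if val is None:
            raise ValueError(f"reading lacks {fieldname} needed for page {page!r}")
        if fieldname in signed_fields:
            put(("-" if val < 0 else "") + str(abs(val)), idxs)
        else:
            put(str(abs(val)), idxs)

    if page == "angulation":
        _draw_bitmap(canvas, layout.degree_mark, layout.degree_mark_pos, fg)
        primary_word = "LAO" if reading.primary_deg >= 0 else "RAO"
        secondary_word = "CRAN" if reading.secondary_deg >= 0 else "CAUD"
        for word, key in ((primary_word, "primary"), (secondary_word, "secondary")):
            for ch, pos in zip(word, layout.word_positions[key]):
                _draw_bitmap(canvas, layout.letter_glyphs[ch], pos, fg)


# ---------------------------------------------------------------------------
# conversion to imaging geometry
# ---------------------------------------------------------------------------

def to_carm_geometry(reading: GeometryReading, config: CArmConfig) -> CArmGeometry:
    """Turn a complete panel reading into an exact-unit imaging geometry.

    Centimeters become millimeters and the configured per-FD pixel-spacing
    calibration (from original DICOM metadata) overrides the FD-derived
    pitch, avoiding the FD display-rounding error.  SPD and image size come
    from the per-C-arm configuration.
    """
    if not reading.complete:
        missing = [f for f in ALL_FIELDS if not reading.valid.get(f, False)]
        raise ValueError(f"reading has invalid fields: {', '.join(missing)}")
    if config.fd_pixel_pitch_mm:
        if reading.fd_cm not in config.fd_pixel_pitch_mm:
            raise ValueError(
                f"FD {reading.fd_cm} cm not in configured pixel-spacing table "
                f"{sorted(config.fd_pixel_pitch_mm)}"
            )
        pitch = config.fd_pixel_pitch_mm[reading.fd_cm]
    else:
        pitch = None
    axis_idx = {"x": 0, "y": 1, "z": 2}
    table = [0.0, 0.0, 0.0]
    for k, fieldname in (
        ("long", "table_long_cm"),
        ("lat", "table_lat_cm"),
        ("vert", "table_vert_cm"),
    ):
        table[axis_idx[config.table_axis_map[k]]] = 10.0 * getattr(reading, fieldname)
    return CArmGeometry(
        primary_angle=float(reading.primary_deg),
        secondary_angle=float(reading.secondary_deg),
        table=tuple(table),
        sid=10.0 * reading.sid_cm,
        fd=10.0 * reading.fd_cm,
        spd=config.spd_mm,
        n_u=config.n_u,
        n_v=config.n_v,
        label=config.label,
        pixel_pitch=pitch,
    )
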