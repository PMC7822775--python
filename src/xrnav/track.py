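"""Template-matching tracking and motion compensation.

2D tracking uses zero-normalized cross-correlation (NCC): both the template
and every candidate image region are mean-subtracted before correlation, so
matching is exactly invariant to positive affine intensity changes of the
frame.  2D motion compensation shifts a registered overlay by the tracked
displacement; 3D tracking matches a catheter-tip template independently in
both biplane views, triangulates the tip, and subtracts the 3D motion vector
of a reference structure tracked the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .geometry import ProjectionMatrix
from .reconstruct import triangulate

__all__ = [
    "Rect",
    "TemplatePatch",
    "Track3D",
    "TrackState",
    "compensate_overlay_2d",
    "match_template",
    "ncc_map",
    "track_tip_3d",
]


@dataclass(frozen=True)
class Rect:
    """Pixel rectangle: origin (u0, v0) and size (width, height)."""

    u0: int
    v0: int
    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle size must be positive")

    @property
    def u1(self) -> int:
        return self.u0 + self.width

    @property
    def v1(self) -> int:
        return self.v0 + self.height

    def inside(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return self.u0 >= 0 and self.v0 >= 0 and self.u1 <= w and self.v1 <= h

    @classmethod
    def centered(cls, center_uv, width: int, height: int, clip_shape=None) -> "Rect":
        u = int(round(center_uv[0])) - width // 2
        v = int(round(center_uv[1])) - height // 2
        if clip_shape is not None:
            h, w = clip_shape
            u = min(max(u, 0), max(w - width, 0))
            v = min(max(v, 0), max(h - height, 0))
        return cls(u, v, width, height)


@dataclass(frozen=True)
class TemplatePatch:
    """Grayscale template with odd side lengths, anchored at its center pixel."""

    pixels: np.ndarray
    frame_id: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("template must be a 2D raster")
        if px.shape[0] % 2 == 0 or px.shape[1] % 2 == 0:
            raise ValueError("template side lengths must be odd")
        object.__setattr__(self, "pixels", px)

    @property
    def anchor(self) -> tuple[int, int]:
        """(du, dv) of the center pixel within the patch."""
        return (self.pixels.shape[1] // 2, self.pixels.shape[0] // 2)

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.pixels) == 0)

    @classmethod
    def cut(cls, frame, center_uv, half: int, frame_id: int = 0) -> "TemplatePatch":
        """Cut a (2*half+1)^2 patch centered on an integer pixel position."""
        u, v = int(round(center_uv[0])), int(round(center_uv[1]))
        return cls(np.asarray(frame, dtype=float)[v - half : v + half + 1, u - half : u + half + 1], frame_id)


@dataclass(frozen=True)
class TrackState:
    """Result of one template match."""

    position_px: tuple[float, float]
    score: float
    search_window: Rect
    motion_vector_px: tuple[float, float] = (0.0, 0.0)
    valid: bool = True


def ncc_map(region: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation of a template over all placements.

    Returns an array of shape (H-h+1, W-w+1); placements where the image
    region is constant (NCC undefined) come back as NaN.
    """
    region = np.asarray(region, dtype=float)
    tpl = np.asarray(template, dtype=float)
    h, w = tpl.shape
    tz = tpl - tpl.mean()
    t_norm = np.sqrt((tz**2).sum())
    if t_norm == 0:
        raise ValueError("template has zero variance; NCC undefined")
    windows = np.lib.stride_tricks.sliding_window_view(region, (h, w))
    n = h * w
    s1 = windows.sum(axis=(-2, -1))
    s2 = (windows**2).sum(axis=(-2, -1))
    var = s2 - s1**2 / n
    var = np.maximum(var, 0.0)
    cross = np.tensordot(windows, tz, axes=([-2, -1], [0, 1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cross / (t_norm * np.sqrt(var))
    out[var <= 1e-12 * np.maximum(s2, 1.0)] = np.nan
    return out


def _parabolic_offset(y_m1: float, y_0: float, y_p1: float) -> float:
    denom = y_m1 - 2 * y_0 + y_p1
    if denom >= 0:  # not a maximum
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -0.5, 0.5))


def match_template(
    frame,
    template: TemplatePatch,
    window: Rect,
    subpixel: bool = False,
) -> TrackState:
    """Find the NCC-optimal placement of a template inside a search window.

    The returned position is the image position of the template's center
    pixel.  Ties are broken towards the smallest (v, u) lexicographically.
    A constant template or an all-constant window region yields an invalid
    state (``valid=False``) rather than an arbitrary position.
    """
    frame = np.asarray(frame, dtype=float)
    if not window.inside(frame.shape):
        raise ValueError("search window must lie inside the frame")
    h, w = template.pixels.shape
    if window.height < h or window.width < w:
        raise ValueError("search window must be at least the template size")
    region = frame[window.v0 : window.v1, window.u0 : window.u1]
    if template.is_constant:
        return TrackState((np.nan, np.nan), np.nan, window, valid=False)
    scores = ncc_map(region, template.pixels)
    if np.all(np.isnan(scores)):
        return TrackState((np.nan, np.nan), np.nan, window, valid=False)
    flat = np.where(np.isnan(scores), -np.inf, scores)
    iv, iu = np.unravel_index(np.argmax(flat), flat.shape)
    score = float(scores[iv, iu])
    du, dv = template.anchor
    u = window.u0 + iu + du
    v = window.v0 + iv + dv
    if subpixel:
        if 0 < iu < flat.shape[1] - 1 and np.isfinite(flat[iv, iu - 1]) and np.isfinite(flat[iv, iu + 1]):
            u += _parabolic_offset(flat[iv, iu - 1], flat[iv, iu], flat[iv, iu + 1])
        if 0 < iv < flat.shape[0] - 1 and np.isfinite(flat[iv - 1, iu]) and np.isfinite(flat[iv + 1, iu]):
            v += _parabolic_offset(flat[iv - 1, iu], flat[iv, iu], flat[iv + 1, iu])
    return TrackState((float(u), float(v)), score, window)


def compensate_overlay_2d(ref: TrackState, cur: TrackState, overlay_origin_px):
    """Shift a 2D overlay origin by the tracked displacement cur - ref."""
    if not (ref.valid and cur.valid):
        raise ValueError("cannot compensate from invalid track states")
    du = cur.position_px[0] - ref.position_px[0]
    dv = cur.position_px[1] - ref.position_px[1]
    return (overlay_origin_px[0] + du, overlay_origin_px[1] + dv)


@dataclass(frozen=True)
class Track3D:
    """Biplane 3D track sample for one frame pair."""

    frame_id: int
    tip_mm: np.ndarray
    compensated_tip_mm: np.ndarray
    motion_mm: np.ndarray
    state_a: TrackState
    state_b: TrackState
    gap_mm: float


def _window_for(last_uv, template: TemplatePatch, frame_shape, scale: float) -> Rect:
    h, w = template.pixels.shape
    return Rect.centered(
        last_uv,
        max(w, int(round(w * scale))),
        max(h, int(round(h * scale))),
        clip_shape=frame_shape,
    )


def track_tip_3d(
    frames_a,
    frames_b,
    tip_template_a: TemplatePatch,
    tip_template_b: TemplatePatch,
    pm_a: ProjectionMatrix,
    pm_b: ProjectionMatrix,
    tip_init_a,
    tip_init_b,
    ref_template_a: TemplatePatch | None = None,
    ref_template_b: TemplatePatch | None = None,
    ref_init_a=None,
    ref_init_b=None,
    window_scale: float = 3.0,
    subpixel: bool = False,
) -> list[Track3D]:
    """Motion-compensated biplane 3D catheter-tip tracking.

    The tip template is matched in each view of every frame pair (search
    window re-centered on the last position), the matches are triangulated
    into a 3D tip, and — when reference templates are given — the 3D motion
    vector of the reference structure relative to its first-frame position is
    subtracted.  Templates stay fixed over the sequence; re-initialization is
    the caller's responsibility.
    """
    if len(frames_a) != len(frames_b):
        raise ValueError("frame sequences must be paired (equal length)")
    compensate = ref_template_a is not None
    if compensate and (ref_template_b is None or ref_init_a is None or ref_init_b is None):
        raise ValueError("reference tracking needs templates and init positions in both views")

    tracks: list[Track3D] = []
    tip_last = [tuple(tip_init_a), tuple(tip_init_b)]
    ref_last = [tuple(ref_init_a), tuple(ref_init_b)] if compensate else None
    ref0_mm: np.ndarray | None = None
    for i, (fa, fb) in enumerate(zip(frames_a, frames_b)):
        fa = np.asarray(fa, dtype=float)
        fb = np.asarray(fb, dtype=float)
        sa = match_template(fa, tip_template_a, _window_for(tip_last[0], tip_template_a, fa.shape, window_scale), subpixel)
        sb = match_template(fb, tip_template_b, _window_for(tip_last[1], tip_template_b, fb.shape, window_scale), subpixel)
        if not (sa.valid and sb.valid):
            raise ValueError(f"invalid tip match at frame {i}")
        rec = triangulate(pm_a, sa.position_px, pm_b, sb.position_px)
        tip_last = [sa.position_px, sb.position_px]

        motion = np.zeros(3)
        if compensate:
            ra = match_template(fa, ref_template_a, _window_for(ref_last[0], ref_template_a, fa.shape, window_scale), subpixel)
            rb = match_template(fb, ref_template_b, _window_for(ref_last[1], ref_template_b, fb.shape, window_scale), subpixel)
            if not (ra.valid and rb.valid):
                raise ValueError(f"invalid reference match at frame {i}")
            ref_rec = triangulate(pm_a, ra.position_px, pm_b, rb.position_px)
            ref_last = [ra.position_px, rb.position_px]
            if ref0_mm is None:
                ref0_mm = ref_rec.p
            motion = ref_rec.p - ref0_mm

        tracks.append(
            Track3D(
                frame_id=i,
                tip_mm=rec.p,
                compensated_tip_mm=rec.p - motion,
                motion_mm=motion,
                state_a=sa,
                state_b=sb,
                gap_mm=rec.gap_mm,
            )
        )
    return tracks


def tracks_to_csv(tracks: list[Track3D], path) -> None:
    """Export a 3D track as CSV (frame_id, per-view u/v/score, tip, compensated tip)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["frame_id", "u_a", "v_a", "score_a", "u_b", "v_b", "score_b",
             "x", "y", "z", "x_comp", "y_comp", "z_comp", "gap_mm"]
        )
        for t in tracks:
            w.writerow(
                [t.frame_id, *t.state_a.position_px, t.state_a.score,
                 *t.state_b.position_px, t.state_b.score,
                 *t.tip_mm, *t.compensated_tip_mm, t.gap_mm]
            )
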