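"""Biplane 3D reconstruction from two projective views.

A point marked in two views (frontal/lateral of a biplane acquisition, or two
monoplane runs at different angulations) is reconstructed by intersecting the
two back-projected viewing rays.  With noisy 2D input the rays do not meet;
the midpoint of their common perpendicular is returned, which for two lines
is exactly the least-squares point minimizing the sum of squared distances to
both rays.  The closest-approach distance (the epipolar residual) is reported
as a consistency diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .geometry import ProjectionMatrix, Ray, backproject_ray, project

__all__ = ["ReconstructedPoint", "closest_point_two_rays", "epipolar_line", "triangulate"]

#: Default minimum angular separation between viewing rays, degrees.
MIN_SEPARATION_DEG = 15.0

#: Ray gap above which a reconstruction is flagged as suspicious, mm.
GAP_WARN_MM = 1.0


@dataclass(frozen=True)
class ReconstructedPoint:
    """3D reconstruction result.

    Attributes
    ----------
    p : (3,) ndarray
        Reconstructed world point, mm.
    gap_mm : float
        Closest-approach distance between the two viewing rays (0 for exact
        correspondences).
    gap_warning : bool
        True when ``gap_mm`` exceeds the warning threshold — the 2D pair is
        probably not a true correspondence.
    """

    p: np.ndarray
    gap_mm: float
    gap_warning: bool = False


def closest_point_two_rays(ray_a: Ray, ray_b: Ray) -> tuple[np.ndarray, float]:
    """Midpoint of the common perpendicular of two rays and their gap."""
    da, db = ray_a.direction, ray_b.direction
    w0 = ray_a.origin - ray_b.origin
    c = float(da @ db)
    denom = 1.0 - c * c
    if denom <= 1e-12:
        raise DegenerateGeometryError("viewing rays are (near-)parallel")
    sa = (c * (w0 @ db) - (w0 @ da)) / denom
    sb = ((w0 @ db) - c * (w0 @ da)) / denom
    pa = ray_a.point_at(sa)
    pb = ray_b.point_at(sb)
    return 0.5 * (pa + pb), float(np.linalg.norm(pa - pb))


def triangulate(
    pm_a: ProjectionMatrix,
    q_a,
    pm_b: ProjectionMatrix,
    q_b,
    min_separation_deg: float = MIN_SEPARATION_DEG,
    gap_warn_mm: float = GAP_WARN_MM,
) -> ReconstructedPoint:
    """Reconstruct a 3D world point from one 2D point per view.

    Raises :class:`DegenerateGeometryError` when the two viewing rays are
    separated by less than ``min_separation_deg`` (ill-conditioned
    intersection); a large ray gap only sets ``gap_warning``.
    """
    ray_a = backproject_ray(pm_a, q_a)
    ray_b = backproject_ray(pm_b, q_b)
    cos_sep = float(np.clip(ray_a.direction @ ray_b.direction, -1.0, 1.0))
    sep = np.degrees(np.arccos(abs(cos_sep)))
    if sep < min_separation_deg:
        raise DegenerateGeometryError(
            f"view separation {sep:.2f} deg below minimum {min_separation_deg} deg"
        )
    p, gap = closest_point_two_rays(ray_a, ray_b)
    return ReconstructedPoint(p=p, gap_mm=gap, gap_warning=gap > gap_warn_mm)


def _solve_s_at(pm_b: ProjectionMatrix, ray: Ray, q: np.ndarray) -> float:
    """Ray parameter s whose projection into view b lands on image point q.

    The projection of ray(s) is ((a1 + b1 s)/(a3 + b3 s), (a2 + b2 s)/(a3 + b3 s));
    either coordinate gives a linear equation in s — use the better-conditioned
    one.
    """
    m = pm_b.m
    a_h = m[:, :3] @ ray.origin + m[:, 3]
    b_h = m[:, :3] @ ray.direction
    best = None
    for i in (0, 1):
        num = q[i] * a_h[2] - a_h[i]
        den = b_h[i] - q[i] * b_h[2]
        if abs(den) > 1e-12:
            s = num / den
            if best is None or abs(den) > best[1]:
                best = (s, abs(den))
    if best is None:
        return np.inf
    return best[0]


def epipolar_line(
    pm_a: ProjectionMatrix,
    q_a,
    pm_b: ProjectionMatrix,
    n_clip_tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the viewing ray of ``q_a`` into view b, clipped to its image.

    Returns the two endpoints (u, v) of the visible epipolar segment, clipped
    to the image rectangle [0, n_u-1] x [0, n_v-1] of view b.  Only the part
    of the ray in front of both sources is considered.  Raises
    :class:`DegenerateGeometryError` when no part of the ray is visible in
    view b (e.g. entirely behind its source).
    """
    ray = backproject_ray(pm_a, q_a)
    m = pm_b.m
    a_h = m[:, :3] @ ray.origin + m[:, 3]
    b_h = m[:, :3] @ ray.direction

    # depth in view b along the ray: w(s) = a_h[2] + b_h[2] s > 0, and s > 0
    s_lo, s_hi = 0.0, np.inf
    if abs(b_h[2]) < 1e-15:
        if a_h[2] <= 0:
            raise DegenerateGeometryError("ray entirely behind the view-b source")
    else:
        s_cross = -a_h[2] / b_h[2]
        if b_h[2] > 0:
            s_lo = max(s_lo, s_cross)
        else:
            s_hi = min(s_hi, s_cross)
    if s_hi <= s_lo:
        raise DegenerateGeometryError("ray entirely behind the view-b source")

    def uv(s):
        h = a_h + s * b_h
        with np.errstate(divide="ignore", invalid="ignore"):
            return h[:2] / h[2]

    # Homogeneous image line through two projections of the ray.
    l = np.cross(a_h, a_h + b_h)

    lo, hi = s_lo + 1e-9 * max(1.0, abs(s_lo)), s_hi
    candidates: list[np.ndarray] = []

    # Border intersections of the line, kept when they correspond to a valid s.
    u_max, v_max = pm_b.n_u - 1.0, pm_b.n_v - 1.0
    borders = [
        np.array([1.0, 0.0, 0.0]),          # u = 0
        np.array([1.0, 0.0, -u_max]),       # u = u_max
        np.array([0.0, 1.0, 0.0]),          # v = 0
        np.array([0.0, 1.0, -v_max]),       # v = v_max
    ]
    for b_line in borders:
        pt = np.cross(l, b_line)
        if abs(pt[2]) < 1e-12:
            continue
        q = pt[:2] / pt[2]
        if -n_clip_tol - 1e-6 <= q[0] <= u_max + 1e-6 and -1e-6 <= q[1] <= v_max + 1e-6:
            s = _solve_s_at(pm_b, ray, q)
            if lo <= s <= hi:
                candidates.append(q)

    # Finite-interval endpoints and the vanishing point, when inside the image.
    interior: list[np.ndarray] = []
    if np.isfinite(lo):
        interior.append(uv(lo))
    if np.isfinite(hi):
        interior.append(uv(hi))
    else:
        if abs(b_h[2]) > 1e-15:
            interior.append(b_h[:2] / b_h[2])  # s -> inf limit
    for q in interior:
        if np.all(np.isfinite(q)) and -1e-6 <= q[0] <= u_max + 1e-6 and -1e-6 <= q[1] <= v_max + 1e-6:
            candidates.append(q)

    if len(candidates) < 2:
        raise DegenerateGeometryError("epipolar line does not cross the view-b image")
    pts = np.array(candidates)
    d = pts - pts.mean(axis=0)
    axis = d[np.argmax(np.linalg.norm(d, axis=1))]
    t = pts @ axis
    p0, p1 = pts[np.argmin(t)], pts[np.argmax(t)]
    clip = lambda q: np.clip(q, [0.0, 0.0], [u_max, v_max])
    return clip(p0), clip(p1)
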