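"""Synthetic sphere-phantom acquisition simulator.

Emulates the accuracy-evaluation phantom — glass spheres of 6, 10 and 20 mm
diameter and a glass tube embedded in gel — imaged on a biplane X-ray system:
analytic forward projections (per-pixel exponential attenuation along the
exact chord length through each sphere/cylinder), composed live-video frames
with a rendered geometry panel, marker sets with controlled localization
noise, and motion sequences with ground-truth 2D/3D tracks.  Every renderer
is deterministic for a fixed seed; all ground truth is returned alongside the
synthetic data so that geometry, reconstruction, registration, tracking and
panel recognition can each be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CArmGeometry, build_projection, project
from .panel import (
    GeometryReading,
    PanelLayout,
    default_layout,
    display_reading,
    render_panel,
)
from .register import PointSet3D, RigidTransform

__all__ = [
    "Cylinder",
    "LinearMotion",
    "MarkerSample",
    "MotionSequence",
    "PhantomScene",
    "SinusoidMotion",
    "Sphere",
    "SyntheticFrame",
    "default_scene",
    "make_motion_sequence",
    "render_frame",
    "render_frame_pair",
    "render_projection",
    "sample_marker_sets",
    "sphere_mesh",
]


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    diameter: float
    attenuation: float = 0.05  # per mm

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("sphere diameter must be positive")


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder between two axis endpoints (the glass tube)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    attenuation: float = 0.02

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth phantom plus acquisition settings."""

    spheres: tuple[Sphere, ...] = ()
    tube: Cylinder | None = None
    marker_sigma_mm: float = 0.0
    layout: PanelLayout | None = None

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.spheres], dtype=float).reshape(-1, 3)

    def displaced(self, displacements: np.ndarray) -> "PhantomScene":
        spheres = tuple(
            replace(s, center=tuple(np.asarray(s.center) + d))
            for s, d in zip(self.spheres, displacements)
        )
        return replace(self, spheres=spheres)


def default_scene() -> PhantomScene:
    """Six glass spheres (two each of 6/10/20 mm) and one tube in ~5 cm of gel."""
    spheres = (
        Sphere((0.0, 0.0, 0.0), 20.0),
        Sphere((25.0, 5.0, 12.0), 10.0),
        Sphere((-20.0, 16.0, -14.0), 6.0),
        Sphere((16.0, -22.0, -10.0), 10.0),
        Sphere((-14.0, -15.0, 17.0), 6.0),
        Sphere((8.0, 21.0, 22.0), 20.0),
    )
    tube = Cylinder((-30.0, -30.0, -30.0), (-30.0, -30.0, 30.0), 2.5)
    return PhantomScene(spheres=spheres, tube=tube, layout=default_layout())


# ---------------------------------------------------------------------------
# analytic forward projection
# ---------------------------------------------------------------------------

def _sphere_chords(origin, dirs, sphere: Sphere) -> np.ndarray:
    oc = np.asarray(sphere.center, dtype=float) - origin
    proj = dirs @ oc
    d2 = oc @ oc - proj**2
    r2 = (sphere.diameter / 2.0) ** 2
    chord = 2.0 * np.sqrt(np.maximum(r2 - d2, 0.0))
    return np.where(proj > 0, chord, 0.0)


def _cylinder_chords(origin, dirs, cyl: Cylinder) -> np.ndarray:
    p0 = np.asarray(cyl.p0, dtype=float)
    p1 = np.asarray(cyl.p1, dtype=float)
    w = p1 - p0
    length = np.linalg.norm(w)
    w = w / length
    oo = origin - p0
    d_perp = dirs - np.outer(dirs @ w, w)
    o_perp = oo - (oo @ w) * w
    a = np.sum(d_perp**2, axis=1)
    b = 2.0 * d_perp @ o_perp
    c = o_perp @ o_perp - cyl.radius**2
    disc = b**2 - 4 * a * c
    hit = (disc > 0) & (a > 1e-15)
    chord = np.zeros(len(dirs))
    if not hit.any():
        return chord
    sq = np.sqrt(np.maximum(disc[hit], 0.0))
    t1 = (-b[hit] - sq) / (2 * a[hit])
    t2 = (-b[hit] + sq) / (2 * a[hit])
    # clip to the finite axial extent: s(t) = (oo + t d) . w in [0, length]
    s0 = oo @ w
    sw = dirs[hit] @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(np.abs(sw) > 1e-15, (0.0 - s0) / sw, -np.inf)
        tb = np.where(np.abs(sw) > 1e-15, (length - s0) / sw, np.inf)
    lo_ax = np.minimum(ta, tb)
    hi_ax = np.maximum(ta, tb)
    inside_ax = np.abs(sw) > 1e-15
    lo_ax = np.where(inside_ax, lo_ax, np.where((s0 >= 0) & (s0 <= length), -np.inf, np.inf))
    hi_ax = np.where(inside_ax, hi_ax, np.where((s0 >= 0) & (s0 <= length), np.inf, -np.inf))
    lo = np.maximum(np.maximum(t1, lo_ax), 0.0)
    hi = np.minimum(t2, hi_ax)
    chord[hit] = np.maximum(hi - lo, 0.0)
    return chord


def render_projection(
    scene: PhantomScene,
    geom: CArmGeometry,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    background: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic X-ray-like projection of the phantom.

    Per-pixel intensity is ``background * exp(-sum mu_i * L_i)`` with L_i the
    exact ray chord length through each sphere/cylinder, plus optional
    Gaussian noise (clipped to [0, 1]).  Returns ``(image, centers_px)``
    where ``image`` has shape (n_v, n_u) and ``centers_px`` the exact
    projected sphere centers as ground truth.
    """
    pm = build_projection(geom)
    u = np.arange(geom.n_u, dtype=float)
    v = np.arange(geom.n_v, dtype=float)
    uu, vv = np.meshgrid(u, v)
    d_cam = np.stack(
        [
            (uu.ravel() - pm.k[0, 2]) / pm.k[0, 0],
            (vv.ravel() - pm.k[1, 2]) / pm.k[1, 1],
            np.ones(uu.size),
        ],
        axis=1,
    )
    dirs = d_cam @ pm.a  # == (a.T @ d_cam.T).T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    path = np.zeros(uu.size)
    for s in scene.spheres:
        path += s.attenuation * _sphere_chords(pm.source_mm, dirs, s)
    if scene.tube is not None:
        path += scene.tube.attenuation * _cylinder_chords(pm.source_mm, dirs, scene.tube)
    img = background * np.exp(-path).reshape(geom.n_v, geom.n_u)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng()
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    centers = (
        project(pm, self_centers) if len(self_centers := scene.centers) else np.empty((0, 2))
    )
    return img, centers


# ---------------------------------------------------------------------------
# live-video frame composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFrame:
    """One synthetic live-video frame plus its ground truth."""

    raster: np.ndarray  # uint8, (frame_h, frame_w)
    geometry_truth: CArmGeometry
    reading_truth: GeometryReading
    page: str


def render_frame(
    scene: PhantomScene,
    geom: CArmGeometry,
    layout: PanelLayout | None = None,
    page: str = "angulation",
    gain: float = 1.0,
    offset: float = 0.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    render_image: bool = True,
) -> SyntheticFrame:
    """Compose a live-video frame: X-ray image region plus geometry panel.

    The panel shows ``geom`` rounded to display precision (whole cm/degrees,
    halves away from zero) on the requested page; ``gain``/``offset`` apply a
    per-frame affine intensity change emulating capture-chain variations.
    """
    layout = layout or scene.layout or default_layout()
    fw, fh = layout.frame_size
    canvas = np.full((fh, fw), 20.0)
    reading = display_reading(geom)
    render_panel(canvas, layout, reading, page)
    x, y, w, h = layout.image_rect
    if render_image and (scene.spheres or scene.tube is not None):
        img_geom = replace(geom, n_u=w, n_v=h)
        img, _ = render_projection(scene, img_geom, noise_sigma=noise_sigma, rng=rng)
        canvas[y : y + h, x : x + w] = 40.0 + 180.0 * img
    else:
        canvas[y : y + h, x : x + w] = 90.0
    out = np.clip(gain * canvas + offset, 0.0, 255.0).astype(np.uint8)
    return SyntheticFrame(raster=out, geometry_truth=geom, reading_truth=reading, page=page)


def render_frame_pair(
    scene: PhantomScene,
    geom: CArmGeometry,
    layout: PanelLayout | None = None,
    gain: float = 1.0,
    offset: float = 0.0,
    **kwargs,
) -> tuple[SyntheticFrame, SyntheticFrame]:
    """Both panel pages (angulation+SID, table+FD) for one geometry."""
    return (
        render_frame(scene, geom, layout, "angulation", gain, offset, **kwargs),
        render_frame(scene, geom, layout, "table", gain, offset, **kwargs),
    )


# ---------------------------------------------------------------------------
# marker sampling (registration ground truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSample:
    """Noisy marker observations plus exact ground truth."""

    mri: PointSet3D                 # tomographic-space markers (noisy)
    points_a: np.ndarray            # (n, 2) px, view a (noisy)
    points_b: np.ndarray            # (n, 2) px, view b (noisy)
    truth: PointSet3D               # exact XR-world marker positions
    tomo_transform: RigidTransform  # maps tomographic -> XR world


def sample_marker_sets(
    scene: PhantomScene,
    sigma_mri_mm: float,
    sigma_px: float,
    geom_a: CArmGeometry,
    geom_b: CArmGeometry,
    seed: int = 0,
    n_markers: int | None = None,
    tomo_transform: RigidTransform | None = None,
) -> MarkerSample:
    """Emulate manual marker identification in MRI and in two X-ray views.

    Tomographic-space markers are the sphere centers mapped through the
    inverse of ``tomo_transform`` plus isotropic Gaussian localization noise;
    ``sigma_mri_mm`` is the RMS *3D* displacement (per-axis sigma/sqrt(3)).
    2D points are the exact projections plus N(0, sigma_px) per coordinate.
    """
    n = len(scene.spheres) if n_markers is None else n_markers
    if not 3 <= n <= len(scene.spheres):
        raise ValueError(
            f"n_markers must be in [3, {len(scene.spheres)}], got {n}"
        )
    rng = np.random.default_rng(seed)
    transform = tomo_transform or RigidTransform.identity()
    centers = scene.centers[:n]
    labels = tuple(f"m{i}" for i in range(n))
    mri = transform.inverse().apply(centers) + rng.normal(
        0.0, sigma_mri_mm / np.sqrt(3.0), (n, 3)
    )
    pa = project(build_projection(geom_a), centers) + rng.normal(0.0, sigma_px, (n, 2))
    pb = project(build_projection(geom_b), centers) + rng.normal(0.0, sigma_px, (n, 2))
    return MarkerSample(
        mri=PointSet3D(labels, mri, space="tomographic"),
        points_a=pa,
        points_b=pb,
        truth=PointSet3D(labels, centers, space="xr-world"),
        tomo_transform=transform,
    )


# ---------------------------------------------------------------------------
# motion sequences (tracking ground truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinusoidMotion:
    """Sinusoidal 3D trajectory: amplitude_mm * sin(2 pi i / period + phase)."""

    amplitude_mm: tuple[float, float, float]
    period_frames: float
    phase: float = 0.0

    def displacement(self, i: int) -> np.ndarray:
        return np.asarray(self.amplitude_mm) * np.sin(
            2 * np.pi * i / self.period_frames + self.phase
        )


@dataclass(frozen=True)
class LinearMotion:
    velocity_mm_per_frame: tuple[float, float, float]

    def displacement(self, i: int) -> np.ndarray:
        return np.asarray(self.velocity_mm_per_frame) * i


@dataclass(frozen=True)
class MotionSequence:
    """Biplane frame sequence with exact 2D/3D ground-truth tracks."""

    frames_a: list[np.ndarray]
    frames_b: list[np.ndarray]
    truth_3d: np.ndarray    # (n_frames, n_structures, 3) mm
    truth_2d_a: np.ndarray  # (n_frames, n_structures, 2) px
    truth_2d_b: np.ndarray


def make_motion_sequence(
    scene: PhantomScene,
    geom_a: CArmGeometry,
    geom_b: CArmGeometry,
    motion: dict[int, SinusoidMotion | LinearMotion],
    n_frames: int,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> MotionSequence:
    """Render a biplane sequence with per-structure injected 3D motion.

    ``motion`` maps sphere indices to trajectories; unlisted spheres stay
    static.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pm_a = build_projection(geom_a)
    pm_b = build_projection(geom_b)
    frames_a, frames_b = [], []
    t3, t2a, t2b = [], [], []
    n_s = len(scene.spheres)
    for i in range(n_frames):
        disp = np.zeros((n_s, 3))
        for idx, traj in motion.items():
            disp[idx] = traj.displacement(i)
        frame_scene = scene.displaced(disp)
        img_a, _ = render_projection(frame_scene, geom_a, noise_sigma, rng)
        img_b, _ = render_projection(frame_scene, geom_b, noise_sigma, rng)
        frames_a.append(img_a)
        frames_b.append(img_b)
        centers = frame_scene.centers
        t3.append(centers)
        t2a.append(project(pm_a, centers))
        t2b.append(project(pm_b, centers))
    return MotionSequence(
        frames_a=frames_a,
        frames_b=frames_b,
        truth_3d=np.array(t3),
        truth_2d_a=np.array(t2a),
        truth_2d_b=np.array(t2b),
    )


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def sphere_mesh(center, diameter: float, n_lat: int = 16, n_lon: int = 32):
    """Triangulated UV sphere as a :class:`~xrnav.io.SurfaceMesh`.

    Vertex count is 2 + (n_lat - 1) * n_lon (two poles plus the rings).
    """
    from .io import SurfaceMesh

    c = np.asarray(center, dtype=float)
    r = diameter / 2.0
    verts = [c + [0, 0, r]]
    for i in range(1, n_lat):
        th = np.pi * i / n_lat
        for j in range(n_lon):
            ph = 2 * np.pi * j / n_lon
            verts.append(
                c + r * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
            )
    verts.append(c + [0, 0, -r])
    south = len(verts) - 1
    ring = lambda i, j: 1 + (i - 1) * n_lon + (j % n_lon)
    polys = []
    for j in range(n_lon):
        polys.append((0, ring(1, j), ring(1, j + 1)))
    for i in range(1, n_lat - 1):
        for j in range(n_lon):
            polys.append((ring(i, j), ring(i + 1, j), ring(i + 1, j + 1)))
            polys.append((ring(i, j), ring(i + 1, j + 1), ring(i, j + 1)))
    for j in range(n_lon):
        polys.append((south, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)))
    return SurfaceMesh(vertices=np.array(verts), polygons=tuple(tuple(p) for p in polys))
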