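"""C-arm projection geometry.

Coordinate conventions
----------------------
World coordinate system (WCS): origin at the gantry iso-center,
x = patient-left, y = patient-anterior, z = cranial.  At zero angulation the
frontal source sits at (0, -SPD, 0) and looks along +y (posterior-anterior).

Primary angulation (LAO positive / RAO negative) rotates the C-arm about the
patient head-foot axis (z); secondary angulation (CRAN positive / CAUD
negative) rotates about the patient left-right axis (x); the two are composed
primary-then-secondary.

Image coordinate system (ICS): origin at the upper-left corner of the image,
u along columns, v along rows (v grows caudally for the frontal view at zero
angulation, i.e. the patient's head is up).  Pixel centers sit at integer
coordinates; the iso-center with the table at zero projects to the principal
point (n_u/2, n_v/2) for every angulation and SID.

The table offset t is a world-frame vector shared by both C-arms: the whole
imaging system effectively orbits the displaced iso-center, so camera
coordinates of a world point p are  A (p - t) + (0, 0, SPD)  with A the
world-to-camera rotation.  At zero angulation the extrinsic translation
column reduces to (-t_x, -t_y, SPD - t_·) in camera axes; at any angulation
the component of a table shift perpendicular to the view axis moves the
projection by SID/SPD-magnified millimeters while the along-axis component
only changes magnification.

All distances are millimeters; angles are degrees at the API boundary and
radians internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidGeometryError, NotProjectableError

__all__ = [
    "CArmConfig",
    "CArmGeometry",
    "ProjectionMatrix",
    "Ray",
    "backproject_ray",
    "build_projection",
    "project",
    "rotation_gantry",
]

#: Fixed world->camera axis permutation at zero angulation:
#: x_cam = x_world (patient-left), y_cam = -z_world (image rows grow caudally,
#: the sign flip of the v axis), z_cam = y_world (depth along the view axis).
_WORLD_TO_CAM0 = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class CArmGeometry:
    """Full imaging state of one C-arm.

    Parameters
    ----------
    primary_angle : float
        Primary angulation in degrees, LAO positive / RAO negative.
    secondary_angle : float
        Secondary angulation in degrees, CRAN positive / CAUD negative.
    table : tuple of float
        Table offset (t_x, t_y, t_z) in world mm, shared by both C-arms.
    sid : float
        Source-image distance in mm.
    fd : float
        Detector field diagonal in mm; sets the pixel pitch unless
        ``pixel_pitch`` overrides it.
    spd : float
        Source-to-patient (iso-center) distance in mm, fixed per C-arm.
    n_u, n_v : int
        Image width and height in pixels.
    label : str
        ``frontal`` | ``lateral`` | ``monoplane``.
    pixel_pitch : float, optional
        Explicit detector pixel pitch in mm/px (vendor calibration per FD
        setting); when given it takes precedence over the FD-derived pitch.
    angle_limits : tuple of float
        Vendor range guard (|primary| <= limits[0], |secondary| <= limits[1]).
    """

    primary_angle: float = 0.0
    secondary_angle: float = 0.0
    table: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sid: float = 1200.0
    fd: float = 150.0
    spd: float = 810.0
    n_u: int = 1000
    n_v: int = 1000
    label: str = "monoplane"
    pixel_pitch: float | None = None
    angle_limits: tuple[float, float] = (185.0, 90.0)

    def __post_init__(self):
        if not (self.sid > self.spd > 0):
            raise InvalidGeometryError(
                f"require sid > spd > 0, got sid={self.sid}, spd={self.spd}"
            )
        if self.fd <= 0:
            raise InvalidGeometryError(f"fd must be positive, got {self.fd}")
        if self.n_u <= 0 or self.n_v <= 0:
            raise InvalidGeometryError("image dimensions must be positive")
        if not (np.isfinite(self.primary_angle) and np.isfinite(self.secondary_angle)):
            raise InvalidGeometryError("angles must be finite")
        lp, ls = self.angle_limits
        if abs(self.primary_angle) > lp or abs(self.secondary_angle) > ls:
            raise InvalidGeometryError(
                f"angulation ({self.primary_angle}, {self.secondary_angle}) outside "
                f"vendor range (+-{lp}, +-{ls})"
            )
        if self.pixel_pitch is not None and self.pixel_pitch <= 0:
            raise InvalidGeometryError("pixel_pitch must be positive")

    @property
    def pitch(self) -> float:
        """Detector pixel pitch in mm/px.

        From the detector diagonal and the image diagonal (FD/(sqrt(2) n_u)
        for square images), unless an explicit per-FD calibration overrides it.
        """
        if self.pixel_pitch is not None:
            return self.pixel_pitch
        return self.fd / float(np.hypot(self.n_u, self.n_v))

    def with_table(self, table) -> "CArmGeometry":
        return replace(self, table=tuple(float(c) for c in table))


@dataclass(frozen=True)
class CArmConfig:
    """Per-C-arm configuration constants.

    ``fd_pixel_pitch_mm`` maps the displayed FD value (integer cm) to the
    calibrated detector pixel pitch in mm/px, mirroring pixel-spacing values
    taken from original DICOM metadata for each FD setting.  When the map is
    present, an FD value not listed in it is rejected.
    """

    label: str = "frontal"
    spd_mm: float = 810.0
    n_u: int = 1000
    n_v: int = 1000
    sid_range_mm: tuple[float, float] = (900.0, 1300.0)
    fd_values_cm: tuple[int, ...] = (15, 20, 25, 31, 40, 48)
    fd_pixel_pitch_mm: dict[int, float] = field(default_factory=dict)
    table_axis_map: dict[str, str] = field(
        default_factory=lambda: {"long": "z", "lat": "x", "vert": "y"}
    )

    @classmethod
    def from_dict(cls, d: dict) -> "CArmConfig":
        d = dict(d)
        if "fd_pixel_pitch_mm" in d:
            d["fd_pixel_pitch_mm"] = {int(k): float(v) for k, v in d["fd_pixel_pitch_mm"].items()}
        for k in ("sid_range_mm", "fd_values_cm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "CArmConfig":
        """Load from YAML or JSON."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class Ray:
    """Half-line from the focal spot, in world millimeters."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("ray direction must be nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction


@dataclass(frozen=True)
class ProjectionMatrix:
    """Homogeneous 3x4 world-mm -> image-px mapping, defined up to scale.

    Attributes
    ----------
    m : (3, 4) ndarray
        The projection matrix ``K [A | tau]``.
    k : (3, 3) ndarray
        Intrinsic matrix (focal length in px on the diagonal, principal point
        in the last column).
    a : (3, 3) ndarray
        World-to-camera rotation.
    tau : (3,) ndarray
        Extrinsic translation column (rotated world-frame table shift plus
        the depth offset SPD).
    source_mm : (3,) ndarray
        World position of the focal spot (the camera center).
    detector_origin_mm, detector_u_mm, detector_v_mm : (3,) ndarray
        Detector-plane frame: center of the detector and in-plane unit axes
        along increasing u and v.
    pitch : float
        Pixel pitch, mm/px.
    n_u, n_v : int
        Image dimensions in px.
    """

    m: np.ndarray
    k: np.ndarray
    a: np.ndarray
    tau: np.ndarray
    source_mm: np.ndarray
    detector_origin_mm: np.ndarray
    detector_u_mm: np.ndarray
    detector_v_mm: np.ndarray
    pitch: float
    n_u: int
    n_v: int

    @property
    def view_axis(self) -> np.ndarray:
        """Unit vector from source towards the detector center (world)."""
        return self.a.T @ np.array([0.0, 0.0, 1.0])

    def scaled(self, lam: float) -> "ProjectionMatrix":
        """Same camera with the homogeneous matrix rescaled (no-op on output)."""
        if lam == 0:
            raise ValueError("scale must be nonzero")
        return replace(self, m=self.m * lam)


def rotation_gantry(primary_angle: float, secondary_angle: float) -> np.ndarray:
    """Gantry rotation R_PA @ R_SA for the given angulation, as a 3x3 matrix.

    The primary angulation rotates about the patient head-foot axis (world z),
    the secondary about the patient left-right axis (world x); both are
    right-handed about the positive axis (LAO and CRAN positive).
    """
    a = np.radians(float(primary_angle))
    b = np.radians(float(secondary_angle))
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    r_pa = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    r_sa = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    return r_pa @ r_sa


def build_projection(geom: CArmGeometry) -> ProjectionMatrix:
    """Build the projection matrix for a C-arm imaging state.

    The intrinsic focal length is SID/pitch px (sqrt(2) n_u SID / FD for a
    square image); the extrinsic translation column carries the world-frame
    table offset rotated into the camera plus the depth offset SPD.  Signs
    are fixed so that the iso-center at zero table projects to the principal
    point, image rows grow downward, and the magnification at iso-center is
    SID/SPD.
    """
    r_g = rotation_gantry(geom.primary_angle, geom.secondary_angle)
    a = _WORLD_TO_CAM0 @ r_g.T
    tau = a @ (-np.asarray(geom.table, dtype=float)) + np.array([0.0, 0.0, geom.spd])
    f = geom.sid / geom.pitch
    k = np.array(
        [[f, 0.0, geom.n_u / 2.0], [0.0, f, geom.n_v / 2.0], [0.0, 0.0, 1.0]]
    )
    m = k @ np.hstack([a, tau[:, None]])
    source = -a.T @ tau
    axis = a.T @ np.array([0.0, 0.0, 1.0])
    u_axis = a.T @ np.array([1.0, 0.0, 0.0])
    v_axis = a.T @ np.array([0.0, 1.0, 0.0])
    return ProjectionMatrix(
        m=m,
        k=k,
        a=a,
        tau=tau,
        source_mm=source,
        detector_origin_mm=source + geom.sid * axis,
        detector_u_mm=u_axis,
        detector_v_mm=v_axis,
        pitch=geom.pitch,
        n_u=geom.n_u,
        n_v=geom.n_v,
    )


def project(pm: ProjectionMatrix, p, strict: bool = True) -> np.ndarray:
    """Project world point(s) (mm) to image pixel coordinates.

    ``p`` may be a single 3-vector or an (n, 3) array.  Points with
    projective depth <= 0 (at or behind the focal spot plane) raise
    :class:`NotProjectableError` when ``strict``; otherwise they come back
    as NaN.
    """
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    h = pts @ pm.m[:, :3].T + pm.m[:, 3]
    # canonical depth sign: det(K A) > 0 for the unscaled camera, so a
    # negative homogeneous scale shows up as det < 0 and is divided out
    sign = 1.0 if np.linalg.det(pm.m[:, :3]) >= 0 else -1.0
    w = h[:, 2] * sign
    h = h * sign
    bad = w <= 0
    if bad.any():
        if strict:
            raise NotProjectableError(
                f"{int(bad.sum())} point(s) at or behind the focal spot (depth <= 0)"
            )
        w = np.where(bad, np.nan, w)
    uv = h[:, :2] / w[:, None]
    return uv[0] if single else uv


def backproject_ray(pm: ProjectionMatrix, q) -> Ray:
    """Back-project an image point to the viewing ray from the focal spot.

    Round-trip contract: ``project(pm, ray.point_at(s)) == q`` for every
    s > 0 in the valid depth range.
    """
    u, v = float(q[0]), float(q[1])
    d_cam = np.array(
        [(u - pm.k[0, 2]) / pm.k[0, 0], (v - pm.k[1, 2]) / pm.k[1, 1], 1.0]
    )
    return Ray(origin=pm.source_mm, direction=pm.a.T @ d_cam)
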