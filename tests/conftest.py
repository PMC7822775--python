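"""Shared fixtures and independent geometric oracles.

The ray/detector-plane oracle reconstructs the projection from first
principles (explicit source position, detector plane and ray-plane
intersection, with scipy's rotations) and never touches the library's
projection-matrix code path.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xrnav import CArmGeometry


# ---------------------------------------------------------------------------
# independent ray -> detector-plane projection oracle
# ---------------------------------------------------------------------------

def oracle_project(geom: CArmGeometry, p) -> np.ndarray:
    """Project a world point by explicit ray/detector-plane intersection.

    Conventions (stated, not imported): world x = patient-left, y = anterior,
    z = cranial; the imaging system orbits the table-displaced iso-center t,
    so at zero angles the source sits at t + (0, -SPD, 0) and looks along +y;
    primary angulation rotates about z, secondary about x, composed
    primary-then-secondary; image u along the rotated +x, v along the rotated
    -z; principal point at the image center.
    """
    r_g = (
        Rotation.from_euler("z", geom.primary_angle, degrees=True)
        * Rotation.from_euler("x", geom.secondary_angle, degrees=True)
    )
    source = np.asarray(geom.table, dtype=float) + r_g.apply([0.0, -geom.spd, 0.0])
    view = r_g.apply([0.0, 1.0, 0.0])
    e_u = r_g.apply([1.0, 0.0, 0.0])
    e_v = r_g.apply([0.0, 0.0, -1.0])
    det_center = source + geom.sid * view

    p = np.asarray(p, dtype=float)
    ray = p - source
    depth = ray @ view
    if depth <= 0:
        raise ValueError("point not projectable")
    hit = source + ray * (geom.sid / depth)
    rel = hit - det_center
    return np.array(
        [geom.n_u / 2.0 + (rel @ e_u) / geom.pitch, geom.n_v / 2.0 + (rel @ e_v) / geom.pitch]
    )


def oracle_two_ray_lstsq(origins, directions) -> np.ndarray:
    """Point minimizing the sum of squared distances to a set of lines."""
    a = np.zeros((3, 3))
    b = np.zeros(3)
    for o, d in zip(origins, directions):
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        m = np.eye(3) - np.outer(d, d)
        a += m
        b += m @ np.asarray(o, dtype=float)
    return np.linalg.solve(a, b)


def random_geometry(rng: np.random.Generator, **overrides) -> CArmGeometry:
    kwargs = dict(
        primary_angle=rng.uniform(-120, 120),
        secondary_angle=rng.uniform(-40, 40),
        table=tuple(rng.uniform(-80, 80, 3)),
        sid=rng.uniform(950, 1300),
        fd=float(rng.choice([150, 200, 250, 310])),
        spd=rng.uniform(700, 850),
        n_u=1000,
        n_v=1000,
    )
    kwargs.update(overrides)
    return CArmGeometry(**kwargs)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: Biplane geometry of the first registration experiment set: frontal LAO 0
#: at SID 120 cm, lateral LAO 90 at SID 130 cm, table (long, lat, vert) =
#: (-64, -7, 6) cm mapped to world axes (lat, vert, long) -> (x, y, z).
TABLE_SET1_MM = (-70.0, 60.0, -640.0)


@pytest.fixture
def frontal_geom() -> CArmGeometry:
    return CArmGeometry(
        primary_angle=0.0, secondary_angle=0.0, table=TABLE_SET1_MM,
        sid=1200.0, fd=150.0, spd=810.0, label="frontal",
    )


@pytest.fixture
def lateral_geom() -> CArmGeometry:
    return CArmGeometry(
        primary_angle=90.0, secondary_angle=0.0, table=TABLE_SET1_MM,
        sid=1300.0, fd=150.0, spd=765.0, label="lateral",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201015)


@pytest.fixture
def scene():
    from xrnav import default_scene

    return default_scene()


@pytest.fixture
def layout():
    from xrnav import default_layout

    return default_layout()
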