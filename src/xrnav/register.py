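"""Paired-point rigid 3D-3D registration.

Registers tomographic (MRI/CT) marker coordinates to X-ray world coordinates
reconstructed from biplane projections.  The transform minimizing the sum of
squared paired-point distances is found in closed form with the Kabsch/SVD
algorithm, with the determinant correction that excludes reflections.
Alignment quality is reported as the root-mean-squared error over pairs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateFitError

__all__ = ["PointSet3D", "RigidTransform", "apply_transform", "fit_rigid", "rmse"]


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map between tomographic space and X-ray world space."""

    r: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be orthonormal with det +1 (no reflection)")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.r
        m[:3, 3] = self.t
        return m

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.r.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.r.T, -self.r.T @ self.t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.r @ other.r, self.r @ other.t + self.t)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(json.loads(text)["matrix"])

    def save(self, path) -> None:
        """Write as JSON (.json) or whitespace 4x4 row-major text otherwise."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(self.to_json())
        else:
            np.savetxt(path, self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_json(path.read_text())
        return cls.from_matrix(np.loadtxt(path))


@dataclass(frozen=True)
class PointSet3D:
    """Labelled 3D marker set; pairing between sets is by label."""

    labels: tuple[str, ...]
    coords: np.ndarray
    space: str = "xr-world"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != len(coords):
            raise ValueError("labels and coordinates must have equal length")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_coords(cls, coords, space: str = "xr-world") -> "PointSet3D":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        return cls(tuple(f"m{i}" for i in range(len(coords))), coords, space)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x", "y", "z"])
            for lab, (x, y, z) in zip(self.labels, self.coords):
                w.writerow([lab, repr(float(x)), repr(float(y)), repr(float(z))])

    @classmethod
    def from_csv(cls, path, space: str = "xr-world") -> "PointSet3D":
        labels, coords = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                labels.append(row["id"])
                coords.append([float(row["x"]), float(row["y"]), float(row["z"])])
        return cls(tuple(labels), np.array(coords), space)


def _paired(moving: PointSet3D, fixed: PointSet3D) -> tuple[np.ndarray, np.ndarray]:
    if set(moving.labels) != set(fixed.labels):
        raise ValueError(
            "point sets are not fully paired: unmatched labels "
            f"{set(moving.labels) ^ set(fixed.labels)}"
        )
    idx = {lab: i for i, lab in enumerate(fixed.labels)}
    order = [idx[lab] for lab in moving.labels]
    return moving.coords, fixed.coords[order]


def fit_rigid(moving: PointSet3D, fixed: PointSet3D) -> RigidTransform:
    """Least-squares rigid transform taking ``moving`` onto ``fixed``.

    Kabsch/SVD solution of min_T sum_i ||T m_i - f_i||^2 over rotations and
    translations, reflection-free.  Requires >= 3 non-collinear pairs.
    """
    m, f = _paired(moving, fixed)
    if len(m) < 3:
        raise DegenerateFitError(f"need >= 3 paired points, got {len(m)}")
    mc = m - m.mean(axis=0)
    fc = f - f.mean(axis=0)
    # Collinear or coincident markers leave the rotation under-determined.
    if np.linalg.matrix_rank(mc, tol=1e-9 * max(1.0, np.abs(mc).max())) < 2:
        raise DegenerateFitError("markers are collinear or coincident")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = f.mean(axis=0) - r @ m.mean(axis=0)
    return RigidTransform(r, t)


def rmse(transform: RigidTransform, moving: PointSet3D, fixed: PointSet3D) -> float:
    """Root-mean-squared paired-point error sqrt(1/n sum ||T m_i - f_i||^2), mm."""
    m, f = _paired(moving, fixed)
    resid = transform.apply(m) - f
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def apply_transform(transform: RigidTransform, obj):
    """Transformed copy of a point array, PointSet3D, or surface mesh."""
    if isinstance(obj, PointSet3D):
        return PointSet3D(obj.labels, transform.apply(obj.coords), obj.space)
    if hasattr(obj, "vertices"):  # SurfaceMesh duck type
        from dataclasses import replace

        normals = obj.normals
        if normals is not None:
            normals = np.asarray(normals, dtype=float) @ transform.r.T
        return replace(obj, vertices=transform.apply(obj.vertices), normals=normals)
    return transform.apply(obj)
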