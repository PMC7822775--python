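"""Readers and writers for the standard formats the system touches.

* X-ray DICOM runs: frames plus the angiographic geometry tags (positioner
  angles, source-detector and source-patient distances, table position
  relative to iso-center, imager pixel spacing).  Reading uses a configurable
  tag map since vendors differ in which table-position tags they populate.
* 3D surface meshes in the legacy VTK polygonal format, ASCII and binary
  (big-endian, per the legacy specification).
* Plain CSV 2D/3D point lists and JSON/text rigid transforms (the latter live
  on :class:`~xrnav.register.RigidTransform` and
  :class:`~xrnav.register.PointSet3D`).

Pixel conventions: 0-based indices with pixel centers at integer coordinates.
"""

from __future__ import annotations

import csv
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MissingTagError, UnsupportedFormatError
from .geometry import CArmGeometry

__all__ = [
    "DicomGeometryRecord",
    "SurfaceMesh",
    "read_points_2d",
    "read_vtk_polydata",
    "read_xr_dicom",
    "write_derived_dicom",
    "write_points_2d",
    "write_vtk_polydata",
]

#: field -> DICOM keyword; override to match a vendor's table-position tags.
DEFAULT_TAG_MAP = {
    "primary_angle": "PositionerPrimaryAngle",
    "secondary_angle": "PositionerSecondaryAngle",
    "sid_mm": "DistanceSourceToDetector",
    "spd_mm": "DistanceSourceToPatient",
    "table_x_mm": "TableXPositionToIsocenter",
    "table_y_mm": "TableYPositionToIsocenter",
    "table_z_mm": "TableZPositionToIsocenter",
    "pixel_spacing_mm": "ImagerPixelSpacing",
}

_XR_MODALITIES = {"XA", "XRF", "RF"}


@dataclass(frozen=True)
class DicomGeometryRecord:
    """Geometry metadata of one X-ray run."""

    primary_angle: float
    secondary_angle: float
    sid_mm: float
    spd_mm: float
    table_mm: tuple[float, float, float]
    pixel_spacing_mm: tuple[float, float]
    rows: int
    columns: int
    n_frames: int
    modality: str

    def to_carm_geometry(self, label: str = "monoplane") -> CArmGeometry:
        pitch = self.pixel_spacing_mm[0]
        fd = pitch * float(np.hypot(self.columns, self.rows))
        return CArmGeometry(
            primary_angle=self.primary_angle,
            secondary_angle=self.secondary_angle,
            table=self.table_mm,
            sid=self.sid_mm,
            fd=fd,
            spd=self.spd_mm,
            n_u=self.columns,
            n_v=self.rows,
            label=label,
            pixel_pitch=pitch,
        )


def read_xr_dicom(path, tag_map: dict[str, str] | None = None):
    """Read an X-ray run: ``(frames, DicomGeometryRecord)``.

    ``frames`` has shape (n_frames, rows, columns) with 0-based frame
    indexing.  Missing mandatory geometry tags raise
    :class:`~xrnav.errors.MissingTagError` listing every absent tag; a
    non-X-ray modality (e.g. the CT workaround used by some writers) is
    accepted with a warning.
    """
    import pydicom

    tags = dict(DEFAULT_TAG_MAP)
    tags.update(tag_map or {})
    ds = pydicom.dcmread(str(path))
    missing = [kw for kw in tags.values() if kw not in ds]
    if missing:
        raise MissingTagError(missing)
    modality = str(getattr(ds, "Modality", ""))
    if modality not in _XR_MODALITIES:
        warnings.warn(
            f"modality {modality!r} is not an X-ray run; reading geometry anyway",
            stacklevel=2,
        )
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[None]
    spacing = ds[tags["pixel_spacing_mm"]].value
    record = DicomGeometryRecord(
        primary_angle=float(ds[tags["primary_angle"]].value),
        secondary_angle=float(ds[tags["secondary_angle"]].value),
        sid_mm=float(ds[tags["sid_mm"]].value),
        spd_mm=float(ds[tags["spd_mm"]].value),
        table_mm=(
            float(ds[tags["table_x_mm"]].value),
            float(ds[tags["table_y_mm"]].value),
            float(ds[tags["table_z_mm"]].value),
        ),
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        rows=int(ds.Rows),
        columns=int(ds.Columns),
        n_frames=frames.shape[0],
        modality=modality,
    )
    return frames, record


def write_derived_dicom(frames, geom: CArmGeometry, path, modality: str = "XA") -> None:
    """Write captured frame(s) as a derived secondary-capture-style DICOM.

    Carries the full imaging geometry in angiographic tags so that
    :func:`read_xr_dicom` is its inverse.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype != np.uint8:
        if frames.max() <= 1.0:
            frames = (frames * 255).round()
        frames = np.clip(frames, 0, 255).astype(np.uint8)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.ConversionType = "WSD"
    ds.SecondaryCaptureDeviceManufacturer = "xrnav"
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"

    ds.PositionerPrimaryAngle = f"{geom.primary_angle:.6g}"
    ds.PositionerSecondaryAngle = f"{geom.secondary_angle:.6g}"
    ds.DistanceSourceToDetector = f"{geom.sid:.6g}"
    ds.DistanceSourceToPatient = f"{geom.spd:.6g}"
    ds.TableXPositionToIsocenter = geom.table[0]
    ds.TableYPositionToIsocenter = geom.table[1]
    ds.TableZPositionToIsocenter = geom.table[2]
    ds.ImagerPixelSpacing = [f"{geom.pitch:.10g}", f"{geom.pitch:.10g}"]

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = frames.shape[1], frames.shape[2]
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    if frames.shape[0] > 1:
        ds.NumberOfFrames = frames.shape[0]
    ds.PixelData = frames.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# legacy VTK polydata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceMesh:
    """Polygonal surface: vertices in mm, polygon vertex-index tuples."""

    vertices: np.ndarray
    polygons: tuple[tuple[int, ...], ...]
    normals: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        polys = tuple(tuple(int(i) for i in p) for p in self.polygons)
        for p in polys:
            if any(i < 0 or i >= len(v) for i in p):
                raise ValueError("polygon index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "polygons", polys)
        if self.normals is not None:
            n = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(n) != len(v):
                raise ValueError("need one normal per vertex")
            object.__setattr__(self, "normals", n)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def write_vtk_polydata(mesh: SurfaceMesh, path, binary: bool = False) -> None:
    """Write a legacy VTK POLYDATA file (ASCII, or big-endian binary)."""
    n_pts = len(mesh.vertices)
    n_poly = len(mesh.polygons)
    conn = [np.array((len(p),) + p, dtype=np.int32) for p in mesh.polygons]
    total = int(sum(len(c) for c in conn))
    with open(path, "wb") as fh:
        fh.write(b"# vtk DataFile Version 3.0\n")
        fh.write(b"xrnav surface mesh\n")
        fh.write(b"BINARY\n" if binary else b"ASCII\n")
        fh.write(b"DATASET POLYDATA\n")
        fh.write(f"POINTS {n_pts} float\n".encode())
        pts = mesh.vertices.astype(">f4")
        if binary:
            fh.write(pts.tobytes())
            fh.write(b"\n")
        else:
            for p in mesh.vertices:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n".encode())
        fh.write(f"POLYGONS {n_poly} {total}\n".encode())
        if binary:
            fh.write(np.concatenate(conn).astype(">i4").tobytes() if conn else b"")
            fh.write(b"\n")
        else:
            for c in conn:
                fh.write((" ".join(str(i) for i in c) + "\n").encode())
        if mesh.normals is not None:
            fh.write(f"POINT_DATA {n_pts}\n".encode())
            fh.write(b"NORMALS normals float\n")
            if binary:
                fh.write(mesh.normals.astype(">f4").tobytes())
                fh.write(b"\n")
            else:
                for n in mesh.normals:
                    fh.write(f"{n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n".encode())


class _VtkParser:
    """Token/blob reader over a legacy VTK byte stream."""

    def __init__(self, data: bytes, binary: bool):
        self.data = data
        self.pos = 0
        self.binary = binary

    def line(self) -> str:
        end = self.data.find(b"\n", self.pos)
        if end < 0:
            end = len(self.data)
        out = self.data[self.pos : end].decode("ascii", "replace")
        self.pos = end + 1
        return out

    def token(self) -> str:
        while self.pos < len(self.data) and self.data[self.pos : self.pos + 1].isspace():
            self.pos += 1
        start = self.pos
        while self.pos < len(self.data) and not self.data[self.pos : self.pos + 1].isspace():
            self.pos += 1
        if start == self.pos:
            raise UnsupportedFormatError("unexpected end of VTK file")
        return self.data[start : self.pos].decode("ascii")

    def numbers(self, count: int, dtype: str) -> np.ndarray:
        if self.binary:
            np_dtype = {"float": ">f4", "double": ">f8", "int": ">i4"}[dtype]
            nbytes = count * np.dtype(np_dtype).itemsize
            if self.data[self.pos] in b"\r\n":
                self.pos += 1
            blob = self.data[self.pos : self.pos + nbytes]
            if len(blob) != nbytes:
                raise UnsupportedFormatError("truncated VTK binary section")
            self.pos += nbytes
            return np.frombuffer(blob, dtype=np_dtype).astype(
                float if dtype != "int" else np.int64
            )
        vals = [self.token() for _ in range(count)]
        if dtype == "int":
            return np.array([int(v) for v in vals], dtype=np.int64)
        return np.array([float(v) for v in vals], dtype=float)


def read_vtk_polydata(path) -> SurfaceMesh:
    """Read a legacy VTK POLYDATA file (ASCII or big-endian binary)."""
    data = Path(path).read_bytes()
    if data.lstrip()[:1] == b"<":
        raise UnsupportedFormatError(
            "XML VTK files are not supported; use the legacy POLYDATA format"
        )
    if not data.startswith(b"# vtk DataFile"):
        raise UnsupportedFormatError("not a legacy VTK file (bad header)")
    p = _VtkParser(data, binary=False)
    p.line()  # version
    p.line()  # title
    fmt = p.line().strip().upper()
    if fmt not in ("ASCII", "BINARY"):
        raise UnsupportedFormatError(f"unknown VTK data format {fmt!r}")
    p.binary = fmt == "BINARY"
    kw = p.token().upper()
    if kw != "DATASET":
        raise UnsupportedFormatError("malformed VTK header: expected DATASET")
    dataset = p.token().upper()
    if dataset != "POLYDATA":
        raise UnsupportedFormatError(f"unsupported VTK dataset type {dataset!r}")

    vertices = polys = normals = None
    while True:
        try:
            kw = p.token().upper()
        except UnsupportedFormatError:
            break
        if kw == "POINTS":
            n = int(p.token())
            dtype = p.token().lower()
            vertices = p.numbers(3 * n, dtype).reshape(n, 3)
        elif kw == "POLYGONS":
            n_poly = int(p.token())
            total = int(p.token())
            flat = p.numbers(total, "int")
            polys, i = [], 0
            for _ in range(n_poly):
                k = int(flat[i])
                polys.append(tuple(int(x) for x in flat[i + 1 : i + 1 + k]))
                i += 1 + k
        elif kw == "POINT_DATA":
            p.token()  # count
        elif kw == "NORMALS":
            p.token()  # name
            dtype = p.token().lower()
            if vertices is None:
                raise UnsupportedFormatError("NORMALS before POINTS")
            normals = p.numbers(3 * len(vertices), dtype).reshape(-1, 3)
        elif kw in ("VERTICES", "LINES", "TRIANGLE_STRIPS"):
            raise UnsupportedFormatError(f"unsupported POLYDATA section {kw}")
        else:
            raise UnsupportedFormatError(f"unsupported VTK section {kw!r}")
    if vertices is None:
        raise UnsupportedFormatError("VTK file has no POINTS section")
    return SurfaceMesh(vertices=vertices, polygons=tuple(polys or ()), normals=normals)


# ---------------------------------------------------------------------------
# CSV point lists
# ---------------------------------------------------------------------------

def write_points_2d(path, labels, points) -> None:
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "u", "v"])
        for lab, (u, v) in zip(labels, points):
            w.writerow([lab, repr(float(u)), repr(float(v))])


def read_points_2d(path) -> tuple[list[str], np.ndarray]:
    labels, pts = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels.append(row["id"])
            pts.append([float(row["u"]), float(row["v"])])
    return labels, np.asarray(pts, dtype=float).reshape(-1, 2)
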