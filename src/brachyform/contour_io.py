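"""Readers and writers for every external representation the pipeline touches.

Three families of files:

* structure contours -- stacks of planar closed polygons per anatomical
  structure, either as DICOM RT-structure objects or as a plain-text
  fixture dialect (one structure per block, one ``x y z`` point per line,
  blank line between slices);
* channel waypoint lists -- one plain-text file per channel, one
  ``x y z`` point per line, mirroring the TEXT-file intermediate of the
  design workflow;
* triangle meshes -- STL, ascii or binary, unit mm.

All coordinates are mm in the DICOM patient coordinate system as stored.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Literal, Sequence

import numpy as np
import trimesh

log = logging.getLogger(__name__)

PLANARITY_TOL = 1e-6  # mm, max out-of-plane residual for a closed contour
MIN_POINT_SEPARATION = 1e-9  # mm, consecutive waypoints must be distinct

Role = Literal["intracavitary", "interstitial", "loop"]

#: structure-label suffix convention for channel roles
ROLE_SUFFIXES = {"_ic": "intracavitary", "_int": "interstitial", "_loop": "loop"}

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


class ContourFormatError(ValueError):
    """File is not a recognisable contour / mesh representation."""


class ContourValidationError(ValueError):
    """File parsed but violates a geometric invariant."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class Structure:
    """One labelled structure: a stack of polygons (or an open polyline)."""

    label: str
    slices: List[np.ndarray]          # each (k, 3) float, mm
    closed: bool = True               # closed planar contours vs open polyline

    def points(self) -> np.ndarray:
        return np.vstack(self.slices)


@dataclass
class ContourSet:
    """Labelled stacks of planar closed polygons in patient coordinates."""

    structures: List[Structure]
    frame_of_reference: str = "2.25.0"
    slice_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def labels(self) -> List[str]:
        return [s.label for s in self.structures]

    def get(self, label: str) -> Structure:
        for s in self.structures:
            if s.label == label:
                return s
        raise KeyError(f"no structure labelled {label!r}")


@dataclass
class WaypointList:
    """Ordered channel waypoints, at least two, consecutive points distinct."""

    label: str
    points: np.ndarray                # (n, 3) float, mm
    role: Role = "intracavitary"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ContourValidationError(
                f"waypoints of {self.label!r} must be an (n, 3) array")
        if len(self.points) < 2:
            raise ContourValidationError(
                f"channel {self.label!r} needs at least 2 waypoints")
        seps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seps <= MIN_POINT_SEPARATION):
            raise ContourValidationError(
                f"channel {self.label!r} has duplicate consecutive waypoints")


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm; the applicator solid representation."""

    vertices: np.ndarray              # (n, 3) float
    faces: np.ndarray                 # (m, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ContourValidationError("face index out of range")

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0


# ----------------------------------------------------------------------
# geometric validation helpers
# ----------------------------------------------------------------------

def _planarity_residual(points: np.ndarray) -> float:
    """Max distance of points from their best-fit plane (SVD)."""
    pts = points - points.mean(axis=0)
    if len(pts) < 4:
        return 0.0
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    return float(np.abs(pts @ vt[-1]).max())


def _validate_structure(struct: Structure, normal: np.ndarray) -> None:
    for i, poly in enumerate(struct.slices):
        if struct.closed and len(poly) < 3:
            raise ContourValidationError(
                f"structure {struct.label!r} slice {i} has < 3 vertices")
        if struct.closed and _planarity_residual(poly) > PLANARITY_TOL:
            raise ContourValidationError(
                f"structure {struct.label!r} slice {i} is not planar "
                f"within {PLANARITY_TOL} mm")


def _sort_slices(struct: Structure, normal: np.ndarray) -> None:
    """Normalise slice order ascending along the slice normal (closed only)."""
    if not struct.closed or len(struct.slices) < 2:
        return
    pos = [float(np.mean(poly @ normal)) for poly in struct.slices]
    order = np.argsort(pos, kind="stable")
    struct.slices = [struct.slices[i] for i in order]


def _finalise(cs: ContourSet) -> ContourSet:
    seen = set()
    for s in cs.structures:
        if s.label in seen:
            raise ContourValidationError(f"duplicate structure label {s.label!r}")
        seen.add(s.label)
        _validate_structure(s, cs.slice_normal)
        _sort_slices(s, cs.slice_normal)
    return cs


# ----------------------------------------------------------------------
# plain-text contour fixture dialect
# ----------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#\s*contourset\b(.*)$")
_STRUCT_RE = re.compile(r"^structure\s+(\S+)(?:\s+(open|closed))?\s*$")


def write_contours_text(contours: ContourSet, path) -> None:
    """Write the plain-text contour dialect (round-trips to 1e-6 mm)."""
    lines = []
    n = contours.slice_normal
    lines.append(f"# contourset frame={contours.frame_of_reference} "
                 f"normal={n[0]:.9g},{n[1]:.9g},{n[2]:.9g}")
    for s in contours.structures:
        lines.append(f"structure {s.label} {'closed' if s.closed else 'open'}")
        for j, poly in enumerate(s.slices):
            if j:
                lines.append("")
            for p in poly:
                lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
        lines.append("")  # terminate last slice
    Path(path).write_text("\n".join(lines) + "\n")


def read_contours_text(path) -> ContourSet:
    frame = "2.25.0"
    normal = np.array([0.0, 0.0, 1.0])
    structures: List[Structure] = []
    current: Structure | None = None
    slice_pts: List[List[float]] = []

    def close_slice():
        nonlocal slice_pts
        if current is not None and slice_pts:
            current.slices.append(np.asarray(slice_pts, dtype=float))
        slice_pts = []

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        m = _HEADER_RE.match(line)
        if m:
            for tok in m.group(1).split():
                key, _, val = tok.partition("=")
                if key == "frame":
                    frame = val
                elif key == "normal":
                    normal = np.array([float(v) for v in val.split(",")])
            continue
        m = _STRUCT_RE.match(line)
        if m:
            close_slice()
            current = Structure(m.group(1), [], (m.group(2) or "closed") == "closed")
            structures.append(current)
            continue
        if not line:
            close_slice()
            continue
        if current is None:
            raise ContourFormatError(f"{path}: point data before any structure")
        vals = line.split()
        if len(vals) != 3:
            raise ContourFormatError(f"{path}: expected 'x y z', got {line!r}")
        slice_pts.append([float(v) for v in vals])
    close_slice()
    if not structures:
        raise ContourFormatError(f"{path}: no structures found")
    return _finalise(ContourSet(structures, frame, normal))


# ----------------------------------------------------------------------
# DICOM RT-structure
# ----------------------------------------------------------------------

def _is_dicom(path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_rtstruct(path) -> ContourSet:
    """Read structure contours from an RT-structure file or the text dialect.

    One ContourSet entry per ROI, polygon points preserved verbatim in mm,
    slice ordering normalised ascending along the slice normal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not _is_dicom(path):
        return read_contours_text(path)

    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ContourFormatError(f"{path}: modality is not RTSTRUCT")
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise ContourFormatError(f"{path}: missing contour sequence")

    names = {int(item.ROINumber): str(item.ROIName)
             for item in ds.StructureSetROISequence}
    frame = "2.25.0"
    for item in ds.StructureSetROISequence:
        uid = getattr(item, "ReferencedFrameOfReferenceUID", None)
        if uid:
            frame = str(uid)
            break

    structures: List[Structure] = []
    for roi in ds.ROIContourSequence:
        label = names.get(int(roi.ReferencedROINumber),
                          f"roi_{roi.ReferencedROINumber}")
        if "ContourSequence" not in roi:
            raise ContourFormatError(
                f"{path}: ROI {label!r} has no contour sequence")
        slices, closed = [], True
        for item in roi.ContourSequence:
            pts = np.asarray([float(v) for v in item.ContourData],
                             dtype=float).reshape(-1, 3)
            slices.append(pts)
            closed = str(getattr(item, "ContourGeometricType",
                                 "CLOSED_PLANAR")).startswith("CLOSED")
        structures.append(Structure(label, slices, closed))
    return _finalise(ContourSet(structures, frame))


def write_fixture_rtstruct(contours: ContourSet, path) -> None:
    """Write a minimal RT-structure object (fixture writer, not conformant)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = "synthetic^fixture"
    ds.PatientID = "SYN000"
    ds.StructureSetLabel = "fixture"

    frame_uid = contours.frame_of_reference
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, s in enumerate(contours.structures, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = s.label
        roi.ReferencedFrameOfReferenceUID = frame_uid
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for poly in s.slices:
            item = Dataset()
            item.ContourGeometricType = ("CLOSED_PLANAR" if s.closed
                                         else "OPEN_NONPLANAR")
            item.NumberOfContourPoints = len(poly)
            item.ContourData = [f"{v:.6f}" for v in np.asarray(poly).ravel()]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)

    ds.save_as(path, enforce_file_format=True)


# ----------------------------------------------------------------------
# waypoint extraction and waypoint files
# ----------------------------------------------------------------------

def role_from_label(label: str) -> Role:
    for suffix, role in ROLE_SUFFIXES.items():
        if label.endswith(suffix):
            return role  # type: ignore[return-value]
    log.warning("channel label %r has no role suffix (_ic/_int/_loop); "
                "defaulting to intracavitary", label)
    return "intracavitary"


def extract_waypoints(contours: ContourSet, label_prefix: str) -> List[WaypointList]:
    """Pull channel waypoint polylines out of a contour set by label prefix.

    Returns one WaypointList per matching structure, points in stored order;
    an empty list (with a logged warning) when nothing matches.
    """
    out: List[WaypointList] = []
    for s in contours.structures:
        if s.label.startswith(label_prefix):
            out.append(WaypointList(s.label, s.points(), role_from_label(s.label)))
    if not out:
        log.warning("no structure label starts with %r", label_prefix)
    return out


def write_waypoints(waypoints: WaypointList, path) -> None:
    lines = [f"# channel {waypoints.label} role={waypoints.role}"]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in waypoints.points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_waypoints(path) -> WaypointList:
    label = Path(path).stem
    role: Role | None = None
    pts: List[List[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"channel\s+(\S+)", line)
            if m:
                label = m.group(1)
            m = re.search(r"role=(\S+)", line)
            if m:
                role = m.group(1)  # type: ignore[assignment]
            continue
        vals = line.split()
        if len(vals) != 3:
            raise ContourFormatError(f"{path}: expected 'x y z', got {line!r}")
        pts.append([float(v) for v in vals])
    if role is None:
        role = role_from_label(label)
    return WaypointList(label, np.asarray(pts, dtype=float), role)


# ----------------------------------------------------------------------
# STL
# ----------------------------------------------------------------------

def write_stl(mesh: SurfaceMesh, path, mode: str = "binary") -> None:
    """Export an STL file; facet normals are recomputed from vertex winding."""
    if mesh.is_empty:
        raise ValueError("refusing to write an empty mesh")
    if mode not in ("ascii", "binary"):
        raise ValueError(f"mode must be 'ascii' or 'binary', got {mode!r}")
    tm = mesh.as_trimesh()
    file_type = "stl_ascii" if mode == "ascii" else "stl"
    tm.export(str(path), file_type=file_type)


def read_stl(path) -> SurfaceMesh:
    """Load an STL (ascii or binary); duplicate vertices are merged."""
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl")
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise ContourFormatError(f"{path}: not a readable STL ({exc})") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ContourFormatError(f"{path}: no triangles found")
    tm.merge_vertices()
    return SurfaceMesh.from_trimesh(tm)
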