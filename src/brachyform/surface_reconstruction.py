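"""Contour stack -> smoothed, watertight surface mesh of the vaginal topography.

The chain mirrors the segmentation post-processing step of the design
workflow: rasterise the closed contours of a structure into a binary
labelmap, extract a closed isosurface, and apply shrink-resistant
(Taubin) smoothing controlled by a single smoothing factor in [0, 1].

Between-slice occupancy uses nearest-slice extrusion: a voxel centre
between two contour planes is tested against the polygon of the nearer
slice.  This is deterministic and convergent for the stacked planar
contours the pipeline consumes; it does no shape-based morphing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from skimage.measure import marching_cubes

from . import config
from .contour_io import ContourSet, SurfaceMesh

log = logging.getLogger(__name__)


@dataclass
class LabelVolume:
    """Binary occupancy grid with voxel size and the centre of voxel [0,0,0]."""

    grid: np.ndarray          # 3D bool
    spacing: np.ndarray       # (3,) mm, strictly positive
    origin: np.ndarray        # (3,) mm, centre of voxel index (0, 0, 0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def occupied_volume(self) -> float:
        return float(self.grid.sum()) * self.voxel_volume


@dataclass
class SmoothingSpec:
    """Surface smoothing strength; factor 0 is the identity."""

    factor: float = config.SMOOTH_FACTOR

    def __post_init__(self):
        if not 0.0 <= self.factor <= 1.0:
            raise ValueError("smoothing factor must lie in [0, 1]")

    @property
    def iterations(self) -> int:
        return int(round(config.SMOOTH_ITER_SCALE * self.factor))


# ----------------------------------------------------------------------
# contour rasterisation
# ----------------------------------------------------------------------

def voxelize(contours: ContourSet, structure_label: str,
             spacing: float | tuple = config.CONTOUR_SPACING) -> LabelVolume:
    """Rasterise one structure's contour stack into a binary labelmap.

    A voxel centre is occupied iff it lies inside the polygon of the
    nearest slice and within the axial span of the stack.  One voxel of
    empty padding is guaranteed on all sides.  Contour planes must be
    perpendicular to the z axis (the slice normal of every fixture and
    RT export this pipeline consumes).
    """
    struct = contours.get(structure_label)
    if len(struct.slices) == 0:
        raise ValueError(f"structure {structure_label!r} is empty")
    if len(struct.slices) < 2:
        raise ValueError(
            f"cannot concatenate one slice (structure {structure_label!r})")
    normal = np.asarray(contours.slice_normal, dtype=float)
    if abs(abs(normal[2]) - 1.0) > 1e-9:
        raise NotImplementedError("voxelize supports z-normal slices only")

    spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing, float)),
                              (3,)).copy()
    z_levels = np.array([float(np.mean(poly[:, 2])) for poly in struct.slices])
    gaps = np.diff(z_levels)
    if np.any(gaps <= 0):
        raise ValueError("slice positions must be strictly ascending")
    if spacing[2] > gaps.min() / 2:
        raise ValueError(
            f"axial spacing {spacing[2]} mm too coarse for inter-slice "
            f"distance {gaps.min()} mm (need <= half)")

    all_pts = struct.points()
    lo_xy, hi_xy = all_pts[:, :2].min(axis=0), all_pts[:, :2].max(axis=0)
    z_lo, z_hi = z_levels[0], z_levels[-1]

    nx, ny = (np.maximum(np.ceil((hi_xy - lo_xy) / spacing[:2]), 1)
              .astype(int))
    nz = max(int(round((z_hi - z_lo) / spacing[2])), 1)
    # voxel centres tile [lo, hi] exactly; +1 voxel empty padding per side
    xs = lo_xy[0] + (np.arange(nx) + 0.5) * spacing[0]
    ys = lo_xy[1] + (np.arange(ny) + 0.5) * spacing[1]
    zs = z_lo + (np.arange(nz) + 0.5) * spacing[2]

    paths = [MplPath(poly[:, :2]) for poly in struct.slices]
    XY = np.column_stack([np.repeat(xs, ny), np.tile(ys, nx)])

    grid = np.zeros((nx + 2, ny + 2, nz + 2), dtype=bool)
    nearest = np.abs(zs[:, None] - z_levels[None, :]).argmin(axis=1)
    for iz, k in enumerate(nearest):
        inside = paths[k].contains_points(XY).reshape(nx, ny)
        grid[1:-1, 1:-1, iz + 1] = inside

    if not grid.any():
        raise ValueError(
            f"structure {structure_label!r} rasterised to an empty labelmap")
    origin = np.array([lo_xy[0] - 0.5 * spacing[0],
                       lo_xy[1] - 0.5 * spacing[1],
                       z_lo - 0.5 * spacing[2]])
    return LabelVolume(grid, spacing, origin)


# ----------------------------------------------------------------------
# isosurface extraction
# ----------------------------------------------------------------------

def extract_surface_field(field: np.ndarray, spacing, origin) -> SurfaceMesh:
    """Marching-cubes isosurface at 0.5 of a fractional occupancy field.

    ``field`` holds per-voxel-centre material occupancy in [0, 1]; binary
    labelmaps are the special case {0, 1}.  Trilinear interpolation puts
    the surface at the 0.5 crossing, so fields graded over one voxel
    locate their boundary with sub-voxel accuracy.  The output is
    watertight and consistently oriented; if it fragments, the largest
    closed component is kept and a warning is logged.
    """
    import trimesh

    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if not (field >= 0.5).any():
        raise ValueError("field has no occupied voxel")
    padded = np.pad(field.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5,
                                        spacing=tuple(spacing))
    verts = verts + (origin - spacing)
    tm = trimesh.Trimesh(verts, faces, process=True)
    if tm.volume < 0:
        tm.invert()

    if tm.body_count > 1:
        bodies = tm.split(only_watertight=True)
        bodies = sorted(bodies, key=lambda b: abs(b.volume), reverse=True)
        log.warning("labelmap produced %d components; keeping the largest "
                    "(%.1f mm^3)", len(bodies), abs(bodies[0].volume))
        tm = bodies[0]
        if tm.volume < 0:
            tm.invert()
    return SurfaceMesh.from_trimesh(tm)


def extract_surface(volume: LabelVolume) -> SurfaceMesh:
    """Marching-cubes isosurface of a binary labelmap at occupancy 0.5."""
    return extract_surface_field(volume.grid.astype(np.float32),
                                 volume.spacing, volume.origin)


# ----------------------------------------------------------------------
# Taubin smoothing
# ----------------------------------------------------------------------

def _uniform_laplacian(n_vertices: int, edges: np.ndarray):
    """Row-normalised umbrella operator L = D^-1 A - I as a sparse matrix."""
    from scipy import sparse

    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    a = sparse.coo_matrix((np.ones(len(i)), (i, j)),
                          shape=(n_vertices, n_vertices)).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    d_inv = sparse.diags(1.0 / deg)
    return d_inv @ a - sparse.identity(n_vertices)


def smooth_surface(mesh: SurfaceMesh,
                   spec: SmoothingSpec | float = None) -> SurfaceMesh:
    """Shrink-resistant Taubin smoothing scaled by the smoothing factor.

    iterations = round(20 * factor) passes of the lambda/mu pair
    (lambda = 0.5, mu = -0.53); factor 0 returns the mesh unchanged.
    Topology (faces, components) is untouched, so watertightness is
    preserved.
    """
    if spec is None:
        spec = SmoothingSpec()
    elif not isinstance(spec, SmoothingSpec):
        spec = SmoothingSpec(float(spec))

    tm = mesh.as_trimesh()
    if not tm.is_watertight:
        raise ValueError("smooth_surface requires a watertight mesh")
    if spec.iterations == 0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())

    lap = _uniform_laplacian(len(tm.vertices), tm.edges_unique)
    verts = np.array(tm.vertices, dtype=float)
    for _ in range(spec.iterations):
        verts += config.TAUBIN_LAMBDA * (lap @ verts)
        verts += config.TAUBIN_MU * (lap @ verts)
    return SurfaceMesh(verts, mesh.faces.copy())


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def mesh_metrics(mesh: SurfaceMesh):
    """(volume mm^3, area mm^2, watertight flag, component count).

    Volume is the signed divergence-theorem volume; the watertight flag
    is computed (every edge shared by exactly two faces), never assumed.
    """
    tm = mesh.as_trimesh()
    watertight = bool(tm.is_watertight)
    volume = float(tm.volume) if len(tm.faces) else 0.0
    return volume, float(tm.area), watertight, int(tm.body_count)
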