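"""Build the printable applicator solid and the calibration template.

The solid workflow is voxel-based throughout: watertight input meshes
are rasterised to a binary occupancy grid (column-parity scan: a voxel
centre is occupied iff it lies inside the mesh), booleans happen on the
grid (union with the cylindrical base, subtraction of swept channel
tubes), and the result is re-extracted with marching cubes.  Voxel
booleans trade a half-pitch surface quantisation for robustness and
determinism; exact surface CSG on marching-cubes meshes is fragile.

A swept channel tube is the envelope of spheres placed densely along
the resampled centreline; the sphere diameter equals the channel bore
except over the final taper length of interstitial channels, where it
narrows linearly to the tip diameter.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import trimesh

from . import config
from .channel_planning import (ChannelPlan, ValidationReport, bundle_check,
                               curvature_profile, fit_spline,
                               validate_channels)
from .contour_io import SurfaceMesh, WaypointList
from .surface_reconstruction import (LabelVolume, extract_surface,
                                     extract_surface_field)

log = logging.getLogger(__name__)


class BuildError(RuntimeError):
    """A design failed validation; no mesh was produced."""


@dataclass
class BaseSpec:
    """The slim uniform cylindrical base at the vaginal introitus.

    The cylinder spans from ``anchor`` (attachment end, inside the
    topography) along ``-axis`` for ``length`` mm.
    """

    diameter: float = config.BASE_DIAMETER
    length: float = config.BASE_LENGTH
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    anchor: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("base diameter and length must be > 0")
        a = np.asarray(self.axis, dtype=float)
        self.axis = tuple(a / np.linalg.norm(a))


@dataclass
class TemplateSpec:
    """Calibration block: one circular-arc channel per radius of curvature."""

    radii: Tuple[float, ...] = config.TEMPLATE_RADII
    wall_thickness: float = config.TEMPLATE_WALL
    channel_diameter: float = config.BORE_DIAMETER
    channel_spacing: float = config.TEMPLATE_SPACING

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii)
        if not all(b > a for a, b in zip(radii, radii[1:])):
            raise ValueError("template radii must be strictly increasing")
        if min(radii) <= 0 or self.wall_thickness <= 0:
            raise ValueError("template radii and wall thickness must be > 0")
        if self.channel_spacing <= self.channel_diameter:
            raise ValueError("channels overlap at the given spacing")
        self.radii = radii


@dataclass
class ApplicatorDesign:
    """Everything needed to build one applicator solid."""

    topography: SurfaceMesh
    base: BaseSpec
    channels: List[ChannelPlan]
    loop_pairs: List[Tuple[str, str]] = field(default_factory=list)
    pitch: float = config.VOXEL_PITCH
    r_hard: float = config.R_HARD
    r_comfort: float = config.R_COMFORT


@dataclass
class ChannelBuildInfo:
    label: str
    r_min: float
    removed_volume: float             # mm^3, voxel count * pitch^3
    openings: int


@dataclass
class BuildReport:
    validation: ValidationReport
    channels: List[ChannelBuildInfo]
    volume: float
    watertight: bool


# ----------------------------------------------------------------------
# occupancy grids
# ----------------------------------------------------------------------

def _grid_geometry(bounds: np.ndarray, pitch: float, pad: int = 2):
    lo = bounds[0] - pad * pitch
    hi = bounds[1] + pad * pitch
    shape = np.maximum(np.ceil((hi - lo) / pitch), 1).astype(int)
    origin = lo + pitch / 2.0         # centre of voxel (0, 0, 0)
    return origin, shape


def mesh_occupancy(mesh: SurfaceMesh | trimesh.Trimesh, pitch: float,
                   bounds: Optional[np.ndarray] = None,
                   pad: int = 2) -> LabelVolume:
    """Rasterise a watertight mesh: voxel centre occupied iff inside.

    Column-parity scan: every triangle deposits a z-crossing in each grid
    column whose centre its xy-projection covers; sorted crossings pair
    into inside intervals.  Centre-exact (no dilation bias), so measured
    diameters and volumes converge at first order in the pitch.
    """
    tm = mesh.as_trimesh() if isinstance(mesh, SurfaceMesh) else mesh
    if bounds is None:
        bounds = np.asarray(tm.bounds, dtype=float)
    origin, shape = _grid_geometry(bounds, pitch, pad)
    nx, ny, nz = (int(v) for v in shape)
    xs = origin[0] + np.arange(nx) * pitch
    ys = origin[1] + np.arange(ny) * pitch

    cols_all, zs_all = [], []
    for tri in tm.triangles:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = tri
        det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(det) < 1e-12:
            continue                   # vertical triangle: measure-zero columns
        ix_lo = int(np.searchsorted(xs, min(x0, x1, x2)))
        ix_hi = int(np.searchsorted(xs, max(x0, x1, x2)) - 1)
        iy_lo = int(np.searchsorted(ys, min(y0, y1, y2)))
        iy_hi = int(np.searchsorted(ys, max(y0, y1, y2)) - 1)
        if ix_hi < ix_lo or iy_hi < iy_lo:
            continue
        gx = xs[ix_lo:ix_hi + 1][:, None] - x0
        gy = ys[iy_lo:iy_hi + 1][None, :] - y0
        u = (gx * (y2 - y0) - gy * (x2 - x0)) / det
        v = ((x1 - x0) * gy - (y1 - y0) * gx) / det
        inside = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not inside.any():
            continue
        z = z0 + u * (z1 - z0) + v * (z2 - z0)
        ix = np.arange(ix_lo, ix_hi + 1)
        iy = np.arange(iy_lo, iy_hi + 1)
        flat = (ix[:, None] * ny + iy[None, :])[inside]
        cols_all.append(flat)
        zs_all.append(z[inside])

    grid = np.zeros((nx, ny, nz), dtype=bool)
    if cols_all:
        col = np.concatenate(cols_all)
        z = np.concatenate(zs_all)
        order = np.lexsort((z, col))
        col, z = col[order], z[order]
        starts = np.flatnonzero(np.r_[True, col[1:] != col[:-1]])
        counts = np.diff(np.r_[starts, len(col)])
        z0g = origin[2]
        for s, c in zip(starts, counts):
            zs = z[s:s + c]
            # column centres on a shared triangle edge collect the same
            # crossing from both triangles; collapse duplicates
            zs = zs[np.r_[True, np.diff(zs) > 1e-9]]
            c = len(zs) - (len(zs) % 2)   # drop an unpaired grazing contact
            ix, iy = divmod(int(col[s]), ny)
            for k in range(0, c, 2):
                lo_i = int(np.ceil((zs[k] - z0g) / pitch))
                hi_i = int(np.floor((zs[k + 1] - z0g) / pitch))
                if hi_i >= lo_i:
                    grid[ix, iy, max(lo_i, 0):min(hi_i + 1, nz)] = True
    return LabelVolume(grid, np.full(3, float(pitch)), origin)


def _swept_profile(plan: ChannelPlan, step: float):
    """Resample the centreline at ``step`` and give the local tube radius."""
    s = plan.arclengths()
    total = s[-1]
    n = max(int(np.ceil(total / step)), 1)
    s_new = np.linspace(0.0, total, n + 1)
    pts = np.column_stack([np.interp(s_new, s, plan.samples[:, k])
                           for k in range(3)])
    radii = np.full(len(s_new), plan.bore_diameter / 2.0)
    if plan.taper_length > 0 and plan.tip_diameter < plan.bore_diameter:
        from_end = total - s_new
        in_taper = from_end < plan.taper_length
        d = (plan.tip_diameter +
             (plan.bore_diameter - plan.tip_diameter) *
             from_end[in_taper] / plan.taper_length)
        radii[in_taper] = d / 2.0
    return pts, radii


def _tube_field(shape, origin, pitch: float, plan: ChannelPlan) -> np.ndarray:
    """Fractional occupancy field of the swept (possibly tapered) tube.

    Per voxel centre: 1 deep inside the tube, 0 outside, graded linearly
    over one pitch across the wall, so the marching-cubes 0.5 level sits
    at the exact local tube radius (sub-voxel accuracy).
    """
    pts, radii = _swept_profile(plan, step=pitch / 2.0)
    field = np.zeros(shape, dtype=np.float32)
    shape = np.asarray(shape)
    origin = np.asarray(origin, dtype=float)
    for p, r in zip(pts, radii):
        reach = r + pitch
        lo = np.floor((p - reach - origin) / pitch).astype(int)
        hi = np.ceil((p + reach - origin) / pitch).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape - 1)
        if np.any(hi < lo):
            continue
        ax = [origin[k] + np.arange(lo[k], hi[k] + 1) * pitch - p[k]
              for k in range(3)]
        dist = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 +
                       ax[2][None, None, :] ** 2)
        occ = np.clip(0.5 + (r - dist) / pitch, 0.0, 1.0).astype(np.float32)
        window = field[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        np.maximum(window, occ, out=window)
    return field


def _cylinder_field(shape, origin, pitch: float, spec: BaseSpec) -> np.ndarray:
    """Fractional occupancy field of the base cylinder (analytic, graded)."""
    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(spec.axis, dtype=float)
    anchor = np.asarray(spec.anchor, dtype=float)
    coords = [origin[k] + np.arange(shape[k]) * pitch for k in range(3)]
    rel = [coords[0][:, None, None] - anchor[0],
           coords[1][None, :, None] - anchor[1],
           coords[2][None, None, :] - anchor[2]]
    t = rel[0] * axis[0] + rel[1] * axis[1] + rel[2] * axis[2]
    d2 = sum(r ** 2 for r in rel) - t ** 2
    radial = np.sqrt(np.maximum(d2, 0.0))
    occ_r = np.clip(0.5 + (spec.diameter / 2.0 - radial) / pitch, 0.0, 1.0)
    occ_top = np.clip(0.5 + (0.0 - t) / pitch, 0.0, 1.0)
    occ_bot = np.clip(0.5 + (t + spec.length) / pitch, 0.0, 1.0)
    return np.minimum(np.minimum(occ_r, occ_top), occ_bot).astype(np.float32)


def _box_field(shape, origin, pitch: float, lo_corner, hi_corner) -> np.ndarray:
    """Fractional occupancy field of an axis-aligned box (graded faces)."""
    origin = np.asarray(origin, dtype=float)
    lo_c = np.asarray(lo_corner, dtype=float)
    hi_c = np.asarray(hi_corner, dtype=float)
    field = None
    for k in range(3):
        x = origin[k] + np.arange(shape[k]) * pitch
        occ = np.minimum(np.clip(0.5 + (x - lo_c[k]) / pitch, 0.0, 1.0),
                         np.clip(0.5 + (hi_c[k] - x) / pitch, 0.0, 1.0))
        occ = occ.reshape([-1 if i == k else 1 for i in range(3)])
        field = occ if field is None else np.minimum(field, occ)
    return field.astype(np.float32)


def _resolution_guard(plan: ChannelPlan, pitch: float) -> None:
    if pitch > plan.tip_diameter / 4.0:
        raise ValueError(
            f"voxel pitch {pitch} mm too coarse for tip diameter "
            f"{plan.tip_diameter} mm (need <= tip/4)")


# ----------------------------------------------------------------------
# solids
# ----------------------------------------------------------------------

def make_base(spec: BaseSpec, sections: int = 64) -> SurfaceMesh:
    """Watertight cylinder for the uniform base (64-gon by default)."""
    tm = trimesh.creation.cylinder(radius=spec.diameter / 2.0,
                                   height=spec.length, sections=sections)
    axis = np.asarray(spec.axis, dtype=float)
    rot = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], axis)
    tm.apply_transform(rot)
    centre = np.asarray(spec.anchor, dtype=float) - axis * spec.length / 2.0
    tm.apply_translation(centre)
    return SurfaceMesh.from_trimesh(tm)


def merge_base_and_template(topography: SurfaceMesh, base: SurfaceMesh,
                            pitch: float = config.VOXEL_PITCH) -> SurfaceMesh:
    """Voxel union of the topography solid and the base cylinder.

    The two solids must overlap; a disjoint pair is a design error, not a
    printable applicator.
    """
    bounds_a = topography.as_trimesh().bounds
    bounds_b = base.as_trimesh().bounds
    bounds = np.array([np.minimum(bounds_a[0], bounds_b[0]),
                       np.maximum(bounds_a[1], bounds_b[1])])
    occ_a = mesh_occupancy(topography, pitch, bounds)
    occ_b = mesh_occupancy(base, pitch, bounds)
    if not (occ_a.grid & occ_b.grid).any():
        raise BuildError("base does not contact topography")
    return extract_surface(LabelVolume(occ_a.grid | occ_b.grid,
                                       occ_a.spacing, occ_a.origin))


def _carve_field(field: np.ndarray, origin, pitch: float,
                 plans: Sequence[ChannelPlan]):
    """Subtract tube fields in place; returns removed volume per plan (mm^3).

    Removed volume is the drop in total fractional occupancy, which the
    graded fields make a first-order-accurate volume estimate.
    """
    removed = []
    for plan in plans:
        tube = _tube_field(field.shape, origin, pitch, plan)
        before = float(field.sum(dtype=np.float64))
        np.minimum(field, 1.0 - tube, out=field)
        removed.append((before - float(field.sum(dtype=np.float64)))
                       * pitch ** 3)
    return removed


def carve_channel(solid: SurfaceMesh, plan: ChannelPlan,
                  pitch: float = config.VOXEL_PITCH,
                  r_hard: float = config.R_HARD,
                  validate: bool = True) -> SurfaceMesh:
    """Subtract one swept channel tube from a solid (voxel boolean).

    The plan must satisfy the hard radius constraint (checked here unless
    ``validate=False``); the pitch must resolve the tip diameter.
    """
    _resolution_guard(plan, pitch)
    if validate:
        report = validate_channels([plan], r_hard=r_hard)
        if not report.all_pass:
            raise BuildError(
                f"channel {plan.label!r} violates the radius constraint "
                f"(r_min = {report.channels[0].r_min:.1f} mm < {r_hard} mm)")
    occ = mesh_occupancy(solid, pitch)
    field = occ.grid.astype(np.float32)
    _carve_field(field, occ.origin, pitch, [plan])
    if not (field >= 0.5).any():
        raise BuildError("carving removed the entire solid")
    return extract_surface_field(field, occ.spacing, occ.origin)


def make_loop_channel(plan_a: ChannelPlan, plan_b: ChannelPlan,
                      bridge_waypoints: np.ndarray,
                      sample_step: float = config.SAMPLE_STEP) -> ChannelPlan:
    """Join two channels end-to-end through a bridge into one loop plan.

    The result runs a -> bridge -> reversed b, carries role ``loop`` and
    the plain bore (no taper: the loop is filled with water or gel to act
    as an MRI-visible anchor, no needle exits it).  Curvature validation
    applies to the joined plan; a bridge tighter than the hard limit shows
    up as a validation failure downstream, it is not silently accepted.
    """
    bridge = np.asarray(bridge_waypoints, dtype=float)
    label = f"{plan_a.label}+{plan_b.label}_loop"
    bridge_plan = fit_spline(WaypointList(f"{label}_bridge", bridge, "loop"),
                             sample_step=sample_step,
                             bore_diameter=plan_a.bore_diameter)
    # concatenate the member splines with the bridge spline rather than
    # refitting one global spline: a C2 refit through the straight-to-arc
    # junction overshoots the bridge curvature
    samples = np.vstack([plan_a.samples, bridge_plan.samples,
                         plan_b.samples[::-1]])
    keep = np.r_[True, np.linalg.norm(np.diff(samples, axis=0), axis=1) > 1e-9]
    way_pts = np.vstack([plan_a.waypoints.points, bridge,
                         plan_b.waypoints.points[::-1]])
    keep_w = np.r_[True, np.linalg.norm(np.diff(way_pts, axis=0), axis=1) > 1e-9]
    wpl = WaypointList(label, way_pts[keep_w], "loop")
    return ChannelPlan(label, "loop", wpl, samples[keep],
                       bore_diameter=plan_a.bore_diameter)


def build_applicator(design: ApplicatorDesign):
    """Union the topography with the base, then carve every channel.

    Channels are validated (curvature + bundle fit) before any carving;
    a failure aborts with no mesh emitted.  Returns (mesh, BuildReport).
    """
    plans = list(design.channels)
    for a, b in design.loop_pairs:
        labels = [p.label for p in plans]
        if a not in labels or b not in labels:
            raise BuildError(f"loop pair ({a!r}, {b!r}) references unknown channels")

    if plans:
        validation = validate_channels(plans, design.r_hard, design.r_comfort)
        if not validation.all_pass:
            bad = [c.label for c in validation.channels if not c.passed]
            raise BuildError(f"channels {bad} violate the radius constraint; "
                             "aborting before carving")
        bundle = bundle_check(plans, base_diameter=design.base.diameter,
                              axis=design.base.axis)
        if not bundle.ok:
            raise BuildError("channels do not fit the base bundle with clearance")
        largest_bore = max(p.bore_diameter for p in plans)
        if design.base.diameter <= largest_bore + config.BUNDLE_CLEARANCE:
            raise BuildError("base diameter must exceed bore + clearance")
        for p in plans:
            _resolution_guard(p, design.pitch)
    else:
        validation = ValidationReport([], design.r_hard, design.r_comfort)

    base_mesh = make_base(design.base)
    bounds_a = design.topography.as_trimesh().bounds
    bounds_b = base_mesh.as_trimesh().bounds
    bounds = np.array([np.minimum(bounds_a[0], bounds_b[0]),
                       np.maximum(bounds_a[1], bounds_b[1])])
    pitch = design.pitch
    occ_topo = mesh_occupancy(design.topography, pitch, bounds)
    # the base is rasterised analytically (graded field), not via its mesh
    base_field = _cylinder_field(occ_topo.grid.shape, occ_topo.origin,
                                 pitch, design.base)
    if not (occ_topo.grid & (base_field >= 0.5)).any():
        raise BuildError("base does not contact topography")
    field = np.maximum(occ_topo.grid.astype(np.float32), base_field)
    solid_before = field >= 0.5

    removed = _carve_field(field, occ_topo.origin, pitch, plans)
    infos = []
    for plan, rem in zip(plans, removed):
        ends_outside = sum(
            1 for end in (plan.samples[0], plan.samples[-1])
            if not _point_occupied(solid_before, occ_topo.origin, pitch, end))
        infos.append(ChannelBuildInfo(plan.label,
                                      curvature_profile(plan).r_min,
                                      rem, ends_outside))

    mesh = extract_surface_field(field, occ_topo.spacing, occ_topo.origin)
    tm = mesh.as_trimesh()
    report = BuildReport(validation, infos, float(tm.volume),
                         bool(tm.is_watertight))
    return mesh, report


def _point_occupied(grid, origin, pitch, point) -> bool:
    idx = np.round((np.asarray(point) - origin) / pitch).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        return False
    return bool(grid[tuple(idx)])


# ----------------------------------------------------------------------
# calibration template
# ----------------------------------------------------------------------

def make_calibration_template(spec: TemplateSpec = None,
                              pitch: float = config.VOXEL_PITCH,
                              block_width: float = 10.0,
                              overshoot: float = 1.5):
    """Block with one circular-arc channel per radius, bridging the wall.

    The wall occupies y in [0, wall_thickness]; channel k lies in the
    plane z = z_k and follows a circle of its nominal radius whose
    leftmost point sits at mid-wall, entering ``overshoot`` mm below the
    y=0 face and exiting the same amount above the y=wall face.  Returns
    (mesh, plans); the plans feed the force-experiment simulation.
    """
    spec = spec or TemplateSpec()
    wall = spec.wall_thickness
    n = len(spec.radii)
    margin = spec.channel_spacing / 2.0 + spec.channel_diameter
    depth = 2 * margin + (n - 1) * spec.channel_spacing
    x_entry = block_width / 2.0

    # analytic block field on a padded grid
    bounds = np.array([[0.0, 0.0, 0.0], [block_width, wall, depth]])
    origin, shape = _grid_geometry(bounds, pitch, pad=2)
    field = _box_field(tuple(int(v) for v in shape), origin, pitch,
                       (0.0, 0.0, 0.0), (block_width, wall, depth))

    plans = []
    for k, r in enumerate(spec.radii):
        z_k = margin + k * spec.channel_spacing
        cy = wall / 2.0
        cx = x_entry + r                    # circle bulges towards -x
        y_way = np.linspace(-overshoot, wall + overshoot, 7)
        x_way = cx - np.sqrt(r ** 2 - (y_way - cy) ** 2)
        pts = np.column_stack([x_way, y_way, np.full_like(y_way, z_k)])
        wpl = WaypointList(f"template_r{int(round(r)):02d}", pts, "intracavitary")
        plan = fit_spline(wpl, sample_step=min(0.25, config.SAMPLE_STEP),
                          bore_diameter=spec.channel_diameter)
        plans.append(plan)

    for plan in plans:
        _resolution_guard(plan, pitch)
    _carve_field(field, origin, pitch, plans)
    mesh = extract_surface_field(field, np.full(3, float(pitch)), origin)
    return mesh, plans


# ----------------------------------------------------------------------
# mesh measurement helpers (used by tests and the acceptance script)
# ----------------------------------------------------------------------

def fit_circle_2d(xy: np.ndarray):
    """Algebraic (Kasa) least-squares circle fit; returns (centre, radius)."""
    xy = np.asarray(xy, dtype=float)
    a = np.column_stack([xy[:, 0], xy[:, 1], np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r = np.sqrt(sol[2] + cx ** 2 + cy ** 2)
    return np.array([cx, cy]), float(r)


def _section_polygons(mesh: SurfaceMesh, plane_origin, plane_normal):
    tm = mesh.as_trimesh()
    sec = tm.section(plane_origin=np.asarray(plane_origin, float),
                     plane_normal=np.asarray(plane_normal, float))
    if sec is None:
        raise ValueError("plane does not intersect the mesh")
    planar, to_3d = sec.to_2D()
    return planar, np.asarray(to_3d)


def section_circle_diameter(mesh: SurfaceMesh, plane_origin, plane_normal,
                            near_point=None, largest: bool = False) -> float:
    """Circle-fit diameter of one closed curve in a planar cross-section.

    ``largest=True`` picks the biggest closed curve (outer boundary, e.g.
    the base cylinder); otherwise the curve whose centroid is nearest
    ``near_point`` (e.g. a carved channel opening) is used.
    """
    planar, to_3d = _section_polygons(mesh, plane_origin, plane_normal)
    polys = list(planar.polygons_closed)
    polys = [p for p in polys if p is not None]
    if not polys:
        raise ValueError("section contains no closed curve")
    if largest or near_point is None:
        poly = max(polys, key=lambda p: p.area)
    else:
        from shapely.geometry import Point

        inv = np.linalg.inv(to_3d)
        p2 = Point(*(inv @ np.append(np.asarray(near_point, float), 1.0))[:2])
        poly = min(polys, key=lambda p: p.exterior.distance(p2))
    _, radius = fit_circle_2d(np.asarray(poly.exterior.coords))
    return 2.0 * radius


def count_section_holes(mesh: SurfaceMesh, plane_origin, plane_normal,
                        max_diameter: float = 10.0) -> int:
    """Number of small closed curves (channel openings) in a section."""
    planar, _ = _section_polygons(mesh, plane_origin, plane_normal)
    n = 0
    for poly in planar.polygons_closed:
        if poly is None:
            continue
        (x0, y0, x1, y1) = poly.bounds
        if max(x1 - x0, y1 - y0) <= max_diameter:
            n += 1
    return n


def _ray_hits(mesh: SurfaceMesh, origin, direction) -> np.ndarray:
    """Sorted ray parameters of all triangle hits (Moller-Trumbore, brute)."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    tri = mesh.vertices[mesh.faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    s = origin - tri[:, 0]
    u = np.where(ok, np.einsum("ij,ij->i", s, h) / np.where(ok, a, 1.0), -1.0)
    q = np.cross(s, e1)
    v = np.where(ok, (q @ direction) / np.where(ok, a, 1.0), -1.0)
    t = np.where(ok, np.einsum("ij,ij->i", e2, q) / np.where(ok, a, 1.0), -1.0)
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
    t = np.sort(t[hit])
    return t[np.r_[True, np.diff(t) > 1e-9]] if len(t) else t


def ray_material_thickness(mesh: SurfaceMesh, origin, direction) -> float:
    """Length of the first solid interval a ray crosses (mm)."""
    t = _ray_hits(mesh, origin, direction)
    if len(t) < 2:
        raise ValueError("ray does not pass through the solid")
    return float(t[1] - t[0])
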