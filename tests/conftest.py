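import numpy as np
import pytest
import trimesh

import brachyform as bf
from brachyform.contour_io import ContourSet, Structure, SurfaceMesh, WaypointList


def circle_samples(radius, n=360, z=0.0, span=2 * np.pi):
    """Points on a circle of given radius in the z-plane (analytic oracle)."""
    ang = np.linspace(0.0, span, n, endpoint=abs(span - 2 * np.pi) > 1e-12)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.full(len(ang), z)])


def arc_plan(radius, label=None, span=np.pi / 2, n=None):
    """ChannelPlan whose samples lie exactly on a circular arc (1 deg step)."""
    if n is None:
        n = max(int(np.degrees(span)), 3) + 1
    ang = np.linspace(0.0, span, n)
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.zeros(n)])
    label = label or f"arc_r{radius:g}"
    wpl = WaypointList(label, pts[:: max(len(pts) // 8, 1)], "intracavitary")
    return bf.ChannelPlan(label, "intracavitary", wpl, pts)


def square_contour(side, z, centre=(0.0, 0.0)):
    cx, cy = centre
    h = side / 2.0
    return np.array([[cx - h, cy - h, z], [cx + h, cy - h, z],
                     [cx + h, cy + h, z], [cx - h, cy + h, z]])


@pytest.fixture(scope="session")
def unit_cube():
    return SurfaceMesh.from_trimesh(trimesh.creation.box(extents=[1, 1, 1]))


@pytest.fixture(scope="session")
def slab_20mm():
    """12 x 12 x 20 mm slab, z in [0, 20] (carving fixture)."""
    tf = trimesh.transformations.translation_matrix([0, 0, 10])
    return SurfaceMesh.from_trimesh(
        trimesh.creation.box(extents=[12, 12, 20], transform=tf))


@pytest.fixture(scope="session")
def sphere_volume():
    """Voxelised sphere r=10 mm at 0.5 mm spacing (analytic solid)."""
    contours = ContourSet([Structure("sphere", [
        circle_samples(np.sqrt(max(100.0 - z * z, 0.25)), n=180, z=z)
        for z in np.arange(-9.75, 10.0, 0.5)])])
    return bf.voxelize(contours, "sphere", 0.25)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_volume):
    return bf.extract_surface(sphere_volume)


@pytest.fixture(scope="session")
def vault_contours():
    return bf.synth_topography(bf.TopographyParams(seed=1))


@pytest.fixture(scope="session")
def built(vault_contours):
    """Full applicator build: vault + default base + 3 passing channels."""
    mesh = bf.smooth_surface(bf.extract_surface(
        bf.voxelize(vault_contours, "vault", 0.5)))
    plans = [bf.fit_spline(w)
             for w in bf.synth_waypoints(3, vault_contours, "pass", seed=1)]
    design = bf.ApplicatorDesign(mesh, bf.BaseSpec(anchor=(0, 0, 2.0)),
                                 plans, pitch=0.3)
    return bf.build_applicator(design)
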