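"""Deterministic synthetic inputs: vault contours, waypoints, force traces.

Every generator is a pure function of its parameters and seed, so the
whole pipeline runs and is tested without any patient data.

* ``synth_topography`` emulates the gel-distended vaginal vault as seen
  by a segmentation: a stack of closed planar contours shrinking from an
  elliptical opening to an apex, with a few low-order harmonic
  perturbations standing in for anatomical irregularity.
* ``synth_waypoints`` produces channel waypoint polylines whose fitted
  splines land in a requested radius-of-curvature band (pass, advisory
  or fail), verified through the curvature module before returning.
* ``synth_force_trace`` emulates the measured insertion-force shape: a
  smooth in-applicator friction peak at the applicator exit depth whose
  height follows peak(r) = a + b / r, then a drop and a linear
  tissue-cutting ramp.  The defaults are calibrated so the peak at the
  35 mm constraint radius equals the 14 N buckling level:
  2 + 420 / 35 = 14 N.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from matplotlib.path import Path as MplPath

from . import config
from .channel_planning import curvature_profile, fit_spline
from .contour_io import ContourSet, Structure, WaypointList
from .force_analysis import ExperimentDesign, ForceTrace

log = logging.getLogger(__name__)


@dataclass
class TopographyParams:
    """Shape of the synthetic gel-distended vault."""

    semi_axis_x: float = 16.0         # mm, base ellipse semi-axis
    semi_axis_y: float = 13.0         # mm
    apex_depth: float = 40.0          # mm, height of the dome
    harmonic_amplitudes: Tuple[float, ...] = (1.5, 1.0, 0.5)  # mm, modes 1..3
    slice_spacing: float = 1.5        # mm between contour planes
    points_per_slice: int = 72
    seed: int = 0

    def __post_init__(self):
        if self.slice_spacing <= 0:
            raise ValueError("slice spacing must be > 0")
        if len(self.harmonic_amplitudes) > 3:
            raise ValueError("at most 3 harmonic modes")
        limit = 0.3 * min(self.semi_axis_x, self.semi_axis_y)
        if sum(abs(a) for a in self.harmonic_amplitudes) >= limit:
            raise ValueError("harmonic amplitudes too large; contours could "
                             "self-intersect (keep sum < 30% of the smallest "
                             "semi-axis)")


@dataclass
class ForceModelParams:
    """Generator for insertion-force traces.

    peak(r) = baseline + friction / r is strictly decreasing in the
    channel radius r; with the defaults peak(35) = 14 N, the buckling
    level, and peak(75) = 7.6 N.
    """

    baseline: float = 2.0             # N, radius-independent force floor
    friction: float = 420.0           # N*mm, in-applicator friction scale
    tissue_slope: float = 0.05        # N/mm, post-exit cutting ramp
    exit_depth: float = 50.0          # mm, applicator exit (peak location)
    peak_width: float = 5.0           # mm, width of the friction peak
    noise_sd: float = 0.3             # N, additive white noise (0 allowed)
    phantom_sd: float = 0.2           # N, phantom-to-phantom random intercept
    tip_effect: float = 0.0           # N, added to sharp-tip peaks
    max_depth: float = 100.0          # mm
    depth_step: float = 0.05          # mm between samples
    seed: int = 0

    def __post_init__(self):
        if min(self.baseline, self.friction, self.tissue_slope,
               self.noise_sd, self.phantom_sd) < 0:
            raise ValueError("force-model scales must be >= 0")

    def peak(self, radius: float) -> float:
        return self.baseline + self.friction / float(radius)


# ----------------------------------------------------------------------
# topography
# ----------------------------------------------------------------------

def synth_topography(params: TopographyParams = None) -> ContourSet:
    """Stack of closed, simple, star-shaped contours tapering to an apex.

    With zero perturbation the stack is the half-ellipsoid with the given
    semi-axes and depth; harmonic modes add seed-dependent, star-shape
    preserving irregularity that shrinks towards the apex along with the
    contour itself.
    """
    params = params or TopographyParams()
    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0, 2 * np.pi, size=len(params.harmonic_amplitudes))

    theta = np.linspace(0, 2 * np.pi, params.points_per_slice, endpoint=False)
    a, b, c = params.semi_axis_x, params.semi_axis_y, params.apex_depth
    ellipse_r = a * b / np.sqrt((b * np.cos(theta)) ** 2 +
                                (a * np.sin(theta)) ** 2)
    perturb = np.zeros_like(theta)
    for m, amp in enumerate(params.harmonic_amplitudes, start=1):
        perturb += amp * np.cos(m * theta + phases[m - 1])

    n_slices = max(int(np.floor(c / params.slice_spacing)), 2)
    slices = []
    for i in range(n_slices):
        z = i * params.slice_spacing
        scale = np.sqrt(max(1.0 - (z / c) ** 2, 1e-4))
        r = scale * (ellipse_r + perturb)
        slices.append(np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                       np.full_like(theta, z)]))
    label = f"2.25.{params.seed % 10_000_000}"
    return ContourSet([Structure("vault", slices, closed=True)],
                      frame_of_reference=label)


def _inside_topography(point: np.ndarray, contours: ContourSet) -> bool:
    """Nearest-slice point-in-polygon test against the vault structure."""
    struct = contours.get("vault")
    z_levels = np.array([float(np.mean(p[:, 2])) for p in struct.slices])
    z = point[2]
    if z < z_levels[0] - 1e-9 or z > z_levels[-1] + 1e-9:
        return False
    k = int(np.argmin(np.abs(z_levels - z)))
    return bool(MplPath(struct.slices[k][:, :2]).contains_point(point[:2]))


# ----------------------------------------------------------------------
# waypoints
# ----------------------------------------------------------------------

_R_BANDS = {"pass": (60.0, 90.0), "advisory": (38.0, 47.0), "fail": (22.0, 32.0)}


def synth_waypoints(n_channels: int, topography: ContourSet,
                    mode: str = "pass", seed: int = 0,
                    start_z: float = -65.0,
                    max_attempts: int = 100) -> List[WaypointList]:
    """Channel waypoints whose fitted splines land in a curvature band.

    Each channel runs straight up through the base region from
    ``start_z`` to the vault opening plane, then follows a circular arc
    of a band-appropriate radius outwards through the dome until it
    leaves the topography.  The band (pass: r_min >= 50; advisory:
    35 <= r_min < 50; fail: r_min < 35) is verified with the curvature
    module; candidates are redrawn up to ``max_attempts`` times.
    """
    if mode not in _R_BANDS:
        raise ValueError(f"mode must be one of {sorted(_R_BANDS)}")
    rng = np.random.default_rng(seed)
    struct = topography.get("vault")
    apex = float(max(np.mean(p[:, 2]) for p in struct.slices))

    out: List[WaypointList] = []
    for i in range(n_channels):
        # entry ring chosen so up to 3-4 bundled channels keep the
        # bore + clearance separation inside the 12 mm base
        psi = 2 * np.pi * i / n_channels + rng.uniform(-0.1, 0.1)
        rho0 = rng.uniform(2.4, 3.0)
        x0, y0 = rho0 * np.cos(psi), rho0 * np.sin(psi)
        e_r = np.array([np.cos(psi), np.sin(psi), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        start = np.array([x0, y0, start_z])

        for attempt in range(max_attempts):
            radius = rng.uniform(*_R_BANDS[mode])
            straight = [start + e_z * f * (0.0 - start_z)
                        for f in (0.0, 1 / 3, 2 / 3, 1.0)]
            centre = straight[-1] + e_r * radius
            arc = []
            for phi in np.arange(0.12, np.pi / 2, 0.12):
                p = centre - e_r * radius * np.cos(phi) + e_z * radius * np.sin(phi)
                arc.append(p)
                outside = (not _inside_topography(p, topography)
                           and p[2] > 2.0)
                if outside or p[2] > apex + 2.0:
                    break
            pts = np.vstack(straight + arc)
            role = "interstitial" if i % 2 == 0 else "intracavitary"
            suffix = {"interstitial": "_int", "intracavitary": "_ic"}[role]
            wpl = WaypointList(f"needle_{i + 1:02d}{suffix}", pts, role)
            r_min = curvature_profile(fit_spline(wpl)).r_min
            band_ok = {"pass": r_min >= config.R_COMFORT,
                       "advisory": config.R_HARD <= r_min < config.R_COMFORT,
                       "fail": r_min < config.R_HARD}[mode]
            if band_ok:
                out.append(wpl)
                break
        else:
            raise RuntimeError(
                f"could not satisfy curvature band {mode!r} for channel "
                f"{i + 1} within {max_attempts} attempts")
    return out


# ----------------------------------------------------------------------
# force traces
# ----------------------------------------------------------------------

def synth_force_trace(radius: float, tip: str = "blunt",
                      params: ForceModelParams = None,
                      phantom: int = 1, repetition: int = 1,
                      phantom_offset: float = 0.0,
                      rng: Optional[np.random.Generator] = None) -> ForceTrace:
    """One insertion-force trace: friction peak at the exit depth + tissue ramp.

    force(d) = peak * exp(-(d - exit)^2 / (2 w^2)) + slope * max(0, d - exit)
    with peak = baseline + friction / r (+ tip effect + phantom offset),
    plus optional white noise.  Noise-free, the global maximum sits at the
    exit depth (the tissue ramp shifts it by slope * w^2 / peak, well
    under 0.2 mm at the defaults).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    params = params or ForceModelParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    depth = np.arange(0.0, params.max_depth + params.depth_step / 2,
                      params.depth_step)
    peak = params.peak(radius) + phantom_offset
    if tip == "sharp":
        peak += params.tip_effect
    bump = np.exp(-((depth - params.exit_depth) ** 2) /
                  (2.0 * params.peak_width ** 2))
    force = peak * bump + params.tissue_slope * np.maximum(
        0.0, depth - params.exit_depth)
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, size=len(depth))
    return ForceTrace(depth, force, float(radius), tip, phantom, repetition)


def synth_force_dataset(design: ExperimentDesign,
                        params: ForceModelParams = None) -> List[ForceTrace]:
    """One trace per design row, with a phantom-level random intercept.

    Deterministic for a fixed ``params.seed``; the phantom intercept
    (sd ``phantom_sd``) emulates gelatin batch variation and is shared by
    every insertion into the same phantom.
    """
    params = params or ForceModelParams()
    rng = np.random.default_rng(params.seed)
    phantom_ids = sorted(design.table["phantom"].unique())
    offsets = dict(zip(phantom_ids,
                       rng.normal(0.0, params.phantom_sd, len(phantom_ids))))
    traces = []
    for row in design.table.itertuples(index=False):
        traces.append(synth_force_trace(
            row.radius, row.tip, params, phantom=int(row.phantom),
            repetition=int(row.repetition),
            phantom_offset=float(offsets[row.phantom]), rng=rng))
    return traces
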