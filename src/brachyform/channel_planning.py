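"""Waypoints -> channel splines, curvature profiles, radius constraints.

A needle forced through a curved channel sees friction grow with
curvature; below a critical radius the needle jams or buckles.  This
module fits a C2 interpolating spline through clinician waypoints,
estimates the radius of curvature along it with a discrete three-point
circumradius (exact on circles, independent of the spline basis), and
enforces two constraints:

* hard limit  r_min >= 35 mm  -- below it insertion fails (buckling);
* comfort limit 50 mm -- between 35 and 50 mm insertion succeeds but
  force feedback is degraded, so the channel is flagged advisory.

A bundle check verifies that all channels fit, with clearance, inside
the slim cylindrical applicator base where they converge.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from . import config
from .contour_io import Role, WaypointList

log = logging.getLogger(__name__)

_COLLINEAR_AREA_TOL = 1e-12  # mm^2, triangles flatter than this are straight


@dataclass
class ChannelPlan:
    """A planned channel: waypoints, its resampled spline, and bore spec."""

    label: str
    role: Role
    waypoints: WaypointList
    samples: np.ndarray               # (n, 3) arc-length-ordered, mm
    bore_diameter: float = config.BORE_DIAMETER
    tip_diameter: float = config.BORE_DIAMETER
    taper_length: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.bore_diameter >= self.tip_diameter > 0:
            raise ValueError("need bore_diameter >= tip_diameter > 0")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.samples, axis=0),
                                    axis=1).sum())

    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.samples, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class CurvatureProfile:
    """Radius of curvature along a channel; +inf marks straight samples."""

    s: np.ndarray                     # arc-length positions of interior samples
    radius: np.ndarray                # same length as s, > 0 (may be +inf)
    r_min: float
    s_at_min: float


@dataclass
class ChannelValidation:
    label: str
    r_min: float
    s_at_min: float
    passed: bool
    advisory: bool
    offending_spans: List[Tuple[float, float]] = field(default_factory=list)


@dataclass
class ValidationReport:
    channels: List[ChannelValidation]
    r_hard: float = config.R_HARD
    r_comfort: float = config.R_COMFORT

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.channels)

    def get(self, label: str) -> ChannelValidation:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(label)

    def to_text(self) -> str:
        lines = ["label\tr_min_mm\ts_at_min_mm\tstatus"]
        for c in self.channels:
            status = ("FAIL" if not c.passed
                      else "PASS-ADVISORY" if c.advisory else "PASS")
            lines.append(f"{c.label}\t{c.r_min:.3f}\t{c.s_at_min:.3f}\t{status}")
        return "\n".join(lines)


@dataclass
class PairFeasibility:
    label_a: str
    label_b: str
    min_distance: float               # mm between centrelines
    required: float                   # bore_a/2 + bore_b/2 + clearance
    ok: bool


@dataclass
class BundleReport:
    fits_base: dict                   # label -> bool (inside base disc)
    pairs: List[PairFeasibility]

    @property
    def ok(self) -> bool:
        return all(self.fits_base.values()) and all(p.ok for p in self.pairs)


# ----------------------------------------------------------------------
# spline fitting
# ----------------------------------------------------------------------

def _end_tangent(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Unit tangent at p0 of the circumcircle through (p0, p1, p2).

    Falls back to the chord direction for (near-)collinear points.
    """
    u, v = p1 - p0, p2 - p0
    n = np.cross(u, v)
    nn = np.linalg.norm(n)
    if nn < 1e-9 * np.linalg.norm(u) * np.linalg.norm(v):
        return u / np.linalg.norm(u)
    centre = np.linalg.solve(np.array([u, v, n]),
                             np.array([u @ u / 2.0, v @ v / 2.0, 0.0]))
    tangent = np.cross(n / nn, -centre)
    tangent /= np.linalg.norm(tangent)
    return tangent if tangent @ u >= 0 else -tangent

def fit_spline(waypoints: WaypointList,
               sample_step: float = config.SAMPLE_STEP,
               bore_diameter: float = config.BORE_DIAMETER,
               tip_diameter: Optional[float] = None,
               taper_length: float = config.TAPER_LENGTH) -> ChannelPlan:
    """Interpolating C2 cubic through the waypoints, resampled by arc length.

    Chord-length parameterised natural cubic; two waypoints degenerate to a
    straight segment.  Resampling is uniform within each waypoint segment
    (step rounded per segment) so every waypoint is itself a sample.
    Interstitial channels get the default 2.2 mm tapered tip unless a tip
    diameter is given explicitly.
    """
    if sample_step <= 0:
        raise ValueError("sample_step must be > 0")
    pts = waypoints.points
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord <= 1e-9):
        raise ValueError(
            f"channel {waypoints.label!r}: duplicate consecutive waypoints")
    t = np.concatenate([[0.0], np.cumsum(chord)])

    if len(pts) == 2:
        def evaluate(tq):
            w = (tq / t[-1])[:, None]
            return (1 - w) * pts[0] + w * pts[1]
    else:
        # end tangents from the osculating circle through the three end
        # waypoints: reproduces circular arcs far better than natural ends
        # (zero end curvature flattens every arc) and degrades gracefully
        # to the chord direction for collinear ends
        d0 = _end_tangent(pts[0], pts[1], pts[2])
        d1 = -_end_tangent(pts[-1], pts[-2], pts[-3])
        cs = CubicSpline(t, pts, axis=0, bc_type=((1, d0), (1, d1)))
        evaluate = cs

    # dense arc-length table per segment, then uniform resample per segment
    samples = [pts[0]]
    for i in range(len(pts) - 1):
        dense_t = np.linspace(t[i], t[i + 1], max(64, int(chord[i] / sample_step) * 8))
        dense_p = evaluate(dense_t)
        seg = np.linalg.norm(np.diff(dense_p, axis=0), axis=1)
        s_dense = np.concatenate([[0.0], np.cumsum(seg)])
        length = s_dense[-1]
        n = max(1, int(round(length / sample_step)))
        s_targets = np.linspace(0.0, length, n + 1)[1:]
        t_targets = np.interp(s_targets, s_dense, dense_t)
        t_targets[-1] = t[i + 1]          # land exactly on the waypoint
        samples.append(evaluate(t_targets))
    samples = np.vstack([np.atleast_2d(s) for s in samples])

    if tip_diameter is None:
        tip_diameter = (config.TIP_DIAMETER if waypoints.role == "interstitial"
                        else bore_diameter)
    if tip_diameter >= bore_diameter:
        taper_length = 0.0
    return ChannelPlan(waypoints.label, waypoints.role, waypoints, samples,
                       bore_diameter, tip_diameter, taper_length)


# ----------------------------------------------------------------------
# curvature
# ----------------------------------------------------------------------

def circumradius(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Circumradius of each point triple; +inf for collinear triples."""
    a = np.linalg.norm(p1 - p0, axis=-1)
    b = np.linalg.norm(p2 - p1, axis=-1)
    c = np.linalg.norm(p2 - p0, axis=-1)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross, axis=-1)           # 2 * triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(area2 > _COLLINEAR_AREA_TOL,
                     a * b * c / (2.0 * area2), np.inf)
    return r


def curvature_profile(plan: ChannelPlan) -> CurvatureProfile:
    """Discrete radius of curvature at every interior sample.

    radius_i is the circumradius of (p_{i-1}, p_i, p_{i+1}); fewer than
    three samples mean a straight channel (r_min = +inf, empty profile).
    """
    p = plan.samples
    if len(p) < 3:
        return CurvatureProfile(np.empty(0), np.empty(0), np.inf, 0.0)
    r = circumradius(p[:-2], p[1:-1], p[2:])
    s = plan.arclengths()[1:-1]
    i = int(np.argmin(r))
    return CurvatureProfile(s, r, float(r[i]), float(s[i]))


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def _offending_spans(s: np.ndarray, r: np.ndarray, r_hard: float):
    bad = r < r_hard
    spans = []
    start = None
    for i, flag in enumerate(bad):
        if flag and start is None:
            start = s[i]
        elif not flag and start is not None:
            spans.append((float(start), float(s[i - 1])))
            start = None
    if start is not None:
        spans.append((float(start), float(s[-1])))
    return spans


def validate_channels(plans: Sequence[ChannelPlan],
                      r_hard: float = config.R_HARD,
                      r_comfort: float = config.R_COMFORT) -> ValidationReport:
    """Apply the hard (35 mm) and advisory (50 mm) radius constraints.

    A channel passes iff its worst-point radius r_min >= r_hard
    (inclusive: insertion succeeds at exactly the hard limit); it is
    advisory when r_hard <= r_min < r_comfort.  Pure in the r_min values:
    permuting the channel order permutes the report identically.
    """
    if not plans:
        raise ValueError("validate_channels needs at least one plan")
    out = []
    for plan in plans:
        prof = curvature_profile(plan)
        # 1 nm tolerance so exact-boundary arcs are not lost to rounding
        passed = prof.r_min >= r_hard - 1e-6
        advisory = passed and prof.r_min < r_comfort - 1e-6
        spans = _offending_spans(prof.s, prof.radius, r_hard) if not passed else []
        out.append(ChannelValidation(plan.label, prof.r_min, prof.s_at_min,
                                     passed, advisory, spans))
    return ValidationReport(out, r_hard, r_comfort)


# ----------------------------------------------------------------------
# bundle feasibility at the base
# ----------------------------------------------------------------------

def bundle_check(plans: Sequence[ChannelPlan],
                 base_diameter: float = config.BASE_DIAMETER,
                 clearance: float = config.BUNDLE_CLEARANCE,
                 axis: Sequence[float] = (0.0, 0.0, 1.0),
                 centre: Optional[Sequence[float]] = None,
                 entry_offset: Optional[float] = None) -> BundleReport:
    """Check that bundled channels fit inside the base with clearance.

    Every plan must cross the base entry plane (perpendicular to ``axis``
    at projection ``entry_offset``; default: the deepest projection all
    plans reach).  Each channel's effective cross-section
    (bore + clearance) must lie inside the base disc, and every pair of
    centrelines must stay at least bore_a/2 + bore_b/2 + clearance apart
    (checked over all samples -- conservative inside and outside the
    base).
    """
    from scipy.spatial import cKDTree

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    projections = [plan.samples @ axis for plan in plans]
    if entry_offset is None:
        entry_offset = max(float(p.min()) for p in projections)
    for plan, proj in zip(plans, projections):
        if proj.min() > entry_offset + 1e-9 or proj.max() < entry_offset - 1e-9:
            raise ValueError(
                f"channel {plan.label!r} does not reach the base entry plane")

    entries = []
    for plan, proj in zip(plans, projections):
        k = int(np.argmin(np.abs(proj - entry_offset)))
        entries.append(plan.samples[k])
    if centre is None:
        centre = np.mean(entries, axis=0)
    centre = np.asarray(centre, dtype=float)

    fits = {}
    for plan, entry in zip(plans, entries):
        radial = entry - centre
        radial = radial - (radial @ axis) * axis
        reach = np.linalg.norm(radial) + (plan.bore_diameter + clearance) / 2
        fits[plan.label] = bool(reach <= base_diameter / 2 + 1e-9)

    pairs = []
    trees = [cKDTree(plan.samples) for plan in plans]
    for i in range(len(plans)):
        for j in range(i + 1, len(plans)):
            d, _ = trees[j].query(plans[i].samples)
            dmin = float(d.min())
            need = (plans[i].bore_diameter + plans[j].bore_diameter) / 2 + clearance
            pairs.append(PairFeasibility(plans[i].label, plans[j].label,
                                         dmin, need, dmin >= need))
    report = BundleReport(fits, pairs)
    for p in report.pairs:
        if not p.ok:
            log.warning("channels %r and %r are %.2f mm apart (need %.2f)",
                        p.label_a, p.label_b, p.min_distance, p.required)
    return report
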