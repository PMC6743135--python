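# Methods

This note records the models, numerical choices and known limitations of
the `brachyform` pipeline. All lengths are mm, forces N; coordinates are
the DICOM patient system (LPS) as stored, with no axis flips.

## Contour handling

Structure contours are stacks of closed planar polygons, one structure
per ROI. Closed contours must be coplanar within 1e-6 mm; structures
marked *open* (channel waypoint polylines, which are genuinely
non-planar 3D curves) are exempt from the planarity check. Slices are
normalised ascending along the slice normal; point order within a
polygon is never altered. A plain-text dialect (one structure per block,
one `x y z` point per line, blank line between slices) mirrors the DICOM
content so that fixtures need no binary files; a minimal RT-structure
writer exercises the DICOM path.

## Surface reconstruction

`voxelize` rasterises a structure on an isotropic grid (default 0.5 mm,
below the 2.2 mm needle-tip scale while fast at desk scale). Occupancy
between contour planes is decided by point-in-polygon against the
*nearest* slice (nearest-slice extrusion). This is deterministic and
converges to the true solid as spacing shrinks; it does not morph
between dissimilar neighbouring contours, which is acceptable for the
smooth, star-shaped vault contours this pipeline consumes but would
staircase a branching structure. One voxel of empty padding guarantees
closed isosurfaces.

`extract_surface` is a marching-cubes isosurface at occupancy 0.5. A
consequence worth noting: a single occupied voxel yields the octahedron
spanning half-way to its neighbours (volume `s^3/6`), not a cuboid —
that is the correct 0.5-level set of the trilinear field. If the
labelmap fragments, the largest closed component is kept and a warning
logged (gel pockets can fragment a segmentation).

`smooth_surface` maps the single smoothing factor `f ∈ [0, 1]` to
`round(20·f)` Taubin passes with λ = 0.5, μ = −0.53 (shrink-resistant
pair, uniform umbrella Laplacian). Factor 0 is the identity; topology is
untouched, so watertightness survives. On the voxelised sphere fixture,
factor 0.5 cuts surface area while holding volume within 5%. The
factor-to-iterations mapping is this package's own convention; the
upstream tool that inspired the parameter does not document its
algorithm, so equivalence is defined by these invariants only.

## Channel planning

Waypoints are interpolated by a chord-length-parameterised C² cubic.
End conditions are first derivatives taken from the **osculating circle
through the three end waypoints** (falling back to the chord direction
when collinear). Natural ends were tried first and rejected: forcing
zero end curvature flattens every arc, missing a 60 mm circle sampled by
4 waypoints by 0.8 mm where the circle-tangent ends stay within
0.03 mm. Resampling to the 0.5 mm sample step is uniform *within each
waypoint segment* so that every waypoint is itself a sample (the
"samples pass through waypoints" invariant); spacing across segments
differs only by step rounding.

Curvature is estimated by the discrete three-point circumradius
`r = abc/(4·Area)` on consecutive samples — exact on circles at any
spacing and independent of the spline basis, hence trivially oracled.
Collinear triples give +∞.

Validation is pointwise at the worst point: a channel passes iff
`r_min ≥ 35 mm` (inclusive — insertions succeed at exactly the limit;
a 1e-6 mm tolerance absorbs floating-point rounding at the boundary),
and carries an advisory flag for `35 ≤ r_min < 50 mm`, where insertion
succeeds but force feedback degrades. Applying the constraint to the
worst point of a multi-curved channel is the conservative reading.

`bundle_check` tests (a) each channel's effective cross-section
(bore + clearance, default 2.6 + 0.4 mm) against the 12 mm base disc at
the entry plane and (b) pairwise centreline separation
`≥ bore_a/2 + bore_b/2 + clearance` over *all* samples, which is
conservative outside the base as well. Polyline distances are nearest
sample-point distances (0.5 mm sampling ⇒ ≲0.25 mm slack, well inside
the clearance).

## Solid construction

All booleans run on **fractional occupancy fields** sampled at voxel
centres: 1 deep inside, 0 outside, graded linearly over one voxel pitch
wherever the surface is analytic (swept tubes, base cylinder, template
block). Marching cubes at level 0.5 then places those surfaces with
sub-voxel accuracy; measured bores and removed volumes are within
~0.3% at the default 0.2 mm pitch, where pure binary masks mis-measured
the 2.6 mm bore by up to 6% under unlucky grid alignment. Watertight
input meshes (the topography) are rasterised binarily by a column-parity
scan — a voxel centre is occupied iff inside the mesh — which is
centre-exact and unbiased; duplicate crossings collected where a column
pierces a shared triangle edge are collapsed before parity pairing.

A swept channel is the envelope of spheres every half-pitch along the
resampled centreline; the local diameter equals the 2.6 mm bore except
over the final taper length (default 10 mm, a configuration choice — the
design fixes only the 2.6 → 2.2 mm end diameters) of interstitial
channels. Loop channels keep the plain bore: they are filled with water
or gel as MRI-visible anchors, no needle exits them. A loop is formed by
concatenating the two member channels' sample polylines with a spline
fitted to the bridge waypoints; refitting one global C² spline was
rejected because it overshoots curvature ~15% at the straight-to-arc
junction, spuriously failing bridges at exactly the constraint radius.
Curvature validation applies to the joined plan.

`build_applicator` validates every channel (curvature, bundle fit,
pitch-resolution guard `pitch ≤ tip/4`) *before* any carving and aborts
without emitting a mesh on failure. The base cylinder is rasterised
analytically from its spec; its placement relative to the topography is
an explicit input (clinician-chosen in practice), not inferred. Removed
volume per channel is the drop in total fractional occupancy times the
voxel volume. Carving commutes to ~1e-3 in final volume because each
subtraction is a pointwise minimum.

The calibration template is a block whose 5 mm wall (y ∈ [0, 5]) is
bridged by one circular-arc channel per radius 20…75 mm (5 mm steps,
6 mm channel spacing, 12 channels), each arc's leftmost point at
mid-wall and overshooting both faces by 1.5 mm so carving opens them.

## Force analysis

The zero-phase filter is a length-20 moving average applied forward and
backward (`filtfilt`) with reflective ("even") edge padding — the edge
policy is this package's choice; it keeps constants exact. The two
passes square the single-pass gain `sin(πfk)/(k sin(πf))` and cancel its
phase.

Buckling is strict exceedance of 14 N **on the filtered trace** (the
raw-vs-filtered choice is exposed in configuration); the abort depth is
the first crossing, summary statistics cover samples up to it, and
buckled insertions are excluded from the factorial analysis. A radius
level whose exclusions leave any (radius × tip) cell with fewer than two
insertions is dropped from the ANOVA with a warning, mirroring how the
experimenters discarded the sub-35 mm channels.

The two-way fixed-effects ANOVA (radius × tip, with interaction) uses
the classical closed-form sums of squares when the design is balanced
(also making 1000-replicate null simulations cheap) and Type II sums of
squares via statsmodels when exclusions unbalance the cells — Type II is
the conventional choice when the interaction is not of primary interest,
and the interaction is still reported. Tukey–Kramer compares all level
pairs with `q = |m_i − m_j| / sqrt((MS_E/2)(1/n_i + 1/n_j))` against
studentized-range critical values computed numerically from
`scipy.stats.studentized_range` (no table lookup; accuracy ~1e-4); with
equal group sizes this reduces exactly to Tukey's HSD.

The randomised design permutes the radius set anew per phantom; the ten
phantoms map one-to-one onto the 2 tips × 5 repetitions, giving n = 5
per cell over 120 insertions for the 12-radius template.

## Synthetic data

The topography generator emulates a gel-distended vault as a half
ellipsoid (semi-axes 16 × 13 mm, depth 40 mm, 1.5 mm slice spacing) with
up to three low-order harmonic perturbations (default 1.5/1.0/0.5 mm,
sum capped below 30% of the smallest semi-axis so contours stay simple
and star-shaped). It reproduces the *format and scale* of a
segmentation, not anatomy: no wall thickness variation, no neighbouring
organs, no segmentation noise — so passing geometry tests demonstrates
pipeline correctness, not clinical adequacy.

Force traces follow
`F(d) = peak(r)·exp(−(d−50)²/(2·5²)) + 0.05·max(0, d−50)` with
`peak(r) = 2 + 420/r`: a smooth in-applicator friction peak at the 50 mm
exit depth, then a drop and a linear tissue-cutting ramp, plus white
noise (sd 0.3 N) and a phantom-level intercept (sd 0.2 N). The 1/r law
is the simplest strictly decreasing model consistent with the observed
monotone trend; no capstan exponential is claimed. The calibration makes
`peak(35) = 14 N`, *exactly* the buckling threshold: every sub-35 mm
radius buckles deterministically, radii above 35 mm never do, and 35 mm
itself is marginal — roughly half of its noisy insertions cross the
threshold, which matches the experimental account of 35 mm as the
testing limit. Consequently the end-to-end tests assert buckling for all
r < 35 and none for r > 35, leaving r = 35 unasserted. A related limit
of the 1/r law: distant high-radius pairs (55 vs 75 mm differ by 2 N)
remain statistically separable even where the measured data plateaued,
so the post-hoc tests assert that all pairs at or below 50 mm differ and
that the *weakest* contrast lies above 50 mm, rather than blanket
non-significance above 50 mm.

Tip type adds no mean effect by default (the experiment's null finding);
a nonzero `tip_effect` is available for power studies. Every generator
is a pure function of (parameters, seed).

## Problem sizes and tolerances

Tests carve at 0.15–0.4 mm pitch on 12–90 mm fixtures and measure
diameters by least-squares circle fits to cross-section polygons
(tolerance 0.2 mm); the acceptance script uses 0.1 mm pitch for slab and
template measurements and 0.15 mm for the full applicator build. The
null-simulation check runs 1000 replicates of a 2×2, n = 5 design with a
fixed seed and expects the 5% type-I rate within [0.03, 0.07]. The
curvature oracle demands `|r_min − R|/R < 1e-3` on 1°-sampled circles
for R ∈ [10, 200] mm.

## Known limitations

Voxelisation assumes z-normal contour planes (true of all RT exports and
fixtures this pipeline consumes). Mesh rasterisation is centre-exact but
binary, so re-voxelised outer surfaces carry up to half-pitch placement
error — analytic primitives avoid this via graded fields. No automated
path planning, needle–tissue deflection modelling, print slicing, dose
calculation or sterilisation/biocompatibility assessment is included.
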