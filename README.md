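# brachyform

Design pipeline for **personalised gynaecological brachytherapy
applicators** with curved needle channels, plus the accompanying
**needle insertion-force analysis**.

Commercial intracavitary applicators are one-size-fits-all; for large or
irregular tumours their fixed needle-channel positions limit dose
conformity. An MRI-driven alternative reconstructs the gel-distended
vaginal vault from segmented contours, plans patient-specific curved
channels for 6F needles, and carves them into a printable solid that
merges the vault topography with a slim cylindrical base. Because a
needle forced through a curved channel sees friction grow as the bend
tightens, channel curvature must respect an experimentally determined
radius constraint; `brachyform` implements both the design chain and the
force experiment's analysis. It is aimed at medical-physics and
device-design researchers prototyping applicator workflows.

## What it computes

* **Surface reconstruction** — RT-structure contours (DICOM or a
  plain-text dialect) → binary labelmap → watertight marching-cubes
  surface → shrink-resistant Taubin smoothing (smoothing factor 0.5 by
  default).
* **Channel planning** — clinician waypoints → chord-length cubic spline
  with osculating-circle end tangents, resampled by arc length; the
  radius of curvature along the channel is the three-point circumradius

  `r_i = (a·b·c) / (4·Area)` over consecutive sample triples,

  validated against the hard limit `r_min ≥ 35 mm` (needle jamming /
  buckling) and the advisory comfort limit `50 mm`, plus a bundle-fit
  check at the 12 mm base.
* **Solid construction** — voxel booleans on fractional occupancy fields:
  union of topography and base, swept-tube subtraction with a 2.6 mm
  bore, 2.2 mm tapered interstitial tips, interlinked fillable loop
  channels, and the calibration template (arc channels r = 20…75 mm in
  5 mm steps bridging a 5 mm wall). STL in/out.
* **Force analysis** — zero-phase moving-average filter (kernel 20),
  per-insertion summaries (peak, median, quartiles), buckling detection
  at 14 N with abort depth, per-radius mean force–depth curves, two-way
  ANOVA (radius × tip, interaction) and Tukey–Kramer post-hoc at
  α = 0.05, with the randomised per-phantom experiment design.
* **Synthetic fixtures** — deterministic generators for vault contour
  stacks, banded-curvature waypoints, and force traces following
  `peak(r) = a + b/r` (defaults `a = 2 N`, `b = 420 N·mm`, so
  `peak(35 mm) = 14 N`) with a friction peak at the 50 mm applicator
  exit and a linear tissue-cutting ramp.

## Worked example

```python
import brachyform as bf

# synthetic vault -> smoothed surface
contours = bf.synth_topography(bf.TopographyParams(seed=1))
mesh = bf.smooth_surface(bf.extract_surface(bf.voxelize(contours, "vault", 0.5)))

# three channels, validated, carved into the applicator
plans = [bf.fit_spline(w) for w in bf.synth_waypoints(3, contours, "pass", seed=1)]
print(bf.validate_channels(plans).to_text())
design = bf.ApplicatorDesign(mesh, bf.BaseSpec(anchor=(0, 0, 2.0)), plans, pitch=0.3)
solid, report = bf.build_applicator(design)
print(f"volume {report.volume:.0f} mm^3, watertight={report.watertight}")
for info in report.channels:
    print(f"  {info.label}: r_min {info.r_min:.1f} mm, openings {info.openings}")
```

prints

```
label	r_min_mm	s_at_min_mm	status
needle_01_int	54.222	72.718	PASS
needle_02_ic	61.512	73.723	PASS
needle_03_int	64.829	74.177	PASS
volume 22912 mm^3, watertight=True
  needle_01_int: r_min 54.2 mm, openings 2
  needle_02_ic: r_min 61.5 mm, openings 2
  needle_03_int: r_min 64.8 mm, openings 2
```

Every channel's worst-point radius of curvature clears the 35 mm hard
limit (and the 50 mm comfort limit, so no advisory flags); each carved
channel opens at the base entry and through the vault surface (2
openings). The insertion-force side runs the same way:

```python
design = bf.randomize_design([float(r) for r in range(20, 80, 5)], seed=3)
traces = bf.synth_force_dataset(design, bf.ForceModelParams(seed=3))
summary, anova, tukey, curves = bf.analyse_experiment(traces, exit_depth=50.0)
print(sorted(summary[summary.buckled].radius.unique()))
print(anova.table.round(3))
```

flags the sub-35 mm radii as buckled (the 35 mm channel itself sits at
the 14 N testing limit) and yields a strongly significant radius effect
with no tip-type or interaction effect.

A thin CLI wraps the same calls: `brachyform simulate | build |
template | forces` (see `--help`).

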