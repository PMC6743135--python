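"""Pipeline-wide defaults.

All lengths are millimetres, all forces Newton, throughout the package.
Coordinates are the DICOM patient coordinate system (LPS) as stored; no
axis flips anywhere, and STL files are written in unit mm.

Values that come from the clinical design are fixed here once; values
the design method leaves open (taper length, base length, smoothing
iteration mapping, voxel pitch) are ordinary configuration and can be
overridden per call.
"""

# --- channel geometry -------------------------------------------------
BORE_DIAMETER = 2.6        # mm, swept-cut cross-section of every needle channel
TIP_DIAMETER = 2.2         # mm, tapered exit of interstitial channels
TAPER_LENGTH = 10.0        # mm, linear diameter transition ending at the surface
SAMPLE_STEP = 0.5          # mm, arc-length resampling step for channel splines

# --- curvature constraints --------------------------------------------
R_HARD = 35.0              # mm, minimum radius of curvature (jamming/buckling)
R_COMFORT = 50.0           # mm, advisory radius below which insertion-force
                           # feedback is degraded

# --- applicator solid --------------------------------------------------
BASE_DIAMETER = 12.0       # mm, slim uniform base at the vaginal introitus
BASE_LENGTH = 60.0         # mm, base length (not clinically prescribed)
BUNDLE_CLEARANCE = 0.4     # mm, wall left between bundled channels
VOXEL_PITCH = 0.2          # mm, default pitch for voxel boolean carving
CONTOUR_SPACING = 0.5      # mm, default labelmap voxel size for contours

# --- surface smoothing -------------------------------------------------
SMOOTH_FACTOR = 0.5        # default closed-surface smoothing factor in [0, 1]
SMOOTH_ITER_SCALE = 20     # iterations = round(SMOOTH_ITER_SCALE * factor)
TAUBIN_LAMBDA = 0.5        # Taubin shrink step
TAUBIN_MU = -0.53          # Taubin inflate step (shrink-resistant pairing)

# --- calibration template ----------------------------------------------
TEMPLATE_RADII = tuple(float(r) for r in range(20, 80, 5))  # 20..75 mm
TEMPLATE_WALL = 5.0        # mm, wall thickness bridged by each arc channel
TEMPLATE_SPACING = 6.0     # mm, centre-to-centre channel spacing in the block

# --- force experiment ---------------------------------------------------
INSERTION_SPEED = 5.0      # mm/s
FILTER_KERNEL = 20         # samples, zero-phase moving-average kernel
BUCKLING_THRESHOLD = 14.0  # N, applied to the *filtered* force trace
ALPHA = 0.05               # significance level for ANOVA / Tukey-Kramer
N_PHANTOMS = 10
N_REPETITIONS = 5
TIP_TYPES = ("blunt", "sharp")
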