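"""Needle insertion-force experiment: filtering, summaries, ANOVA, Tukey-Kramer.

The experiment inserts 6F brachytherapy needles at 5 mm/s through the
calibration template's curved channels (radii 20..75 mm) into a gelatin
phantom, recording axial force versus insertion depth.  The analysis
chain is:

1. zero-phase moving-average filtering (kernel 20, forward-backward, so
   the filtered trace has no depth lag);
2. per-insertion summary statistics (peak, median, quartiles) and
   buckling detection -- a filtered force exceeding 14 N aborts the
   insertion and excludes the trace from the factorial analysis;
3. per-radius mean force-depth curves;
4. two-way fixed-effects ANOVA (radius x tip type, with interaction) on
   the peak forces, classical sums of squares when balanced, Type II via
   statsmodels when exclusions unbalance the cells;
5. Tukey-Kramer all-pairs comparison on the studentized range, valid for
   unequal group sizes (reduces to Tukey's HSD when n is equal).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import config

log = logging.getLogger(__name__)


@dataclass
class ForceTrace:
    """Raw or filtered depth-force samples for one insertion."""

    depth: np.ndarray                 # mm, monotone non-decreasing
    force: np.ndarray                 # N
    radius: float                     # mm, channel radius of curvature
    tip: str = "blunt"                # blunt | sharp
    phantom: int = 1
    repetition: int = 1
    speed: float = config.INSERTION_SPEED

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.depth.shape != self.force.shape or self.depth.ndim != 1:
            raise ValueError("depth and force must be equal-length 1D arrays")
        if np.any(np.diff(self.depth) < 0):
            raise ValueError("depth must be monotone non-decreasing")
        if not (np.isfinite(self.depth).all() and np.isfinite(self.force).all()):
            raise ValueError("trace contains non-finite values")

    def replace_force(self, force: np.ndarray) -> "ForceTrace":
        return ForceTrace(self.depth.copy(), np.asarray(force, float),
                          self.radius, self.tip, self.phantom,
                          self.repetition, self.speed)


@dataclass
class ForceSummary:
    peak: float
    median: float
    q25: float
    q75: float
    peak_depth: float
    buckled: bool
    abort_depth: Optional[float] = None
    peak_in_applicator: Optional[bool] = None

    def __post_init__(self):
        if not self.q25 <= self.median <= self.q75 <= self.peak + 1e-12:
            raise ValueError("summary quartiles are inconsistent")
        if self.buckled and self.abort_depth is None:
            raise ValueError("a buckled insertion must carry an abort depth")


@dataclass
class AnovaTable:
    """Two-factor ANOVA decomposition with interaction."""

    table: pd.DataFrame               # rows: factors, interaction, residual
    alpha: float = config.ALPHA

    def p(self, source: str) -> float:
        return float(self.table.loc[source, "p"])

    def significant(self, source: str) -> bool:
        return self.p(source) < self.alpha

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["residual", "mean_sq"])

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["residual", "df"])


@dataclass
class ExperimentDesign:
    """Randomised insertion order: radii permuted anew per phantom."""

    table: pd.DataFrame               # columns: phantom, radius, tip, repetition
    seed: int


@dataclass
class MeanForceCurves:
    depth: np.ndarray                 # common depth grid, mm
    curves: Dict[float, np.ndarray]   # radius -> mean force, N
    peak_depths: Dict[float, float]   # radius -> depth of the curve maximum


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

def zero_phase_ma(trace: ForceTrace,
                  kernel: int = config.FILTER_KERNEL) -> ForceTrace:
    """Zero-phase moving average: forward then backward, reflective edges.

    The two passes square the single-pass moving-average frequency
    response and cancel its phase, so the output peaks at zero lag
    against the input.  Output length equals input length.
    """
    n = len(trace.force)
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    if kernel > n:
        raise ValueError(f"kernel {kernel} exceeds trace length {n}")
    if kernel == 1:
        return trace.replace_force(trace.force.copy())
    b = np.full(kernel, 1.0 / kernel)
    out = signal.filtfilt(b, [1.0], trace.force,
                          padtype="even", padlen=kernel - 1)
    return trace.replace_force(out)


# ----------------------------------------------------------------------
# per-insertion summary and buckling
# ----------------------------------------------------------------------

def summarize(trace: ForceTrace,
              buckling_threshold: float = config.BUCKLING_THRESHOLD,
              exit_depth: Optional[float] = None) -> ForceSummary:
    """Summary statistics up to the abort depth; buckling by strict exceedance.

    The insertion buckles iff the (filtered) force strictly exceeds the
    threshold; the abort depth is the first crossing and statistics cover
    samples up to and including it.
    """
    if len(trace.force) == 0:
        raise ValueError("cannot summarise an empty trace")
    over = trace.force > buckling_threshold
    if over.any():
        idx = int(np.argmax(over))
        buckled, abort_depth = True, float(trace.depth[idx])
        force = trace.force[:idx + 1]
        depth = trace.depth[:idx + 1]
    else:
        buckled, abort_depth = False, None
        force, depth = trace.force, trace.depth
    peak_idx = int(np.argmax(force))
    q25, med, q75 = np.percentile(force, [25, 50, 75])
    in_app = (float(depth[peak_idx]) <= exit_depth
              if exit_depth is not None else None)
    return ForceSummary(float(force[peak_idx]), float(med), float(q25),
                        float(q75), float(depth[peak_idx]), buckled,
                        abort_depth, in_app)


# ----------------------------------------------------------------------
# mean curves
# ----------------------------------------------------------------------

def mean_force_curves(traces: Sequence[ForceTrace],
                      grid_step: Optional[float] = None) -> MeanForceCurves:
    """Pointwise mean force-depth curve per channel radius.

    Traces are linearly resampled onto a common depth grid spanning the
    intersection of their depth ranges (ranges that differ are truncated
    with a warning).
    """
    if not traces:
        raise ValueError("no traces given")
    lo = max(float(t.depth.min()) for t in traces)
    hi = min(float(t.depth.max()) for t in traces)
    if hi <= lo:
        raise ValueError("traces have no common depth range")
    if (max(float(t.depth.max()) for t in traces) - hi > 1e-9 or
            lo - min(float(t.depth.min()) for t in traces) > 1e-9):
        log.warning("traces cover different depth ranges; truncating to "
                    "[%.1f, %.1f] mm", lo, hi)
    if grid_step is None:
        grid_step = float(np.median(np.diff(traces[0].depth)))
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    by_radius: Dict[float, List[np.ndarray]] = {}
    for t in traces:
        by_radius.setdefault(float(t.radius), []).append(
            np.interp(grid, t.depth, t.force))
    curves = {r: np.mean(fs, axis=0) for r, fs in sorted(by_radius.items())}
    peak_depths = {r: float(grid[int(np.argmax(f))]) for r, f in curves.items()}
    return MeanForceCurves(grid, curves, peak_depths)


# ----------------------------------------------------------------------
# two-way ANOVA
# ----------------------------------------------------------------------

def _check_cells(data: pd.DataFrame, response: str, factors):
    fa, fb = factors
    counts = data.groupby([fa, fb], observed=True)[response].count()
    levels_a = data[fa].unique()
    levels_b = data[fb].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    for a in levels_a:
        for b in levels_b:
            n = counts.get((a, b), 0)
            if n < 2:
                raise ValueError(
                    f"cell ({fa}={a}, {fb}={b}) has {n} observations; "
                    "need at least 2")
    return counts


def _balanced_anova(data, response, factors):
    fa, fb = factors
    y = data[response].to_numpy(dtype=float)
    mu = y.mean()
    n_total = len(y)
    cell = data.groupby([fa, fb], observed=True)[response]
    a_means = data.groupby(fa, observed=True)[response].mean()
    b_means = data.groupby(fb, observed=True)[response].mean()
    a_counts = data.groupby(fa, observed=True)[response].count()
    b_counts = data.groupby(fb, observed=True)[response].count()

    ss_a = float((a_counts * (a_means - mu) ** 2).sum())
    ss_b = float((b_counts * (b_means - mu) ** 2).sum())
    cell_means = cell.transform("mean").to_numpy(dtype=float)
    ss_e = float(((y - cell_means) ** 2).sum())
    ss_cells = float(((cell_means - mu) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b

    ka, kb = len(a_means), len(b_means)
    df_a, df_b = ka - 1, kb - 1
    df_ab = df_a * df_b
    df_e = n_total - ka * kb
    return (ss_a, df_a), (ss_b, df_b), (ss_ab, df_ab), (ss_e, df_e)


def _type2_anova(data, response, factors):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    d = data.rename(columns={response: "_y", fa: "_a", fb: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    rows = {"C(_a)": 0, "C(_b)": 1, "C(_a):C(_b)": 2, "Residual": 3}
    out = [None] * 4
    for name, i in rows.items():
        out[i] = (float(tab.loc[name, "sum_sq"]), float(tab.loc[name, "df"]))
    return tuple(out)


def two_way_anova(data: pd.DataFrame, response: str = "peak",
                  factors: Tuple[str, str] = ("radius", "tip"),
                  alpha: float = config.ALPHA) -> AnovaTable:
    """Fixed-effects two-factor ANOVA with interaction on a long table.

    Balanced designs use the classical sums-of-squares decomposition
    (SS_total = SS_A + SS_B + SS_AB + SS_E); unbalanced designs (e.g.
    after excluding buckled insertions) use Type II sums of squares via
    statsmodels.  p-values come from the F distribution.
    """
    counts = _check_cells(data, response, factors)
    balanced = counts.nunique() == 1
    if balanced:
        parts = _balanced_anova(data, response, factors)
    else:
        parts = _type2_anova(data, response, factors)
    (ss_a, df_a), (ss_b, df_b), (ss_ab, df_ab), (ss_e, df_e) = parts

    ms_e = ss_e / df_e
    rows = []
    for name, ss, df in [(factors[0], ss_a, df_a), (factors[1], ss_b, df_b),
                         (f"{factors[0]}:{factors[1]}", ss_ab, df_ab)]:
        ms = ss / df
        f = ms / ms_e if ms_e > 0 else np.inf
        p = float(stats.f.sf(f, df, df_e)) if np.isfinite(f) else 0.0
        if ss <= 1e-30 and ms_e <= 1e-30:
            f, p = 0.0, 1.0
        rows.append((name, ss, df, ms, f, p))
    rows.append(("residual", ss_e, df_e, ms_e, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["source", "sum_sq", "df",
                                        "mean_sq", "F", "p"]).set_index("source")
    return AnovaTable(table, alpha)


# ----------------------------------------------------------------------
# Tukey-Kramer
# ----------------------------------------------------------------------

def tukey_kramer(data: pd.DataFrame, anova: AnovaTable,
                 response: str = "peak", factor: str = "radius",
                 alpha: Optional[float] = None) -> pd.DataFrame:
    """All-pairs comparison of one factor's level means (studentized range).

    q = |m_i - m_j| / sqrt((MS_E / 2)(1/n_i + 1/n_j)); a pair is
    significant iff q exceeds the studentized-range critical value at
    (alpha, k levels, error df), computed numerically.  With equal group
    sizes this reduces to Tukey's HSD.
    """
    alpha = anova.alpha if alpha is None else alpha
    groups = data.groupby(factor, observed=True)[response]
    means = groups.mean()
    counts = groups.count()
    levels = list(means.index)
    k = len(levels)
    if k < 2:
        raise ValueError("factor needs at least 2 levels")
    ms_e, df_e = anova.residual_ms, anova.residual_df
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_e))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            li, lj = levels[i], levels[j]
            diff = float(means[li] - means[lj])
            se = np.sqrt((ms_e / 2.0) * (1.0 / counts[li] + 1.0 / counts[lj]))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_e))
            rows.append((li, lj, diff, float(q), q_crit, p, bool(q > q_crit)))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "diff", "q",
                                       "q_crit", "p", "significant"])


# ----------------------------------------------------------------------
# experiment design
# ----------------------------------------------------------------------

def randomize_design(radii: Sequence[float],
                     phantoms: int = config.N_PHANTOMS,
                     tips: Sequence[str] = config.TIP_TYPES,
                     reps: int = config.N_REPETITIONS,
                     *, seed: int) -> ExperimentDesign:
    """Randomised insertion order: the radius set permuted per phantom.

    Each phantom receives every radius once; phantoms map one-to-one onto
    the (tip, repetition) combinations, so ``phantoms`` must equal
    ``len(tips) * reps`` (10 = 2 x 5 by default).  Deterministic for a
    fixed seed.
    """
    if phantoms != len(tips) * reps:
        raise ValueError(f"phantoms ({phantoms}) must equal "
                         f"len(tips) * reps ({len(tips) * reps})")
    rng = np.random.default_rng(seed)
    radii = [float(r) for r in radii]
    rows = []
    for p in range(phantoms):
        tip = tips[p % len(tips)]
        rep = p // len(tips) + 1
        for r in rng.permutation(radii):
            rows.append((p + 1, float(r), tip, rep))
    table = pd.DataFrame(rows, columns=["phantom", "radius", "tip", "repetition"])
    return ExperimentDesign(table, seed)


# ----------------------------------------------------------------------
# trace files (delimited text)
# ----------------------------------------------------------------------

def write_force_trace(trace: ForceTrace, path) -> None:
    header = (f"# radius_mm={trace.radius:g} tip={trace.tip} "
              f"phantom={trace.phantom} repetition={trace.repetition} "
              f"speed_mm_s={trace.speed:g}\n"
              "depth_mm\tforce_N\n")
    body = "\n".join(f"{d:.9g}\t{f:.9g}"
                     for d, f in zip(trace.depth, trace.force))
    Path(path).write_text(header + body + "\n")


def read_force_trace(path) -> ForceTrace:
    meta = {"radius_mm": 0.0, "tip": "blunt", "phantom": 1,
            "repetition": 1, "speed_mm_s": config.INSERTION_SPEED}
    depth, force = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                key, _, val = tok.partition("=")
                if key in meta:
                    meta[key] = val
            continue
        if line.startswith("depth"):
            continue
        d, f = line.split()
        depth.append(float(d))
        force.append(float(f))
    return ForceTrace(np.asarray(depth), np.asarray(force),
                      float(meta["radius_mm"]), str(meta["tip"]),
                      int(meta["phantom"]), int(meta["repetition"]),
                      float(meta["speed_mm_s"]))


def analyse_experiment(traces: Sequence[ForceTrace],
                       kernel: int = config.FILTER_KERNEL,
                       threshold: float = config.BUCKLING_THRESHOLD,
                       exit_depth: Optional[float] = None,
                       alpha: float = config.ALPHA):
    """Full chain: filter, summarise, exclude buckled, ANOVA + Tukey-Kramer.

    Returns (summary table, AnovaTable, Tukey table, MeanForceCurves of
    the non-buckled traces).
    """
    rows, kept = [], []
    for t in traces:
        filt = zero_phase_ma(t, kernel)
        s = summarize(filt, threshold, exit_depth)
        rows.append((t.radius, t.tip, t.phantom, t.repetition, s.peak,
                     s.median, s.q25, s.q75, s.peak_depth, s.buckled,
                     s.abort_depth))
        if not s.buckled:
            kept.append(filt)
    summary = pd.DataFrame(rows, columns=["radius", "tip", "phantom",
                                          "repetition", "peak", "median",
                                          "q25", "q75", "peak_depth",
                                          "buckled", "abort_depth"])
    ok = summary[~summary.buckled]
    # a radius level whose buckling exclusions leave any (radius, tip) cell
    # with fewer than 2 insertions cannot enter the factorial analysis
    cell_min = ok.groupby("radius").apply(
        lambda g: g.groupby("tip").peak.count().reindex(
            summary.tip.unique()).fillna(0).min(),
        include_groups=False)
    keep_radii = cell_min[cell_min >= 2].index
    dropped = sorted(set(ok.radius.unique()) - set(keep_radii))
    if dropped:
        log.warning("radius levels %s dropped from the ANOVA: too few "
                    "non-buckled insertions", dropped)
    ok = ok[ok.radius.isin(keep_radii)]
    anova = two_way_anova(ok, "peak", ("radius", "tip"), alpha)
    tukey = tukey_kramer(ok, anova, "peak", "radius")
    curves = mean_force_curves(kept)
    return summary, anova, tukey, curves
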