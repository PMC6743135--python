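"""Zero-phase filter, summaries, buckling, ANOVA, Tukey-Kramer, design."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import brachyform as bf
from brachyform.force_analysis import (ForceTrace, randomize_design, summarize,
                                       tukey_kramer, two_way_anova,
                                       zero_phase_ma)


def make_trace(force, radius=50.0, step=0.1, **meta):
    force = np.asarray(force, dtype=float)
    return ForceTrace(np.arange(len(force)) * step, force, radius, **meta)


class TestZeroPhaseFilter:
    def test_constant_signal_unchanged(self):
        out = zero_phase_ma(make_trace(np.full(200, 3.7)), kernel=20)
        np.testing.assert_allclose(out.force, 3.7, atol=1e-12)

    def test_impulse_response_symmetric(self):
        x = np.zeros(301)
        x[150] = 1.0
        out = zero_phase_ma(make_trace(x), kernel=20).force
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)
        assert np.argmax(out) == 150

    def test_sinusoid_gain_squared_ma_response(self):
        # single-pass MA gain at frequency f: |sin(pi f k) / (k sin(pi f))|;
        # forward-backward filtering squares it
        k, period, n = 20, 40.0, 4000
        f = 1.0 / period
        x = np.sin(2 * np.pi * f * np.arange(n))
        out = zero_phase_ma(make_trace(x), kernel=k).force
        gain = np.abs(np.sin(np.pi * f * k) / (k * np.sin(np.pi * f))) ** 2
        core = slice(500, n - 500)
        amp = np.sqrt(2 * np.mean(out[core] ** 2))
        assert amp == pytest.approx(gain, abs=1e-6)

    def test_zero_lag_cross_correlation(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.normal(size=800))
        out = zero_phase_ma(make_trace(x), kernel=20).force
        xc = np.correlate(x - x.mean(), out - out.mean(), mode="full")
        assert np.argmax(xc) == len(x) - 1           # lag 0

    def test_linearity_and_shift_invariance_interior(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=500), rng.normal(size=500)
        fa = zero_phase_ma(make_trace(a), 20).force
        fb = zero_phase_ma(make_trace(b), 20).force
        fab = zero_phase_ma(make_trace(2 * a + 3 * b), 20).force
        core = slice(50, 450)
        np.testing.assert_allclose(fab[core], (2 * fa + 3 * fb)[core],
                                   atol=1e-9)
        shifted = zero_phase_ma(make_trace(np.roll(a, 7)), 20).force
        np.testing.assert_allclose(shifted[57:443], fa[50:436], atol=1e-9)

    def test_kernel_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            zero_phase_ma(make_trace(np.zeros(10)), kernel=20)


class TestSummarize:
    @staticmethod
    def triangle(peak, n=401, step=0.25):
        half = np.linspace(0.0, peak, n // 2 + 1)
        return make_trace(np.r_[half, half[-2::-1]], step=step)

    def test_peak_below_threshold_not_buckled(self):
        s = summarize(self.triangle(13.0))
        assert not s.buckled and s.abort_depth is None
        assert s.peak == pytest.approx(13.0)
        assert s.q25 <= s.median <= s.q75 <= s.peak

    def test_crossing_threshold_buckles_at_first_crossing(self):
        t = self.triangle(15.0)
        s = summarize(t)
        assert s.buckled
        crossing = t.depth[np.argmax(t.force > 14.0)]
        assert s.abort_depth == pytest.approx(crossing)
        # statistics only cover samples up to the abort
        assert s.peak <= t.force[t.depth <= s.abort_depth].max() + 1e-12

    def test_decision_boundary_at_14N_by_bisection(self):
        lo, hi = 10.0, 20.0
        for _ in range(40):
            mid = (lo + hi) / 2
            if summarize(self.triangle(mid)).buckled:
                hi = mid
            else:
                lo = mid
        assert (lo + hi) / 2 == pytest.approx(14.0, abs=0.01)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            summarize(make_trace(np.empty(0)))


class TestMeanCurves:
    def test_identical_traces_mean_is_the_trace(self):
        t = bf.synth_force_trace(55.0, params=bf.ForceModelParams(noise_sd=0))
        curves = bf.mean_force_curves([t, t, t])
        np.testing.assert_allclose(curves.curves[55.0],
                                   np.interp(curves.depth, t.depth, t.force),
                                   atol=1e-9)

    def test_peak_force_decreases_with_radius(self):
        params = bf.ForceModelParams(noise_sd=0)
        traces = [bf.synth_force_trace(r, params=params)
                  for r in (35.0, 45.0, 55.0, 65.0, 75.0)]
        curves = bf.mean_force_curves(traces)
        peaks = [curves.curves[r].max() for r in (35.0, 45.0, 55.0, 65.0, 75.0)]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_peak_depth_at_applicator_exit(self):
        t = bf.synth_force_trace(55.0, params=bf.ForceModelParams(noise_sd=0))
        curves = bf.mean_force_curves([t])
        assert curves.peak_depths[55.0] == pytest.approx(50.0, abs=1.0)

    def test_mismatched_ranges_truncated_with_warning(self, caplog):
        a = make_trace(np.ones(100), radius=40.0)
        b = ForceTrace(np.arange(50) * 0.1 + 2.0, np.ones(50), 50.0)
        with caplog.at_level("WARNING"):
            curves = bf.mean_force_curves([a, b])
        assert any("truncating" in r.message for r in caplog.records)
        assert curves.depth.min() >= 2.0 - 1e-9


class TestAnova:
    @staticmethod
    def small_balanced(jitter=0.1):
        rows = []
        rng = np.random.default_rng(11)
        for a, base in (("A1", 1.0), ("A2", 3.0)):
            for b in ("B1", "B2"):
                for _ in range(2):
                    rows.append((a, b, base + rng.uniform(-jitter, jitter)))
        return pd.DataFrame(rows, columns=["radius", "tip", "peak"])

    def test_matches_direct_sum_of_squares(self):
        # brute-force oracle: explicit cell/margin mean decomposition
        df = self.small_balanced()
        y = df.peak.to_numpy()
        mu = y.mean()
        a_mean = df.groupby("radius").peak.mean()
        b_mean = df.groupby("tip").peak.mean()
        cell = df.groupby(["radius", "tip"]).peak.transform("mean").to_numpy()
        ss_a = 4 * ((a_mean - mu) ** 2).sum()
        ss_b = 4 * ((b_mean - mu) ** 2).sum()
        ss_e = ((y - cell) ** 2).sum()
        ss_ab = ((cell - mu) ** 2).sum() - ss_a - ss_b
        table = two_way_anova(df).table
        assert table.loc["radius", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert table.loc["tip", "sum_sq"] == pytest.approx(ss_b, abs=1e-9)
        assert table.loc["radius:tip", "sum_sq"] == pytest.approx(ss_ab,
                                                                  abs=1e-9)
        f_a = (ss_a / 1) / (ss_e / 4)
        assert table.loc["radius", "F"] == pytest.approx(f_a, abs=1e-9)
        assert table.loc["radius", "p"] == pytest.approx(
            stats.f.sf(f_a, 1, 4), abs=1e-12)

    def test_balanced_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = self.small_balanced()
        mine = two_way_anova(df).table
        ref = sm.stats.anova_lm(
            smf.ols("peak ~ C(radius) * C(tip)", data=df).fit(), typ=2)
        assert mine.loc["radius", "sum_sq"] == pytest.approx(
            ref.loc["C(radius)", "sum_sq"], rel=1e-9)
        assert mine.loc["radius:tip", "F"] == pytest.approx(
            ref.loc["C(radius):C(tip)", "F"], rel=1e-9)

    def test_all_equal_observations_give_zero_ss(self):
        rows = [(a, b, 5.0) for a in "xy" for b in "uv" for _ in range(3)]
        table = two_way_anova(pd.DataFrame(
            rows, columns=["radius", "tip", "peak"])).table
        for src in ("radius", "tip", "radius:tip"):
            assert table.loc[src, "sum_sq"] == pytest.approx(0.0, abs=1e-20)

    def test_total_ss_decomposition_and_df_sum(self):
        rng = np.random.default_rng(3)
        rows = [(a, b, rng.normal()) for a in "pqr" for b in "uv"
                for _ in range(4)]
        df = pd.DataFrame(rows, columns=["radius", "tip", "peak"])
        table = two_way_anova(df).table
        total = ((df.peak - df.peak.mean()) ** 2).sum()
        assert table.sum_sq.sum() == pytest.approx(total, rel=1e-9)
        assert table.df.sum() == len(df) - 1

    def test_permutation_of_rows_leaves_table_unchanged(self):
        df = self.small_balanced()
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        pd.testing.assert_frame_equal(two_way_anova(df).table,
                                      two_way_anova(shuffled).table)

    def test_monte_carlo_type_I_rate(self):
        # null model: equal means everywhere, alpha = 0.05
        rng = np.random.default_rng(20)
        reps = 1000
        rejections = np.zeros(3)
        radius = np.repeat(["a", "b"], 10)
        tip = np.tile(np.repeat(["u", "v"], 5), 2)
        for _ in range(reps):
            df = pd.DataFrame({"radius": radius, "tip": tip,
                               "peak": rng.normal(size=20)})
            an = two_way_anova(df)
            rejections += [an.significant("radius"), an.significant("tip"),
                           an.significant("radius:tip")]
        for rate in rejections / reps:
            assert 0.03 <= rate <= 0.07

    def test_empty_cell_rejected_naming_cell(self):
        df = self.small_balanced()
        df = df[~((df.radius == "A2") & (df.tip == "B2"))]
        with pytest.raises(ValueError, match="A2"):
            two_way_anova(df)

    def test_unbalanced_type2_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        rows = [(a, b, rng.normal(loc=float(a == "p")))
                for a in "pq" for b in "uv" for _ in range(4)]
        rows += [("p", "u", rng.normal(loc=1.0)) for _ in range(3)]
        df = pd.DataFrame(rows, columns=["radius", "tip", "peak"])
        mine = two_way_anova(df).table
        ref = sm.stats.anova_lm(
            smf.ols("peak ~ C(radius) * C(tip)", data=df).fit(), typ=2)
        assert mine.loc["radius", "sum_sq"] == pytest.approx(
            ref.loc["C(radius)", "sum_sq"], rel=1e-9)


class TestTukeyKramer:
    @staticmethod
    def three_groups(shift=0.0):
        rng = np.random.default_rng(15)
        rows = []
        for g, mean in (("g1", 0.0), ("g2", shift), ("g3", 2 * shift)):
            for b in ("u", "v"):
                for _ in range(4):
                    rows.append((g, b, rng.normal(mean, 0.5)))
        return pd.DataFrame(rows, columns=["radius", "tip", "peak"])

    def test_identical_means_not_significant(self):
        df = self.three_groups(0.0)
        anova = two_way_anova(df)
        out = tukey_kramer(df, anova)
        assert not out.significant.any()

    def test_equal_n_reduces_to_tukey_hsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = self.three_groups(1.5)
        anova = two_way_anova(df)
        mine = tukey_kramer(df, anova)
        # independent HSD: statsmodels uses the one-way MS_E; rebuild the
        # comparison with the same error term for an exact reduction check
        groups = df.groupby("radius").peak
        k, n = 3, 8
        ss_e = sum(((g - g.mean()) ** 2).sum() for _, g in groups)
        df_e = len(df) - k
        ref = pairwise_tukeyhsd(df.peak, df.radius, alpha=0.05)
        q_mine = mine.q.to_numpy()
        diffs = mine["diff"].abs().to_numpy()
        q_ref = np.abs(ref.meandiffs) / np.sqrt(ss_e / df_e / n)
        np.testing.assert_allclose(np.sort(diffs),
                                   np.sort(np.abs(ref.meandiffs)), atol=1e-9)
        q_expected = diffs / np.sqrt(anova.residual_ms / n)
        np.testing.assert_allclose(q_mine, q_expected, atol=1e-9)

    def test_monotone_in_mean_difference(self):
        base = self.three_groups(0.5)
        anova = two_way_anova(base)
        q_small = tukey_kramer(base, anova).set_index(["level_a", "level_b"]).q
        grown = base.copy()
        grown.loc[grown.radius == "g3", "peak"] += 2.0
        q_big = tukey_kramer(grown, two_way_anova(grown)).set_index(
            ["level_a", "level_b"]).q
        assert q_big["g1", "g3"] > q_small["g1", "g3"]

    def test_critical_value_matches_distribution(self):
        df = self.three_groups(1.0)
        anova = two_way_anova(df)
        out = tukey_kramer(df, anova)
        expected = stats.studentized_range.ppf(0.95, 3, anova.residual_df)
        assert out.q_crit.unique()[0] == pytest.approx(expected, abs=1e-4)


class TestDesign:
    def test_deterministic_for_fixed_seed(self):
        radii = [float(r) for r in range(20, 80, 5)]
        a = randomize_design(radii, seed=7)
        b = randomize_design(radii, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_each_phantom_gets_a_permutation(self):
        radii = [float(r) for r in range(20, 80, 5)]
        design = randomize_design(radii, seed=7)
        for _, grp in design.table.groupby("phantom"):
            assert sorted(grp.radius) == sorted(radii)

    def test_counts_match_phantoms_tips_reps(self):
        radii = [35.0, 55.0, 75.0]
        design = randomize_design(radii, seed=1)
        assert len(design.table) == 10 * len(radii)
        counts = design.table.groupby(["tip", "repetition"]).phantom.nunique()
        assert (counts == 1).all() and len(counts) == 10

    def test_different_seeds_differ(self):
        radii = [float(r) for r in range(20, 80, 5)]
        a = randomize_design(radii, seed=1).table.radius.to_numpy()
        b = randomize_design(radii, seed=2).table.radius.to_numpy()
        assert not np.array_equal(a, b)

    def test_mismatched_phantom_count_rejected(self):
        with pytest.raises(ValueError):
            randomize_design([35.0, 55.0], phantoms=7, seed=0)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        t = bf.synth_force_trace(45.0, "sharp",
                                 bf.ForceModelParams(noise_sd=0.1, seed=2),
                                 phantom=3, repetition=2)
        path = tmp_path / "trace.txt"
        bf.write_force_trace(t, path)
        back = bf.read_force_trace(path)
        assert (back.radius, back.tip, back.phantom, back.repetition) == \
            (45.0, "sharp", 3, 2)
        np.testing.assert_allclose(back.force, t.force, atol=1e-6)
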