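"""Fate classification, anaphase alignment, phase calling, duration
summaries, dose-response fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktrcycle import simulate
from ktrcycle.benchmarks import brute_force_fate
from ktrcycle.cycle_metrics import (ClassificationRule, align_to_anaphase,
                                    annotate_phases, call_phases,
                                    classify_fate, duration_stats,
                                    ic50_from_sphase, _four_pl)

RULE = ClassificationRule()
T48 = np.arange(0.0, 48.01, 0.2)


def _const_trace(level):
    return np.full(T48.size, level)


class TestClassifyFate:
    def test_sustained_inside_window_is_proliferating(self):
        a = np.full(T48.size, 0.5)
        a[(T48 >= 32) & (T48 <= 40)] = 1.2
        assert classify_fate(T48, a, RULE) == "proliferating"

    def test_activity_outside_window_is_quiescent(self):
        a = np.full(T48.size, 0.5)
        a[(T48 >= 10) & (T48 <= 20)] = 1.2
        assert classify_fate(T48, a, RULE) == "quiescent"

    def test_short_burst_not_sustained(self):
        a = np.full(T48.size, 0.5)
        a[(T48 >= 35) & (T48 <= 36.5)] = 1.5  # 1.5 h < 2 h
        assert classify_fate(T48, a, RULE) == "quiescent"

    def test_single_subthreshold_frame_breaks_run(self):
        a = np.full(T48.size, 1.5)
        a[T48 < 30] = 0.5
        # poke holes every 1.8 h inside the window so no run exceeds 2 h
        for t0 in np.arange(30.0, 48.1, 1.8):
            a[np.argmin(np.abs(T48 - t0))] = 0.9
        assert classify_fate(T48, a, RULE) == "quiescent"

    def test_window_not_covered_unclassified(self):
        t = np.arange(0.0, 40.0, 0.2)
        assert classify_fate(t, np.full(t.size, 2.0), RULE) == "unclassified"

    def test_gap_filled_frames_need_flanking_support(self):
        # activity only on [34, 36.4] h (2.6 h), one gap-filled frame at 35
        a = np.full(T48.size, 0.5)
        a[(T48 >= 34.0) & (T48 <= 36.4)] = 1.5
        gf = np.zeros(T48.size, dtype=bool)
        i = np.argmin(np.abs(T48 - 35.0))
        a[i] = np.nan
        gf[i] = True
        assert classify_fate(T48, a, RULE, gap_filled=gf) == "proliferating"
        # same gap with a sub-threshold measured neighbour: run breaks into
        # two sub-2 h pieces
        a2 = a.copy()
        a2[i + 1] = 0.5
        assert classify_fate(T48, a2, RULE, gap_filled=gf) == "quiescent"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nseg = rng.integers(1, 12)
        cuts = (np.sort(rng.choice(np.arange(1, T48.size), nseg - 1, replace=False))
                if nseg > 1 else np.array([], int))
        vals = rng.uniform(0.2, 2.0, nseg)
        a = np.empty(T48.size)
        start = 0
        for k, b in enumerate(list(cuts) + [T48.size]):
            a[start:b] = vals[k]
            start = b
        assert classify_fate(T48, a, RULE) == brute_force_fate(T48, a, RULE)

    def test_raising_threshold_monotone(self):
        """A higher activity threshold can only demote cells."""
        rng = np.random.default_rng(10)
        for _ in range(50):
            a = rng.uniform(0.2, 2.0, T48.size)
            lo = classify_fate(T48, a, ClassificationRule(activity_threshold=1.0))
            hi = classify_fate(T48, a, ClassificationRule(activity_threshold=1.3))
            assert not (lo == "quiescent" and hi == "proliferating")


class TestAlignment:
    def test_time_arithmetic(self):
        traces = pd.DataFrame({"cell_id": [7] * 3, "frame": [40, 45, 50],
                               "time_h": [8.0, 9.0, 10.0]})
        out = align_to_anaphase(traces, {7: 8.0})
        assert list(out.t_since_anaphase_h) == [0.0, 1.0, 2.0]

    def test_cells_without_anaphase_excluded(self):
        traces = pd.DataFrame({"cell_id": [1, 2], "frame": [0, 0],
                               "time_h": [0.0, 0.0]})
        out = align_to_anaphase(traces, {1: 0.0})
        assert set(out.cell_id) == {1}

    def test_cohort_mean_crosses_threshold_at_g1s(self):
        """Aligned mean CDK2 of a cohort crosses 1 near the generator's mean
        G1 length (CDK2 reaches 1 just before G1/S by construction)."""
        cfg = simulate.SimConfig(n_cells=150, duration_hours=40,
                                 proliferating_fraction=1.0, g1_cv=0.1,
                                 rng_seed=15)
        traces, truth = simulate.simulate_traces(cfg)
        born = truth.cells[(truth.cells.birth_h >= 0)
                           & (truth.cells.birth_h < 20)]
        ana = born.set_index("cell_id").birth_h
        aligned = align_to_anaphase(traces, ana)
        aligned["bin"] = (aligned.t_since_anaphase_h // cfg.dt_h).astype(int)
        mean_tr = aligned.groupby("bin").cdk2.mean()
        mean_tr = mean_tr[mean_tr.index >= 0]
        crossing = mean_tr[mean_tr > 1.0]
        assert len(crossing) > 0
        t_cross = crossing.index[0] * cfg.dt_h
        # generator: crossing at 0.95 * G1; mean G1 is 10 h
        assert t_cross == pytest.approx(0.95 * cfg.g1_mean_h, abs=1.0)


class TestCallPhases:
    def test_canonical_noiseless_boundaries(self):
        """High 0-6 h, fall 6-7 h, low 7-14 h, rise 14-16 h: boundaries at
        6 h and 14 h within one frame."""
        t = np.arange(0, 16.01, 0.2)
        d = np.piecewise(
            t,
            [t < 6, (t >= 6) & (t < 7), (t >= 7) & (t < 14), t >= 14],
            [1000.0, lambda x: 1000 - 940 * (x - 6), 60.0,
             lambda x: 60 + 270 * (x - 14)])
        g1s, sg2 = call_phases(t, d, "cdt1")
        assert g1s == pytest.approx(6.0, abs=0.21)
        assert sg2 == pytest.approx(14.0, abs=0.21)

    def test_flat_trace_no_boundaries(self):
        t = np.arange(0, 20, 0.2)
        rng = np.random.default_rng(0)
        g1s, sg2 = call_phases(t, 800 + rng.normal(0, 10, t.size), "cdt1")
        assert g1s is None and sg2 is None

    def test_geminin_onset(self):
        t = np.arange(0, 20.01, 0.2)
        d = np.where(t < 8, 50.0, 50.0 + 60.0 * (t - 8))
        g1s, sg2 = call_phases(t, d, "geminin")
        assert g1s == pytest.approx(8.0, abs=0.4)
        assert sg2 is None

    def test_boundary_recovery_on_simulated_cohort(self):
        """Default-noise traces: both boundaries within 2 frames for >= 90%
        of cells; annotated durations are additive by construction."""
        from ktrcycle.benchmarks import phase_benchmark

        out = phase_benchmark(seed=3, n_cells=40)
        assert out["n"] >= 80
        assert out["g1s_within2_pct"] >= 90.0
        assert out["sg2_within2_pct"] >= 90.0
        assert out["additivity_pct"] == 100.0


class TestAnnotateAndStats:
    def test_annotation_durations_additive(self):
        cfg = simulate.SimConfig(n_cells=30, duration_hours=55,
                                 proliferating_fraction=1.0, rng_seed=19)
        traces, truth = simulate.simulate_traces(cfg)
        obs = truth.cells[(truth.cells.birth_h >= 0)
                          & np.isfinite(truth.cells.division_h)
                          & (truth.cells.division_h < cfg.duration_hours)]
        ana = obs.set_index("cell_id").birth_h.to_dict()
        div = obs.set_index("cell_id").division_h.to_dict()
        ann = annotate_phases(traces, ana, division_times=div)
        full = ann.dropna(subset=["g1_h", "s_h", "g2m_h", "imt_h"])
        assert len(full) > 10
        np.testing.assert_allclose(full.g1_h + full.s_h + full.g2m_h,
                                   full.imt_h, atol=cfg.dt_h)
        # ordering invariant
        assert (full.anaphase_time_h < full.g1s_time_h).all()
        assert (full.g1s_time_h < full.sg2_time_h).all()
        assert (full.sg2_time_h < full.next_anaphase_time_h).all()

    def test_duration_stats_basic(self):
        ann = pd.DataFrame({"g1_h": [10.0, 12.0, 14.0], "group": "a"})
        out = duration_stats(ann, metrics=("g1_h",))
        row = out.iloc[0]
        assert row["mean"] == 12.0 and row["median"] == 12.0 and row.n == 3

    def test_single_cell_ci_undefined(self):
        ann = pd.DataFrame({"imt_h": [20.0], "group": "solo"})
        out = duration_stats(ann, metrics=("imt_h",))
        assert np.isnan(out.iloc[0].ci95_lo)

    def test_group_mean_ratio_recovery(self):
        """Two simulated groups with true G1 means 6 h and 18 h: estimated
        ratio ~= 3 at n = 300/group."""
        g1a = simulate._draw_lognormal(np.random.default_rng(1), 6.0, 0.3, 300)
        g1b = simulate._draw_lognormal(np.random.default_rng(2), 18.0, 0.3, 300)
        ann = pd.DataFrame({"g1_h": np.concatenate([g1a, g1b]),
                            "group": ["a"] * 300 + ["b"] * 300})
        out = duration_stats(ann, metrics=("g1_h",)).set_index("group")
        ratio = out.loc["b", "mean"] / out.loc["a", "mean"]
        assert ratio == pytest.approx(3.0, rel=0.12)


class TestIC50:
    DOSES = np.array([0.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])

    def test_exact_samples_recovered(self):
        rel = _four_pl(self.DOSES, 1.0, 0.05, 120.0, 1.2)
        fit = ic50_from_sphase(self.DOSES, rel * 0.3, 0.3)
        assert fit["ic50"] == pytest.approx(120.0, rel=1e-3)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(5)
        rel = _four_pl(self.DOSES, 1.0, 0.05, 120.0, 1.2)
        noisy = rel * 0.3 * (1 + rng.normal(0, 0.02, rel.size))
        fit = ic50_from_sphase(self.DOSES, noisy, 0.3)
        assert fit["ic50"] == pytest.approx(120.0, rel=0.1)

    def test_flat_response_rejected(self):
        with pytest.raises(ValueError, match="no inhibition"):
            ic50_from_sphase(self.DOSES, np.full(7, 0.3), 0.3)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            ic50_from_sphase([0, 10, 100], [0.3, 0.2, 0.1], 0.3)
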