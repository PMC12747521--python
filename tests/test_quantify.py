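"""KTR ratios, bleed-through correction, fixed-cell classifiers, FISH
puncta counting."""

import numpy as np
import pandas as pd
import pytest

from ktrcycle import simulate
from ktrcycle.quantify import (classify_edu, classify_prb, correct_cdk46,
                               count_fish_puncta, fit_bleedthrough, ktr_ratio,
                               measure_fixed_field, valley_threshold)


class TestKtrRatio:
    @pytest.mark.parametrize("ring,nuc,expect", [
        (200.0, 100.0, 2.0),
        (100.0, 100.0, 1.0),
        (30.0, 60.0, 0.5),
    ])
    def test_arithmetic(self, ring, nuc, expect):
        assert ktr_ratio(nuc, ring) == pytest.approx(expect)

    def test_low_signal_and_flags_missing(self):
        assert np.isnan(ktr_ratio(5.0, 50.0, floor=10.0))
        assert np.isnan(ktr_ratio(-3.0, 50.0))
        assert np.isnan(ktr_ratio(100.0, 50.0, invalid=True))
        out = ktr_ratio(np.array([100.0, 100.0]), np.array([50.0, 50.0]),
                        invalid=np.array([False, True]))
        assert out[0] == pytest.approx(0.5)
        assert np.isnan(out[1])

    def test_scale_invariance(self):
        """Multiplying both medians by any positive constant leaves the
        ratio unchanged."""
        rng = np.random.default_rng(0)
        nuc = rng.uniform(50, 500, 20)
        ring = rng.uniform(10, 800, 20)
        for k in (0.2, 3.0, 117.0):
            np.testing.assert_allclose(ktr_ratio(k * nuc, k * ring),
                                       ktr_ratio(nuc, ring), rtol=1e-12)


class TestCorrectCdk46:
    def test_printed_formula(self):
        assert correct_cdk46(0.8, 1.0, 0.41) == pytest.approx(0.39)
        assert correct_cdk46(0.8, 0.0, 0.41) == pytest.approx(0.8)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        r1, c1 = rng.uniform(0, 2, 50), rng.uniform(0, 2, 50)
        r2, c2 = rng.uniform(0, 2, 50), rng.uniform(0, 2, 50)
        lhs = correct_cdk46(r1 + r2, c1 + c2, 0.41)
        rhs = correct_cdk46(r1, c1, 0.41) + correct_cdk46(r2, c2, 0.41)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_nan_propagates(self):
        out = correct_cdk46(np.array([0.8, np.nan]), np.array([1.0, 1.0]))
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestBleedthrough:
    def test_alpha_recovery(self):
        cfg = simulate.SimConfig(n_cells=50, duration_hours=48,
                                 cdk46_suppressed=True, rng_seed=31)
        traces, _ = simulate.simulate_traces(cfg)
        a, se = fit_bleedthrough(traces)
        assert a == pytest.approx(0.41, abs=0.02)

    def test_null_alpha(self):
        cfg = simulate.SimConfig(n_cells=50, duration_hours=48,
                                 cdk46_suppressed=True, cdk2_bleed_alpha=0.0,
                                 rng_seed=32)
        traces, _ = simulate.simulate_traces(cfg)
        a, _ = fit_bleedthrough(traces)
        assert a == pytest.approx(0.0, abs=0.02)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"cdk46_raw": np.random.default_rng(0).normal(size=100),
                           "cdk2": np.ones(100)})
        with pytest.raises(ValueError):
            fit_bleedthrough(df)

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"cdk46_raw": [1.0] * 10, "cdk2": range(10)})
        with pytest.raises(ValueError):
            fit_bleedthrough(df)

    def test_corrected_trace_flat_when_cdk46_off(self):
        """CDK4/6i-saturated cells: raw sensor rises with CDK2 in S/G2, the
        alpha-corrected trace stays near zero."""
        cfg = simulate.SimConfig(n_cells=40, duration_hours=48,
                                 cdk46_suppressed=True, rng_seed=33)
        traces, truth = simulate.simulate_traces(cfg)
        tr = traces.merge(truth.cells[["cell_id", "g1s_h", "division_h"]],
                          on="cell_id")
        sg2 = tr[(tr.time_h >= tr.g1s_h) & (tr.time_h < tr.division_h)]
        counts = sg2.groupby("cell_id").size()
        sg2 = sg2[sg2.cell_id.isin(counts[counts >= 10].index)]
        assert len(sg2) > 100
        corrected = correct_cdk46(sg2.cdk46_raw, sg2.cdk2, 0.41)
        per_cell = pd.Series(np.asarray(corrected),
                             index=sg2.index).groupby(sg2.cell_id.values).mean()
        assert per_cell.abs().max() <= 0.05
        assert sg2.cdk46_raw.mean() > 0.4  # raw tracks CDK2


class TestClassifiers:
    def _bimodal(self, rng, n, frac, lo=(2.0, 0.1), hi=(3.5, 0.15)):
        pos = rng.random(n) < frac
        logv = np.where(pos, rng.normal(*hi, n), rng.normal(*lo, n))
        return pd.DataFrame({"edu": 10.0 ** logv, "true": pos})

    def test_valley_between_modes_and_accuracy(self):
        rng = np.random.default_rng(2)
        df = self._bimodal(rng, 1000, 0.5)
        out = classify_edu(df)
        thr = out.attrs["edu_threshold"]
        assert 10**2.0 < thr < 10**3.5
        acc = (out.edu_positive == out.true).mean()
        assert acc >= 0.99

    def test_positive_fraction_binomial(self):
        rng = np.random.default_rng(3)
        df = self._bimodal(rng, 1000, 0.5)
        out = classify_edu(df)
        assert out.edu_positive.mean() == pytest.approx(0.5, abs=0.04)

    def test_manual_threshold_and_all_negative(self):
        rng = np.random.default_rng(4)
        df = self._bimodal(rng, 300, 0.0)
        out = classify_edu(df, threshold=10.0**3.0)
        assert out.edu_positive.sum() == 0

    def test_unimodal_rejected(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"edu": 10 ** rng.normal(2.0, 0.1, 500)})
        with pytest.raises(ValueError):
            classify_edu(df)

    def test_prb_ratio_classification(self):
        rng = np.random.default_rng(6)
        n = 600
        pos = rng.random(n) < 0.5
        trb = 500 * rng.uniform(0.8, 1.2, n)
        ratio = 10 ** np.where(pos, rng.normal(-0.1, 0.15, n),
                               rng.normal(-1.3, 0.15, n))
        df = pd.DataFrame({"prb": trb * ratio, "trb": trb, "true": pos})
        out = classify_prb(df)
        assert (out.prb_positive == out.true).mean() >= 0.99

    def test_prb_zero_trb_excluded(self):
        rng = np.random.default_rng(7)
        n = 250
        pos = rng.random(n) < 0.5
        trb = 500 * np.ones(n)
        trb[0] = 0.0
        ratio = 10 ** np.where(pos, rng.normal(-0.1, 0.1, n), rng.normal(-1.1, 0.1, n))
        df = pd.DataFrame({"prb": trb * ratio, "trb": trb})
        out = classify_prb(df)
        assert bool(out.excluded.iloc[0])
        assert out.exclude_reason.iloc[0] == "low_trb"
        assert not out.prb_positive.iloc[0]

    def test_valley_threshold_unimodal_raises(self):
        with pytest.raises(ValueError):
            valley_threshold(10 ** np.random.default_rng(8).normal(2, 0.1, 400))


class TestFishPuncta:
    def test_known_counts_recovered(self, fixed_field):
        stack, truth = fixed_field
        rec = measure_fixed_field(stack)
        assert len(rec) == len(truth.cells)
        got = []
        for r in rec.itertuples():
            j = np.hypot(truth.cells.x_um - r.x_um,
                         truth.cells.y_um - r.y_um).idxmin()
            got.append((int(truth.cells.loc[j, "fish_count"]), int(r.fish_puncta)))
        assert all(a == b for a, b in got)

    def test_zero_puncta_field(self):
        stack, truth = simulate.render_fixed_field(
            n_cells=4, puncta_per_cell=0, prb_positive_fraction=0.5,
            edu_positive_fraction=0.5, seed=41)
        rec = measure_fixed_field(stack)
        assert (rec.fish_puncta == 0).all()

    def test_offset_invariance(self, fixed_field):
        """Adding a constant to the FISH frame does not change counts: the
        top-hat removes any offset."""
        from ktrcycle.segment import segment_fixed

        stack, truth = fixed_field
        fish = stack.frame(0, "fish")
        nuclei = segment_fixed(stack.frame(0, "hoechst"), stack.pixel_size_um)
        base = count_fish_puncta(fish, nuclei, stack.pixel_size_um)
        shifted = count_fish_puncta(fish + 137.0, nuclei, stack.pixel_size_um)
        pd.testing.assert_series_equal(base.fish_puncta, shifted.fish_puncta)

    def test_close_cells_excluded_overlap_neighbor(self):
        """Two cells 60 um apart: their 50-um dilation zones overlap, so both
        are excluded (edge-to-edge < 100 um by geometry)."""
        stack, truth = simulate.render_fixed_field(
            n_cells=2, puncta_per_cell=3, prb_positive_fraction=0.5,
            edu_positive_fraction=0.5, seed=42, spacing_um=60.0)
        d = np.hypot(np.diff(truth.cells.x_um), np.diff(truth.cells.y_um))[0]
        assert d < 100
        rec = measure_fixed_field(stack)
        assert rec.excluded.all()
        assert (rec.exclude_reason == "overlap_neighbor").all()

    def test_kernel_larger_than_image_rejected(self):
        from ktrcycle.io import LabelMap

        with pytest.raises(ValueError):
            count_fish_puncta(np.zeros((20, 20)),
                              LabelMap(np.zeros((20, 20), dtype=np.int32)),
                              pixel_size_um=1.0, kernel_um=100.0)
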