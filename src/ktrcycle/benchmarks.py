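"""Self-contained validation benchmarks on synthetic data.

Each function generates its own ground-truthed inputs with the package's
synthetic-data module, runs the relevant pipeline stage(s), and returns the
measured quantities as a flat dict.  The test suite asserts tolerances on
these numbers; ``scripts/acceptance.py`` re-computes and reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cycle_metrics, evaluate, pipeline, quantify, segment, simulate

__all__ = [
    "classification_benchmark",
    "bleedthrough_benchmark",
    "ratio_benchmark",
    "tracking_benchmark",
    "phase_benchmark",
    "end_to_end_benchmark",
    "fixed_cell_benchmark",
    "ic50_benchmark",
]


def brute_force_fate(time_h, cdk2, rule: cycle_metrics.ClassificationRule) -> str:
    """Exhaustive contiguous-run scan of the sustained-CDK2 rule.

    Checks every contiguous window of in-window frames for all-above-threshold
    occupancy; independent of the incremental run-length implementation.
    """
    t = np.asarray(time_h, dtype=float)
    a = np.asarray(cdk2, dtype=float)
    lo, hi = rule.window_h
    if t.size < 2 or t.min() > lo + 1e-9 or t.max() < hi - 1e-9:
        return "unclassified"
    dt = np.median(np.diff(t))
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    above = (a[sel] > rule.activity_threshold).astype(int)
    n = above.size
    csum = np.concatenate([[0], np.cumsum(above)])
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    length = j - i + 1
    full = (csum[j + 1] - csum[i]) == length
    ok = full & (length * dt > rule.min_sustained_h + 1e-9)
    return "proliferating" if bool(ok.any()) else "quiescent"


def _random_piecewise_traces(rng, n_traces, t):
    out = []
    for _ in range(n_traces):
        nseg = rng.integers(1, 12)
        cuts = np.sort(rng.choice(np.arange(1, t.size), size=nseg - 1,
                                  replace=False)) if nseg > 1 else np.array([], int)
        vals = rng.uniform(0.2, 2.0, nseg)
        a = np.empty(t.size)
        start = 0
        for k, b in enumerate(list(cuts) + [t.size]):
            a[start:b] = vals[k]
            start = b
        out.append(a)
    return out


def classification_benchmark(seed: int, n_traces: int = 10_000) -> dict:
    """Agreement of classify_fate with the brute-force run-scan oracle."""
    rng = np.random.default_rng(seed)
    rule = cycle_metrics.ClassificationRule()
    t = np.arange(0.0, 48.0 + 1e-9, 0.2)
    agree = 0
    for a in _random_piecewise_traces(rng, n_traces, t):
        agree += (cycle_metrics.classify_fate(t, a, rule)
                  == brute_force_fate(t, a, rule))
    return dict(n=n_traces, agreement_pct=100.0 * agree / n_traces)


def bleedthrough_benchmark(seed: int, n_cells: int = 60) -> dict:
    """Alpha recovery and corrected-trace flatness on CDK4/6i-saturated cells."""
    cfg = simulate.SimConfig(n_cells=n_cells, duration_hours=48.0,
                             cdk46_suppressed=True, rng_seed=seed)
    traces, truth = simulate.simulate_traces(cfg)
    alpha, alpha_se = quantify.fit_bleedthrough(traces)

    cfg0 = simulate.SimConfig(n_cells=n_cells, duration_hours=48.0,
                              cdk46_suppressed=True, cdk2_bleed_alpha=0.0,
                              rng_seed=seed + 1)
    traces0, _ = simulate.simulate_traces(cfg0)
    alpha0, _ = quantify.fit_bleedthrough(traces0)

    # per-cell mean corrected activity over S/G2 frames (cells observed for
    # at least 10 S/G2 frames, so the mean is a trace-level summary rather
    # than a single noisy sample)
    tr = traces.merge(truth.cells[["cell_id", "g1s_h", "division_h"]], on="cell_id")
    sg2 = tr[(tr.time_h >= tr.g1s_h) & (tr.time_h < tr.division_h)]
    counts = sg2.groupby("cell_id").size()
    keep = counts[counts >= 10].index
    sg2 = sg2[sg2.cell_id.isin(keep)]
    corrected = quantify.correct_cdk46(sg2.cdk46_raw, sg2.cdk2,
                                       alpha=cfg.cdk2_bleed_alpha)
    per_cell = pd.Series(corrected, index=sg2.index).groupby(sg2.cell_id).mean()
    raw_rise = sg2.groupby("cell_id").cdk46_raw.mean()
    return dict(alpha=float(alpha), alpha_se=float(alpha_se),
                alpha_null=float(alpha0),
                corrected_sg2_max_abs=float(per_cell.abs().max()),
                raw_sg2_mean=float(raw_rise.mean()),
                n=int(per_cell.size))


def ratio_benchmark(seed: int) -> dict:
    """C/N ratio recovery for isolated rendered cells at fixed activities.

    Renders single static cells with true CDK2 C/N in {0.2, 1.0, 2.0} at
    zero and default noise, and measures the background-subtraction residual.
    """
    out = {"n": 3}
    for label, noise in (("zero_noise", 0.0), ("default_noise", 10.0)):
        errs = []
        for k, act in enumerate((0.2, 1.0, 2.0)):
            cfg = simulate.SimConfig(n_cells=1, duration_hours=0.4,
                                     noise_sd=noise, field_size_um=120,
                                     proliferating_fraction=1.0,
                                     motility_um_per_frame=0.0,
                                     rng_seed=seed + k)
            traces, truth = simulate.simulate_traces(cfg)
            # pin the true activity at the requested level
            truth.frames["cdk2_true"] = act
            frame = simulate.render_frame(truth, cfg, 0)
            labels = segment.segment_live(frame[0], cfg.pixel_size_um)
            rings = segment.build_rings(labels, cfg.pixel_size_um)
            ch = {r: frame[i] for r, i in simulate._CHANNEL_ROLES.items()}
            m = quantify.measure_frame(ch, labels, rings, cfg.pixel_size_um)
            meas = float((m.cdk2_ring_med / m.cdk2_nuc_med).iloc[0])
            errs.append(abs(meas - act) / act)
            if label == "zero_noise" and k == 0:
                bg = frame[2][labels.labels == 0]
                corrected = frame[2] - np.median(bg)
                out["bg_median_after_subtraction"] = float(
                    np.median(corrected[labels.labels == 0]))
        out[f"max_rel_err_pct_{label}"] = 100.0 * max(errs)
    return out


def tracking_benchmark(seed: int, n_cells: int = 100,
                       duration_hours: float = 47.8) -> dict:
    """Link recovery and mitosis detection on a full rendered movie."""
    cfg = simulate.SimConfig(n_cells=n_cells, duration_hours=duration_hours,
                             rng_seed=seed)
    traces, truth = simulate.simulate_traces(cfg)
    res = pipeline.process_simulation(truth, cfg)
    links = evaluate.link_recovery(res.tracks, truth.frames)
    divs = evaluate.division_metrics(res.events, res.tracks, truth)
    return dict(n=int(truth.frames.shape[0]),
                n_frames=cfg.n_frames,
                link_recovery_pct=100.0 * links["fraction"],
                n_true_divisions=divs["n_true"],
                division_recall_pct=100.0 * divs["recall"],
                division_fp_pct=100.0 * divs["fp_rate"])


def phase_benchmark(seed: int, n_cells: int = 120) -> dict:
    """G1/S and S/G2 boundary recovery and duration additivity.

    Simulates proliferating cells at default trace noise, calls boundaries
    per fully observed cycle, and scores against generator truth.
    """
    cfg = simulate.SimConfig(n_cells=n_cells, duration_hours=60.0,
                             proliferating_fraction=1.0, rng_seed=seed)
    traces, truth = simulate.simulate_traces(cfg)
    cells = truth.cells
    obs = cells[(cells.birth_h >= 0) & np.isfinite(cells.division_h)
                & (cells.division_h < cfg.duration_hours)]
    dt = cfg.dt_h
    hits_g1s = hits_sg2 = 0
    additive = total = 0
    n = 0
    for r in obs.itertuples():
        tr = traces[traces.cell_id == r.cell_id]
        g1s, sg2 = cycle_metrics.call_phases(
            tr.time_h.to_numpy() - r.birth_h, tr.degron.to_numpy(), "cdt1")
        n += 1
        if g1s is not None and abs(g1s - (r.g1s_h - r.birth_h)) <= 2 * dt + 1e-9:
            hits_g1s += 1
        if sg2 is not None and abs(sg2 - (r.sg2_h - r.birth_h)) <= 2 * dt + 1e-9:
            hits_sg2 += 1
        if g1s is not None and sg2 is not None:
            imt = r.division_h - r.birth_h
            g1, s = g1s, sg2 - g1s
            g2m = imt - sg2
            total += 1
            if abs((g1 + s + g2m) - imt) <= dt + 1e-9:
                additive += 1
    return dict(n=n,
                g1s_within2_pct=100.0 * hits_g1s / n,
                sg2_within2_pct=100.0 * hits_sg2 / n,
                additivity_pct=100.0 * additive / max(total, 1))


def _condition_g1_stats(cfg) -> pd.DataFrame:
    """Image-level pipeline -> per-cell phase durations for one condition."""
    traces, truth = simulate.simulate_traces(cfg)
    res = pipeline.process_simulation(truth, cfg)
    dt = cfg.dt_h
    div_times = {}
    for e in res.events.itertuples():
        div_times[int(e.mother_track)] = e.anaphase_frame * dt
    ann = cycle_metrics.annotate_phases(
        res.traces.dropna(subset=["degron"]),
        anaphase_times=res.anaphase_h, division_times=div_times,
        frame_interval_min=cfg.frame_interval_min)
    return ann


def end_to_end_benchmark(seed: int, n_cells_fast: int = 56,
                         n_cells_slow: int = 80) -> dict:
    """Recovery of a 3x G1-duration difference through the full image pipeline.

    Two rendered conditions share S and G2M distributions; condition B's G1
    mean is 3x condition A's.  Reports the estimated G1-mean ratio and the
    S and G2M mean ratios (true value 1).
    """
    cfg_a = simulate.SimConfig(n_cells=n_cells_fast, duration_hours=42.0,
                               g1_mean_h=6.0, proliferating_fraction=1.0,
                               rng_seed=seed)
    cfg_b = simulate.SimConfig(n_cells=n_cells_slow, duration_hours=42.0,
                               g1_mean_h=18.0, proliferating_fraction=1.0,
                               rng_seed=seed + 1)
    ann_a = _condition_g1_stats(cfg_a)
    ann_b = _condition_g1_stats(cfg_b)
    out = dict(n_cells_a=int(ann_a.shape[0]), n_cells_b=int(ann_b.shape[0]))
    for m in ("g1_h", "s_h", "g2m_h"):
        a = ann_a[m].dropna()
        b = ann_b[m].dropna()
        out[f"{m}_mean_a"] = float(a.mean())
        out[f"{m}_mean_b"] = float(b.mean())
        out[f"{m}_ratio"] = float(b.mean() / a.mean())
        out[f"{m}_n_a"] = int(a.size)
        out[f"{m}_n_b"] = int(b.size)
    return out


def fixed_cell_benchmark(seed: int, n_cells: int = 300) -> dict:
    """FISH puncta exactness, bimodal classifier accuracy, dilation exclusion."""
    # puncta: known counts 0/5/12, well separated cells
    counts = np.tile([0, 5, 12], 3)
    stack, truth = simulate.render_fixed_field(
        n_cells=9, puncta_per_cell=counts, prb_positive_fraction=0.5,
        edu_positive_fraction=0.5, seed=seed)
    rec = quantify.measure_fixed_field(stack)
    matched = []
    for r in rec.itertuples():
        j = np.hypot(truth.cells.x_um - r.x_um,
                     truth.cells.y_um - r.y_um).idxmin()
        matched.append(int(r.fish_puncta) == int(truth.cells.loc[j, "fish_count"]))
    puncta_exact = 100.0 * np.mean(matched) if matched else 0.0

    # classifier accuracy on a larger cohort (no FISH channel needed)
    stack2, truth2 = simulate.render_fixed_field(
        n_cells=n_cells, puncta_per_cell=0, prb_positive_fraction=0.5,
        edu_positive_fraction=0.5, seed=seed + 1, spacing_um=40.0)
    from .segment import segment_fixed
    frame = stack2.pixels[0]
    roles = stack2.channel_roles
    labels = segment_fixed(frame[roles["hoechst"]], stack2.pixel_size_um)
    lab = labels.labels
    from scipy import ndimage as ndi
    ids = np.unique(lab)
    ids = ids[ids != 0]
    cy, cx = zip(*ndi.center_of_mass(np.ones_like(lab), lab, ids))
    rec2 = pd.DataFrame({"label": ids, "x_um": np.asarray(cx), "y_um": np.asarray(cy)})
    for role in ("edu", "prb", "trb"):
        img = frame[roles[role]].astype(float)
        img = img - np.median(img[lab == 0])
        rec2[role] = ndi.labeled_comprehension(img, lab, ids, np.median, float, np.nan)
    rec2 = quantify.classify_edu(rec2)
    rec2 = quantify.classify_prb(rec2)
    e_ok = p_ok = 0
    for r in rec2.itertuples():
        j = np.hypot(truth2.cells.x_um - r.x_um, truth2.cells.y_um - r.y_um).idxmin()
        e_ok += r.edu_positive == truth2.cells.loc[j, "edu_positive"]
        p_ok += r.prb_positive == truth2.cells.loc[j, "prb_positive"]

    # exclusion of overlapping 50-um dilation zones, vs brute force
    stack3, truth3 = simulate.render_fixed_field(
        n_cells=4, puncta_per_cell=3, prb_positive_fraction=0.5,
        edu_positive_fraction=0.5, seed=seed + 2, spacing_um=60.0)
    rec3 = quantify.measure_fixed_field(stack3)
    # brute force: nuclei whose edge-to-edge distance < 100 um
    brute = []
    cells3 = truth3.cells
    for r in rec3.itertuples():
        j = np.hypot(cells3.x_um - r.x_um, cells3.y_um - r.y_um).idxmin()
        me = cells3.loc[j]
        others = cells3.drop(j)
        edge = (np.hypot(others.x_um - me.x_um, others.y_um - me.y_um)
                - others.radius_um - me.radius_um)
        brute.append(bool((edge < 100.0).any()))
    excl_match = 100.0 * np.mean([b == e for b, e
                                  in zip(brute, rec3.excluded.tolist())])
    return dict(n=int(len(rec2)),
                puncta_exact_pct=float(puncta_exact),
                edu_accuracy_pct=100.0 * e_ok / len(rec2),
                prb_accuracy_pct=100.0 * p_ok / len(rec2),
                exclusion_match_pct=float(excl_match))


def ic50_benchmark(seed: int, true_ic50: float = 120.0) -> dict:
    """4PL IC50 recovery at zero and 2% multiplicative noise."""
    rng = np.random.default_rng(seed)
    doses = np.array([0.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])
    control = 0.35
    rel = cycle_metrics._four_pl(doses, 1.0, 0.04, true_ic50, 1.1)
    fit0 = cycle_metrics.ic50_from_sphase(doses, rel * control, control)
    noisy = rel * control * (1.0 + rng.normal(0.0, 0.02, doses.size))
    fit2 = cycle_metrics.ic50_from_sphase(doses, noisy, control)
    return dict(n=int(doses.size), true_ic50_nm=true_ic50,
                ic50_zero_noise_nm=fit0["ic50"],
                ic50_err_pct_zero_noise=100.0 * abs(fit0["ic50"] - true_ic50) / true_ic50,
                ic50_2pct_noise_nm=fit2["ic50"],
                ic50_err_pct_2pct_noise=100.0 * abs(fit2["ic50"] - true_ic50) / true_ic50)
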