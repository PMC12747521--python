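"""Proliferative-fate classification, anaphase alignment, degron-based
phase calling, duration summaries, and dose-response fitting.

The fate rule labels a cell *proliferating* when its CDK2 C/N ratio exceeds
1 continuously for more than 2 hours somewhere inside the 30-48 h analysis
window; under drug-combination conditions the same rule yields the
*persister* label.  Phase boundaries come from the Cdt1-degron trace: the
fragment builds through G1, its degradation onset marks G1/S, and its
re-accumulation after the S-phase trough marks S/G2.  A Geminin-degron
variant marks G1/S by accumulation onset instead (no S/G2 call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ClassificationRule",
    "classify_fate",
    "align_to_anaphase",
    "call_phases",
    "annotate_phases",
    "duration_stats",
    "ic50_from_sphase",
]


@dataclass
class ClassificationRule:
    """Sustained-CDK2-activity rule for proliferative fate.

    ``activity_threshold`` is in C/N ratio units (1 is the natural unit of
    the sensor readout); ``min_sustained_h`` is the strict lower bound on
    run duration; ``window_h`` is the analysis window in hours from movie
    start.
    """

    activity_threshold: float = 1.0
    min_sustained_h: float = 2.0
    window_h: tuple = (30.0, 48.0)


def classify_fate(time_h, cdk2, rule: ClassificationRule | None = None,
                  gap_filled=None) -> str:
    """Classify one cell's trace as proliferating / quiescent / unclassified.

    A cell is proliferating iff some contiguous run of frames inside the
    window has CDK2 above threshold at every frame and total duration
    (frames x interval) strictly greater than ``min_sustained_h``.  A single
    sub-threshold frame breaks a run.  Gap-filled frames (NaN activity)
    count toward a run only when both flanking measured frames are above
    threshold, flagged via ``gap_filled``.  Cells whose trace does not cover
    the window are ``"unclassified"``.
    """
    rule = rule or ClassificationRule()
    t = np.asarray(time_h, dtype=np.float64)
    a = np.asarray(cdk2, dtype=np.float64)
    order = np.argsort(t, kind="stable")
    t, a = t[order], a[order]
    gf = (np.asarray(gap_filled, dtype=bool)[order] if gap_filled is not None
          else np.zeros(t.size, dtype=bool))
    lo, hi = rule.window_h
    if t.size < 2 or t.min() > lo + 1e-9 or t.max() < hi - 1e-9:
        return "unclassified"
    dt = np.median(np.diff(t))
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    a, gf = a[sel], gf[sel]

    above = a > rule.activity_threshold
    # gap-filled frames inherit truth only between two above-threshold
    # measured neighbours
    for i in np.nonzero(gf)[0]:
        j = i - 1
        while j >= 0 and gf[j]:
            j -= 1
        k = i + 1
        while k < above.size and gf[k]:
            k += 1
        above[i] = (j >= 0 and k < above.size and above[j] and above[k])

    run = 0
    for ok in above:
        run = run + 1 if ok else 0
        if run * dt > rule.min_sustained_h + 1e-9:
            return "proliferating"
    return "quiescent"


def align_to_anaphase(traces: pd.DataFrame, anaphase_times: pd.Series | dict
                      ) -> pd.DataFrame:
    """Re-index traces to time since anaphase (t = 0 at division).

    ``anaphase_times`` maps cell id -> anaphase time in hours (cells whose
    birth was observed; typically daughters from detected mitoses).  Cells
    without an observed anaphase are excluded.  Adds ``t_since_anaphase_h``.
    """
    if isinstance(anaphase_times, dict):
        anaphase_times = pd.Series(anaphase_times)
    out = traces[traces.cell_id.isin(anaphase_times.index)].copy()
    out["t_since_anaphase_h"] = out.time_h - out.cell_id.map(anaphase_times)
    return out


def call_phases(time_h, degron, degron_kind: str = "cdt1",
                f_drop: float = 0.5, r_rise: float = 2.0, k_frames: int = 3,
                smooth_frames: int = 3):
    """Call G1/S and S/G2 boundary times from one aligned degron trace.

    ``time_h`` is time since anaphase.  For the Cdt1 fragment, G1/S is the
    onset of sustained degradation: the first time the (median-smoothed)
    trace falls below ``f_drop`` of its running pre-drop maximum and keeps
    falling for ``k_frames``, walked back to where the decline began.  S/G2
    is the onset of sustained re-accumulation after the trough: the first
    sustained rise above ``r_rise`` x the trough level, walked back to where
    the trace left the trough plateau.  For the Geminin fragment, G1/S is
    the onset of sustained accumulation and no S/G2 is defined.

    Returns ``(g1s_h, sg2_h)``; either may be None when no boundary is found.
    """
    t = np.asarray(time_h, dtype=np.float64)
    d = np.asarray(degron, dtype=np.float64)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    ok = np.isfinite(d)
    t, d = t[ok], d[ok]
    if t.size < 2 * k_frames + 2:
        return None, None
    if smooth_frames > 1:
        pad = smooth_frames // 2
        dp = np.pad(d, pad, mode="edge")
        d = np.array([np.median(dp[i:i + smooth_frames]) for i in range(t.size)])

    if degron_kind == "geminin":
        base = float(np.median(d[:max(k_frames, 2)]))
        scale = max(d.max() - base, 1e-9)
        rise = d > base + 0.2 * scale
        ci = _first_sustained(rise, k_frames)
        if ci is None:
            return None, None
        # back-extrapolate the accumulation limb to the G1 baseline
        je = min(ci + k_frames, t.size - 1)
        slope = (d[je] - d[ci]) / max(t[je] - t[ci], 1e-9)
        if slope > 0:
            onset = float(np.clip(t[ci] - (d[ci] - base) / slope, t[0], t[ci]))
        else:
            onset = float(t[ci])
        return onset, None
    if degron_kind != "cdt1":
        raise ValueError("degron_kind must be 'cdt1' or 'geminin'")

    runmax = np.maximum.accumulate(d)
    below = d < f_drop * runmax
    # sustained: below for k consecutive frames
    ci = _first_sustained(below, k_frames)
    if ci is None:
        return None, None
    # walk back to decline onset (last frame still near the running max)
    j = ci
    while j > 0 and d[j - 1] < 0.95 * runmax[j - 1]:
        j -= 1
    g1s = float(t[j])

    # trough and re-accumulation after the drop; the rise test starts at the
    # trough so the falling limb cannot satisfy it
    tail = np.arange(ci, t.size)
    if tail.size < k_frames + 1:
        return g1s, None
    trough_idx = ci + int(np.argmin(d[ci:]))
    trough = max(float(np.percentile(d[ci:], 10)), 1e-9)
    risen = d > r_rise * trough
    risen[:trough_idx] = False
    ri = _first_sustained(risen, k_frames)
    if ri is None:
        return g1s, None
    # back-extrapolate the rising limb to the trough level to find the
    # re-accumulation onset (robust to noise on the S-phase plateau)
    je = min(ri + k_frames, t.size - 1)
    slope = (d[je] - d[ri]) / max(t[je] - t[ri], 1e-9)
    if slope > 0:
        onset = t[ri] - (d[ri] - trough) / slope
        onset = float(np.clip(onset, t[trough_idx], t[ri]))
    else:
        onset = float(t[max(ri - 1, trough_idx)])
    return g1s, onset


def _first_sustained(flags: np.ndarray, k: int):
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= k:
            return i - k + 1
    return None


def annotate_phases(traces: pd.DataFrame, anaphase_times, division_times=None,
                    classes=None, degron_kind: str = "cdt1",
                    frame_interval_min: float = 12.0, **call_kw) -> pd.DataFrame:
    """Build per-cell phase annotations for a cohort.

    ``anaphase_times`` maps cell id -> observed anaphase (h);
    ``division_times`` maps cell id -> the cell's own next anaphase (h) where
    observed; ``classes`` maps cell id -> fate label (quiescent cells get no
    boundary calls).  Durations: G1 = G1/S - anaphase, S = S/G2 - G1/S,
    G2M = next anaphase - S/G2, IMT = next anaphase - anaphase, so
    G1 + S + G2M = IMT exactly whenever all terms are defined.
    """
    if isinstance(anaphase_times, dict):
        anaphase_times = pd.Series(anaphase_times, dtype=float)
    division_times = (pd.Series(division_times, dtype=float)
                      if division_times is not None else pd.Series(dtype=float))
    aligned = align_to_anaphase(traces, anaphase_times)
    rows = []
    for cid, grp in aligned.groupby("cell_id", sort=True):
        ana = float(anaphase_times[cid])
        cls = classes.get(cid, "proliferating") if classes is not None else "proliferating"
        row = dict(cell_id=cid, anaphase_time_h=ana, cls=cls,
                   g1s_time_h=np.nan, sg2_time_h=np.nan,
                   next_anaphase_time_h=np.nan, g1_h=np.nan, s_h=np.nan,
                   g2m_h=np.nan, imt_h=np.nan, boundary_missing=False)
        nxt = division_times.get(cid, np.nan)
        if np.isfinite(nxt):
            row["next_anaphase_time_h"] = nxt
            row["imt_h"] = nxt - ana
        if cls == "quiescent":
            rows.append(row)
            continue
        g1s, sg2 = call_phases(grp.t_since_anaphase_h.to_numpy(),
                               grp.degron.to_numpy(), degron_kind=degron_kind,
                               **call_kw)
        if g1s is None:
            row["boundary_missing"] = True
        else:
            row["g1s_time_h"] = ana + g1s
            row["g1_h"] = g1s
            if sg2 is not None:
                row["sg2_time_h"] = ana + sg2
                row["s_h"] = sg2 - g1s
                if np.isfinite(nxt):
                    row["g2m_h"] = (nxt - ana) - sg2
            elif degron_kind == "cdt1":
                row["boundary_missing"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def duration_stats(annotations: pd.DataFrame, group_col: str = "group",
                   metrics=("imt_h", "g1_h", "s_h", "g2m_h")) -> pd.DataFrame:
    """Per-group n / mean / median / sd / 95% CI for each duration metric.

    The CI is the normal approximation mean +/- 1.96 SE; single-cell groups
    report NaN CI.  Empty groups are omitted with a warning.
    """
    rows = []
    groups = (annotations.groupby(group_col) if group_col in annotations
              else [("all", annotations)])
    for g, df in groups:
        for m in metrics:
            if m not in df:
                continue
            v = df[m].dropna().to_numpy()
            if v.size == 0:
                warnings.warn(f"group {g!r}: no values for {m}; omitted")
                continue
            mean = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
            se = sd / np.sqrt(v.size) if v.size > 1 else np.nan
            rows.append(dict(group=g, metric=m, n=int(v.size), mean=mean,
                             median=float(np.median(v)), sd=sd,
                             ci95_lo=mean - 1.96 * se if v.size > 1 else np.nan,
                             ci95_hi=mean + 1.96 * se if v.size > 1 else np.nan))
    return pd.DataFrame(rows)


def _four_pl(dose, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def ic50_from_sphase(doses, s_phase_fraction, control_fraction: float):
    """Four-parameter logistic IC50 from S-phase fractions.

    ``s_phase_fraction`` at each dose is divided by ``control_fraction``
    (drug-naive S-phase fraction) and fitted with
    ``bottom + (top - bottom) / (1 + (dose/IC50)^h)``.  The IC50 is the dose
    of half-maximal inhibition.  Raises ``ValueError`` when the data show no
    inhibition.  Returns a dict with ``ic50``, ``ic50_ci`` (approximate 95%),
    the other parameters, and residuals.
    """
    doses = np.asarray(doses, dtype=np.float64)
    frac = np.asarray(s_phase_fraction, dtype=np.float64)
    if doses.size < 5 or doses.size != frac.size:
        raise ValueError("need >= 5 matched dose levels")
    if control_fraction <= 0:
        raise ValueError("control_fraction must be positive")
    rel = frac / control_fraction
    pos = doses > 0
    if not pos.any():
        raise ValueError("need at least one non-zero dose")
    hi_resp = rel[doses <= np.min(doses[pos])].mean()
    lo_resp = rel[doses == doses.max()].mean()
    if hi_resp - lo_resp < 0.1 * max(hi_resp, 1e-9):
        raise ValueError("no inhibition detected: response does not decrease with dose")
    p0 = [max(rel.max(), 1e-3), max(min(rel.min(), lo_resp), 0.0),
          float(np.exp(np.mean(np.log(doses[pos])))), 1.0]
    bounds = ([0, 0, np.min(doses[pos]) / 100, 0.2],
              [10, 10, np.max(doses) * 100, 10])
    popt, pcov = curve_fit(_four_pl, doses, rel, p0=p0, bounds=bounds,
                           maxfev=20000)
    top, bottom, ic50, hill = popt
    resid = rel - _four_pl(doses, *popt)
    se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    return dict(ic50=float(ic50), ic50_ci=(ic50 - 1.96 * se, ic50 + 1.96 * se),
                top=float(top), bottom=float(bottom), hill=float(hill),
                residuals=resid, rel_response=rel)
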