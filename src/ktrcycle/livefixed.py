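"""Registration of the final live frame to the fixed-cell image of the same
field, one-to-one cell matching, and transfer of live history onto fixed
measurements.

After live imaging the same wells are pulsed with EdU, fixed, and re-imaged;
a small stage shift separates the two acquisitions.  The shift is recovered
by cross-correlating the two nuclear channels (H2B live, Hoechst fixed);
cells are then matched by mutual nearest centroids, and each fixed-cell
record inherits the matched cell's time since anaphase and final CDK2
activity, enabling endpoint readouts (EdU, p-Rb, mRNA puncta) to be plotted
against live-cell history.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

__all__ = [
    "register_fields",
    "match_cells",
    "annotate_fixed",
    "binned_summary",
]


class RegistrationError(RuntimeError):
    pass


def register_fields(live_h2b: np.ndarray, fixed_hoechst: np.ndarray,
                    pixel_size_um: float = 1.0, upsample: int = 20,
                    min_correlation: float = 0.2):
    """Recover the rigid translation from live to fixed coordinates.

    Returns ``(dy_um, dx_um)`` such that a live position plus the offset
    lands on the corresponding fixed position.  Sub-pixel refinement via
    upsampled cross-correlation.  Raises :class:`RegistrationError` when the
    aligned images do not actually correlate (wrong field pairing).
    """
    live = np.asarray(live_h2b, dtype=np.float64)
    fixed = np.asarray(fixed_hoechst, dtype=np.float64)
    shift, _, _ = phase_cross_correlation(fixed, live, upsample_factor=upsample)
    # verify with normalized correlation after integer alignment
    sy, sx = int(round(shift[0])), int(round(shift[1]))
    rolled = np.roll(np.roll(live, sy, axis=0), sx, axis=1)
    a = rolled - rolled.mean()
    b = fixed - fixed.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    ncc = float((a * b).sum() / denom) if denom > 0 else 0.0
    if ncc < min_correlation:
        raise RegistrationError(
            f"fields do not correspond (normalized correlation {ncc:.3f})")
    return float(shift[0]) * pixel_size_um, float(shift[1]) * pixel_size_um


def match_cells(live_cells: pd.DataFrame, fixed_cells: pd.DataFrame,
                offset_um=(0.0, 0.0), max_dist_um: float = 10.0) -> pd.DataFrame:
    """Mutual-nearest one-to-one matching of live to fixed cells.

    Both tables need ``x_um, y_um`` and an id column (``cell_id`` for live,
    ``label`` for fixed; falls back to ``cell_id``).  ``offset_um`` is the
    ``(dy, dx)`` registration shift added to live positions.  Non-mutual or
    too-distant candidates stay unmatched with a reason.

    Returns a MatchTable: ``live_id, fixed_id, match_dist_um, reason`` where
    unmatched rows carry NaN on the missing side and a reason in
    {``no_candidate``, ``ambiguous``}.
    """
    dy, dx = offset_um
    lid = "cell_id" if "cell_id" in live_cells else "label"
    fid = "label" if "label" in fixed_cells else "cell_id"
    lp = live_cells[["x_um", "y_um"]].to_numpy() + np.array([[dx, dy]])
    fp = fixed_cells[["x_um", "y_um"]].to_numpy()
    rows = []
    if len(lp) == 0 or len(fp) == 0:
        for i in range(len(lp)):
            rows.append(dict(live_id=live_cells[lid].iloc[i], fixed_id=np.nan,
                             match_dist_um=np.nan, reason="no_candidate"))
        for j in range(len(fp)):
            rows.append(dict(live_id=np.nan, fixed_id=fixed_cells[fid].iloc[j],
                             match_dist_um=np.nan, reason="no_candidate"))
        return pd.DataFrame(rows)

    ftree = cKDTree(fp)
    ltree = cKDTree(lp)
    d_lf, near_f = ftree.query(lp)       # for each live, nearest fixed
    d_fl, near_l = ltree.query(fp)       # for each fixed, nearest live
    matched_f = set()
    for i in range(len(lp)):
        j = near_f[i]
        if d_lf[i] > max_dist_um:
            rows.append(dict(live_id=live_cells[lid].iloc[i], fixed_id=np.nan,
                             match_dist_um=np.nan, reason="no_candidate"))
        elif near_l[j] == i:
            rows.append(dict(live_id=live_cells[lid].iloc[i],
                             fixed_id=fixed_cells[fid].iloc[j],
                             match_dist_um=float(d_lf[i]), reason=""))
            matched_f.add(j)
        else:
            rows.append(dict(live_id=live_cells[lid].iloc[i], fixed_id=np.nan,
                             match_dist_um=np.nan, reason="ambiguous"))
    for j in range(len(fp)):
        if j not in matched_f:
            reason = "no_candidate" if d_fl[j] > max_dist_um else "ambiguous"
            rows.append(dict(live_id=np.nan, fixed_id=fixed_cells[fid].iloc[j],
                             match_dist_um=np.nan, reason=reason))
    return pd.DataFrame(rows)


def annotate_fixed(matches: pd.DataFrame, annotations: pd.DataFrame,
                   fixed_records: pd.DataFrame, movie_end_h: float,
                   final_cdk2: pd.Series | dict | None = None) -> pd.DataFrame:
    """Merge live history onto matched fixed-cell records.

    Each matched fixed record gains ``t_since_anaphase_h`` (movie end minus
    the cell's anaphase; NaN when the cell's anaphase was never observed,
    such cells stay usable for activity-binned analyses) and, when
    ``final_cdk2`` is given, ``cdk2_final``.
    """
    ok = matches.dropna(subset=["live_id", "fixed_id"])
    if len(ok) == 0:
        warnings.warn("empty match table; merged record set is empty")
    merged = fixed_records.merge(
        ok.rename(columns={"fixed_id": "label"})[["label", "live_id", "match_dist_um"]],
        on="label", how="inner")
    ana = annotations.set_index("cell_id")["anaphase_time_h"] if len(annotations) else pd.Series(dtype=float)
    merged["t_since_anaphase_h"] = movie_end_h - merged.live_id.map(ana)
    if final_cdk2 is not None:
        if isinstance(final_cdk2, dict):
            final_cdk2 = pd.Series(final_cdk2)
        merged["cdk2_final"] = merged.live_id.map(final_cdk2)
    return merged


def binned_summary(records: pd.DataFrame, value_col: str, by: str,
                   bin_width_h: float = 1.0, n_quantile_bins: int = 10,
                   fraction: bool = False) -> pd.DataFrame:
    """Binned means (or positive fractions) with 95% CIs.

    ``by = "time"`` bins ``t_since_anaphase_h`` in ``bin_width_h`` steps;
    ``by = "cdk2"`` uses quantile bins of ``cdk2_final``.  With
    ``fraction=True`` the value column is boolean and the summary is the
    positive fraction with a normal-approximation CI.
    """
    df = records.copy()
    if by == "time":
        key = "t_since_anaphase_h"
        df = df.dropna(subset=[key, value_col])
        df["bin"] = (df[key] // bin_width_h) * bin_width_h + bin_width_h / 2
    elif by == "cdk2":
        key = "cdk2_final"
        df = df.dropna(subset=[key, value_col])
        df["bin"] = pd.qcut(df[key], q=n_quantile_bins, duplicates="drop").apply(
            lambda iv: iv.mid).astype(float)
    else:
        raise ValueError("by must be 'time' or 'cdk2'")
    rows = []
    for b, grp in df.groupby("bin"):
        v = grp[value_col].astype(float).to_numpy()
        n = v.size
        m = float(v.mean())
        if fraction:
            se = np.sqrt(m * (1 - m) / n) if n else np.nan
        else:
            se = v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append(dict(bin=float(b), n=int(n), mean=m,
                         ci95_lo=m - 1.96 * se, ci95_hi=m + 1.96 * se))
    return pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)
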