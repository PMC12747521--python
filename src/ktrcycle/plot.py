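"""Figure helpers: single-cell activity heatmaps and aligned mean traces.

The heatmap mirrors the standard presentation of single-cell CDK-activity
cohorts: one row per cell, time on the x axis, rows ordered by fate class
(proliferating first) and, within a class, by the time the cell's CDK2
activity first crosses the classification threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cycle_metrics import ClassificationRule, classify_fate

__all__ = ["heatmap_matrix", "plot_activity_heatmap", "plot_aligned_mean"]


def heatmap_matrix(traces: pd.DataFrame, value_col: str = "cdk2",
                   rule: ClassificationRule | None = None):
    """Cell-by-frame matrix with rows ordered by class, then first crossing.

    Returns ``(matrix, ordered_cell_ids, classes)`` where ``matrix`` is
    (n_cells, n_frames) with NaN for frames a cell was not observed.
    """
    rule = rule or ClassificationRule()
    pivot = traces.pivot_table(index="cell_id", columns="frame",
                               values=value_col, aggfunc="first")
    order = []
    for cid, grp in traces.groupby("cell_id"):
        cls = classify_fate(grp.time_h, grp[value_col], rule)
        above = grp[grp[value_col] > rule.activity_threshold]
        t_cross = above.time_h.min() if len(above) else np.inf
        rank = {"proliferating": 0, "quiescent": 1, "unclassified": 2}[cls]
        order.append((rank, t_cross, cid, cls))
    order.sort()
    ids = [cid for _, _, cid, _ in order]
    classes = {cid: cls for _, _, cid, cls in order}
    return pivot.loc[ids].to_numpy(), ids, classes


def plot_activity_heatmap(traces: pd.DataFrame, value_col: str = "cdk2",
                          rule: ClassificationRule | None = None,
                          frame_interval_min: float = 12.0, ax=None,
                          vmax: float = 2.0):
    """Render the ordered single-cell activity heatmap; returns the axes."""
    import matplotlib.pyplot as plt

    mat, ids, _ = heatmap_matrix(traces, value_col, rule)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    dt = frame_interval_min / 60.0
    im = ax.imshow(mat, aspect="auto", interpolation="nearest",
                   vmin=0.0, vmax=vmax, cmap="viridis",
                   extent=(0, mat.shape[1] * dt, len(ids), 0))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cells (ordered)")
    ax.figure.colorbar(im, ax=ax, label=f"{value_col} (C/N)")
    return ax


def plot_aligned_mean(aligned: pd.DataFrame, value_col: str = "cdk2",
                      bin_h: float = 0.2, ax=None):
    """Mean trace vs time since anaphase with a 95% CI band; returns axes.

    ``aligned`` must carry ``t_since_anaphase_h`` (see
    :func:`ktrcycle.cycle_metrics.align_to_anaphase`).
    """
    import matplotlib.pyplot as plt

    df = aligned.dropna(subset=[value_col, "t_since_anaphase_h"]).copy()
    df["bin"] = (df.t_since_anaphase_h / bin_h).round() * bin_h
    g = df.groupby("bin")[value_col]
    mean = g.mean()
    se = g.std(ddof=1) / np.sqrt(g.size())
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(mean.index, mean.to_numpy(), lw=1.5)
    ax.fill_between(mean.index, mean - 1.96 * se, mean + 1.96 * se, alpha=0.3)
    ax.set_xlabel("time since anaphase (h)")
    ax.set_ylabel(f"{value_col} (C/N)")
    return ax
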