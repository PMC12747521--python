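"""Comparison of pipeline output against simulator ground truth.

Used by the test suite and the acceptance script to score detection,
frame-to-frame link recovery, division detection, and phase-boundary
accuracy on synthetic movies where every quantity is known.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "match_frame_detections",
    "link_recovery",
    "division_metrics",
    "track_to_truth_map",
]


def match_frame_detections(det_xy: np.ndarray, truth_xy: np.ndarray,
                           radius_um: float = 5.0) -> np.ndarray:
    """Greedy nearest matching of detections to true cells in one frame.

    Returns for each detection the index into ``truth_xy`` or -1.
    """
    out = np.full(len(det_xy), -1, dtype=int)
    if len(det_xy) == 0 or len(truth_xy) == 0:
        return out
    tree = cKDTree(truth_xy)
    dists, idx = tree.query(det_xy)
    order = np.argsort(dists)
    taken = set()
    for i in order:
        if dists[i] > radius_um:
            break
        j = idx[i]
        if j in taken:
            # fall back to next nearest free truth point
            cand = tree.query(det_xy[i], k=min(4, len(truth_xy)))
            found = False
            for d, jj in zip(np.atleast_1d(cand[0]), np.atleast_1d(cand[1])):
                if d <= radius_um and jj not in taken:
                    j, found = jj, True
                    break
            if not found:
                continue
        out[i] = j
        taken.add(j)
    return out


def _per_frame_assignment(tracks: pd.DataFrame, truth_frames: pd.DataFrame,
                          radius_um: float) -> pd.DataFrame:
    """Rows ``frame, track_id, cell_id`` for every matched detection."""
    rows = []
    for f, det in tracks[~tracks.gap_filled.astype(bool)].groupby("frame"):
        tf = truth_frames[truth_frames.frame == f]
        if len(tf) == 0 or len(det) == 0:
            continue
        m = match_frame_detections(det[["x_um", "y_um"]].to_numpy(),
                                   tf[["x_um", "y_um"]].to_numpy(), radius_um)
        cid = tf.cell_id.to_numpy()
        for (tid, mi) in zip(det.track_id.to_numpy(), m):
            if mi >= 0:
                rows.append((int(f), int(tid), int(cid[mi])))
    return pd.DataFrame(rows, columns=["frame", "track_id", "cell_id"])


def link_recovery(tracks: pd.DataFrame, truth_frames: pd.DataFrame,
                  radius_um: float = 5.0) -> dict:
    """Fraction of true same-cell consecutive-frame links present in tracks.

    A true link (cell c alive at f and f+1) counts as recovered when both
    frames hold detections matched to c that share a track id.
    """
    asg = _per_frame_assignment(tracks, truth_frames, radius_um)
    key = asg.set_index(["cell_id", "frame"]).track_id
    total = 0
    hit = 0
    for cid, grp in truth_frames.groupby("cell_id"):
        fr = np.sort(grp.frame.to_numpy())
        for a, b in zip(fr[:-1], fr[1:]):
            if b != a + 1:
                continue
            total += 1
            ta = key.get((cid, int(a)))
            tb = key.get((cid, int(b)))
            if ta is not None and ta == tb:
                hit += 1
    return dict(recovered=hit, total=total,
                fraction=hit / total if total else np.nan)


def division_metrics(events: pd.DataFrame, tracks: pd.DataFrame,
                     truth, radius_um: float = 15.0,
                     frame_tol: int = 1) -> dict:
    """Division recall and false-positive count against lineage truth.

    A true division is a mother with two on-camera daughters; a detected
    event matches it when the anaphase frames agree within ``frame_tol`` and
    the daughters' first centroids lie within ``radius_um`` of the true
    daughters' birth positions.
    """
    cfg = truth.config
    dt = cfg.dt_h
    kids = truth.cells[truth.cells.parent_id >= 0]
    first_pos = (truth.frames.sort_values("frame")
                 .groupby("cell_id")[["frame", "x_um", "y_um"]].first())
    true_divs = []
    for mid, grp in kids.groupby("parent_id"):
        ids = [c for c in grp.cell_id if c in first_pos.index]
        if len(ids) != 2:
            continue
        f0 = int(first_pos.loc[ids[0], "frame"])
        cx = first_pos.loc[ids, "x_um"].mean()
        cy = first_pos.loc[ids, "y_um"].mean()
        true_divs.append((int(mid), f0, cx, cy))

    first_det = (tracks[~tracks.gap_filled.astype(bool)]
                 .sort_values("frame").groupby("track_id")[["x_um", "y_um"]].first())
    det = []
    for e in events.itertuples():
        xs, ys = [], []
        for d in (e.daughter_a, e.daughter_b):
            if d in first_det.index:
                xs.append(first_det.loc[d, "x_um"])
                ys.append(first_det.loc[d, "y_um"])
        if xs:
            det.append((int(e.anaphase_frame), float(np.mean(xs)), float(np.mean(ys))))

    matched_truth = set()
    matched_det = set()
    for ti, (mid, f0, cx, cy) in enumerate(true_divs):
        best = None
        for di, (f, x, y) in enumerate(det):
            if di in matched_det or abs(f - f0) > frame_tol:
                continue
            d = np.hypot(x - cx, y - cy)
            if d <= radius_um and (best is None or d < best[0]):
                best = (d, di)
        if best is not None:
            matched_truth.add(ti)
            matched_det.add(best[1])
    n_true = len(true_divs)
    n_det = len(det)
    fp = n_det - len(matched_det)
    return dict(n_true=n_true, n_detected=n_det,
                recall=len(matched_truth) / n_true if n_true else np.nan,
                false_positives=fp,
                fp_rate=fp / n_true if n_true else np.nan)


def track_to_truth_map(tracks: pd.DataFrame, truth_frames: pd.DataFrame,
                       radius_um: float = 5.0, min_votes: int = 3) -> pd.Series:
    """Majority-vote mapping from track id to true cell id."""
    asg = _per_frame_assignment(tracks, truth_frames, radius_um)
    if len(asg) == 0:
        return pd.Series(dtype=int)
    votes = asg.groupby(["track_id", "cell_id"]).size().reset_index(name="n")
    votes = votes.sort_values("n", ascending=False).drop_duplicates("track_id")
    votes = votes[votes.n >= min_votes]
    return votes.set_index("track_id").cell_id
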