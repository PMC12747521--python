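"""Frame-to-frame linking, gap bridging, and mitosis detection.

Linking minimizes total displacement per frame pair by optimal assignment on
motion-predicted positions: each active track's next position is extrapolated
from its recent velocity, candidate detections within ``max_step_um`` of the
track's last position are scored by distance to that prediction, and the
globally optimal assignment is taken.  This resolves "deflections", where a
naive nearest-neighbour link would steal a competing track's detection.
Unmatched detections open new tracks; track fragments separated by short
detection dropouts are re-joined by gap bridging; divisions are recognized by
the appearance of two daughter nuclei adjacent to a prior nucleus, each
carrying roughly 45-55% of the mother's integrated H2B signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "link_frames",
    "bridge_gaps",
    "detect_mitoses",
    "MitosisEvent",
    "detections_from_frames",
]

_VEL_DAMP = 0.5  # fraction of last displacement used for motion prediction


@dataclass
class MitosisEvent:
    mother_track: int
    daughter_tracks: tuple
    anaphase_frame: int
    daughter_h2b_fractions: tuple


def detections_from_frames(labelmaps, pixel_size_um: float) -> list:
    """Turn a sequence of label maps into per-frame detection tables.

    Each table has ``label, x_um, y_um, area_um2``; intensity columns may be
    added by the quantification stage before linking.
    """
    from scipy import ndimage as ndi
    out = []
    for lm in labelmaps:
        labels = lm.labels if hasattr(lm, "labels") else np.asarray(lm)
        ids = np.unique(labels)
        ids = ids[ids != 0]
        if ids.size:
            cy, cx = zip(*ndi.center_of_mass(np.ones_like(labels), labels, ids))
            areas = ndi.sum_labels(np.ones_like(labels), labels, ids)
        else:
            cy, cx, areas = [], [], []
        out.append(pd.DataFrame({
            "label": ids.astype(int),
            "x_um": np.asarray(cx) * pixel_size_um,
            "y_um": np.asarray(cy) * pixel_size_um,
            "area_um2": np.asarray(areas) * pixel_size_um**2,
        }))
    return out


def link_frames(detections, max_step_um: float, pixel_size_um: float | None = None
                ) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    ``detections`` is either a sequence of label maps (then
    ``pixel_size_um`` is required) or a sequence of per-frame DataFrames with
    at least ``x_um, y_um`` columns (extra columns are carried through).
    Returns a tidy DataFrame with ``track_id, parent_id, frame, gap_filled``
    plus all detection columns, sorted by track then frame.
    """
    dets = list(detections)
    if len(dets) < 2:
        raise ValueError("need at least 2 frames to link")
    if not isinstance(dets[0], pd.DataFrame):
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required when passing label maps")
        dets = detections_from_frames(dets, pixel_size_um)

    next_id = 0
    # active track state: id -> (x, y, vx, vy)
    active: dict[int, tuple] = {}
    rows = []

    def _open(frame, rec):
        nonlocal next_id
        tid = next_id
        next_id += 1
        active[tid] = (rec["x_um"], rec["y_um"], 0.0, 0.0)
        rows.append({**rec, "track_id": tid, "frame": frame})
        return tid

    for rec in dets[0].to_dict("records"):
        _open(0, rec)

    for f in range(1, len(dets)):
        det = dets[f]
        track_ids = sorted(active)
        n_t, n_d = len(track_ids), len(det)
        if n_d == 0:
            active.clear()
            continue
        if n_t == 0:
            for rec in det.to_dict("records"):
                _open(f, rec)
            continue
        last = np.array([[active[t][0], active[t][1]] for t in track_ids])
        pred = last + _VEL_DAMP * np.array(
            [[active[t][2], active[t][3]] for t in track_ids])
        pos = det[["x_um", "y_um"]].to_numpy()
        d_last = np.hypot(last[:, 0:1] - pos[None, :, 0], last[:, 1:2] - pos[None, :, 1])
        d_pred = np.hypot(pred[:, 0:1] - pos[None, :, 0], pred[:, 1:2] - pos[None, :, 1])
        BIG = 1e6
        cost = np.where(d_last <= max_step_um, d_pred, BIG)
        ti, di = linear_sum_assignment(cost)
        matched_d = set()
        new_active: dict[int, tuple] = {}
        recs = det.to_dict("records")
        for a, b in zip(ti, di):
            if cost[a, b] >= BIG:
                continue
            tid = track_ids[a]
            x0, y0 = active[tid][0], active[tid][1]
            x1, y1 = recs[b]["x_um"], recs[b]["y_um"]
            new_active[tid] = (x1, y1, x1 - x0, y1 - y0)
            rows.append({**recs[b], "track_id": tid, "frame": f})
            matched_d.add(b)
        active = new_active
        for b in range(n_d):
            if b not in matched_d:
                _open(f, recs[b])

    tracks = pd.DataFrame(rows)
    tracks["parent_id"] = -1
    tracks["gap_filled"] = False
    return tracks.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


def bridge_gaps(tracks: pd.DataFrame, max_gap_frames: int = 3,
                max_step_um: float = 20.0) -> pd.DataFrame:
    """Join track ends to later track starts across short detection dropouts.

    A candidate bridge joins the end of one track to the start of another
    when the gap is ``<= max_gap_frames`` missing frames and the displacement
    is consistent with ``max_step_um`` per elapsed frame.  Bridges are
    applied greedily in order of increasing displacement; bridged frames get
    interpolated centroids, NaN intensities, and ``gap_filled=True``.
    """
    tracks = tracks.copy()
    ends = tracks.loc[tracks.groupby("track_id").frame.idxmax()]
    starts = tracks.loc[tracks.groupby("track_id").frame.idxmin()]
    starts = starts[starts.frame > 0]

    cands = []
    for e in ends.itertuples():
        for s in starts.itertuples():
            if s.track_id == e.track_id:
                continue
            gap = s.frame - e.frame - 1
            if gap < 1 or gap > max_gap_frames:
                continue
            d = np.hypot(s.x_um - e.x_um, s.y_um - e.y_um)
            if d <= max_step_um * (gap + 1):
                cands.append((d, e.track_id, s.track_id, e.frame, s.frame))
    cands.sort()
    used_end, used_start = set(), set()
    merge_into: dict[int, int] = {}
    fill_rows = []
    for d, e_id, s_id, ef, sf in cands:
        if e_id in used_end or s_id in used_start or s_id in merge_into:
            continue
        used_end.add(e_id)
        used_start.add(s_id)
        merge_into[s_id] = e_id
        e_row = tracks[(tracks.track_id == e_id) & (tracks.frame == ef)].iloc[0]
        s_row = tracks[(tracks.track_id == s_id) & (tracks.frame == sf)].iloc[0]
        for f in range(ef + 1, sf):
            w = (f - ef) / (sf - ef)
            fill = {c: np.nan for c in tracks.columns}
            fill.update(track_id=e_id, frame=f, parent_id=-1, gap_filled=True,
                        x_um=(1 - w) * e_row.x_um + w * s_row.x_um,
                        y_um=(1 - w) * e_row.y_um + w * s_row.y_um)
            fill_rows.append(fill)

    # resolve chains (a->b->c) to the root id
    def root(tid):
        while tid in merge_into:
            tid = merge_into[tid]
        return tid

    tracks["track_id"] = tracks["track_id"].map(root)
    if fill_rows:
        fills = pd.DataFrame(fill_rows)
        fills["track_id"] = fills["track_id"].map(root)
        tracks = pd.concat([tracks, fills], ignore_index=True)
    return tracks.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


def detect_mitoses(tracks: pd.DataFrame, fraction_range=(0.45, 0.55),
                   adjacency_um: float = 25.0, fraction_tol: float = 0.05,
                   h2b_col: str = "h2b_nuc_med"):
    """Detect division events and assemble the lineage forest.

    A division is recorded when a nucleus is replaced at frame ``t+1`` by two
    adjacent nuclei whose integrated H2B signals (area x median) are each
    "about" 45-55% of the mother's at ``t``.  Two geometries are handled:
    the mother track ends and two new tracks start nearby, or the linker
    carried the mother's identity onto one daughter (an H2B drop into the
    daughter range on a continuing track) while the other daughter opened a
    new track -- in that case the continuing track is split at the division.

    ``fraction_tol`` pads the configured range to absorb measurement noise in
    the area-times-median estimate; grossly asymmetric splits are still
    rejected.  Candidate sets with three or more daughters produce no event.

    Returns ``(tracks, events)`` where ``tracks`` has ``parent_id`` filled in
    and split tracks relabelled, and ``events`` is a DataFrame of
    :class:`MitosisEvent` fields.
    """
    tracks = tracks.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    if h2b_col not in tracks.columns:
        raise ValueError(f"tracks must carry {h2b_col!r} to test the daughter rule")
    lo = fraction_range[0] - fraction_tol
    hi = fraction_range[1] + fraction_tol

    tracks["h2b_integ"] = tracks["area_um2"] * tracks[h2b_col]
    first = tracks.loc[tracks.groupby("track_id").frame.idxmin()]
    last = tracks.loc[tracks.groupby("track_id").frame.idxmax()]
    first_by_frame: dict[int, list] = {}
    for r in first.itertuples():
        if r.frame > 0:
            first_by_frame.setdefault(int(r.frame), []).append(r)

    by_tf = tracks.set_index(["track_id", "frame"])
    last_frame = last.set_index("track_id").frame.to_dict()
    first_frame = first.set_index("track_id").frame.to_dict()

    events = []
    next_tid = int(tracks.track_id.max()) + 1
    parent_of: dict[int, int] = {}          # keyed on final (post-split) ids
    splits: dict[int, list] = {}            # raw tid -> [(frame, new_tid)] asc
    mother_locked: dict = {}                # (raw tid, frame) -> True
    claimed: set = set()                    # newcomer tids already daughters

    def eff_id(raw_tid: int, frame: int) -> int:
        """Final track id owning raw track ``raw_tid`` at ``frame``."""
        out = raw_tid
        for sf, nid in splits.get(raw_tid, []):
            if frame >= sf:
                out = nid
        return out

    for f in sorted(first_by_frame):
        newcomers = [r for r in first_by_frame[f] if r.track_id not in claimed]
        if not newcomers:
            continue
        # mothers whose track ends at f-1, plus tracks continuing through f
        enders = last[last.frame == f - 1]
        cont = tracks[(tracks.frame == f) & (~tracks.gap_filled.astype(bool))]
        for nc in newcomers:
            if nc.track_id in claimed:
                continue
            # --- geometry 1: ended mother + two new tracks ----------------
            for m in enders.itertuples():
                if mother_locked.get((m.track_id, f)):
                    continue
                if np.hypot(nc.x_um - m.x_um, nc.y_um - m.y_um) > adjacency_um:
                    continue
                sibs = [r for r in first_by_frame[f]
                        if r.track_id != nc.track_id
                        and r.track_id not in claimed
                        and np.hypot(r.x_um - m.x_um, r.y_um - m.y_um) <= adjacency_um]
                if len(sibs) > 1:
                    warnings.warn(f"track {m.track_id}: >2 daughter candidates "
                                  f"at frame {f}; no event recorded")
                    continue
                if len(sibs) != 1:
                    continue
                sib = sibs[0]
                mi = m.h2b_integ
                if not np.isfinite(mi) or mi <= 0:
                    continue
                f1 = nc.h2b_integ / mi
                f2 = sib.h2b_integ / mi
                if lo <= f1 <= hi and lo <= f2 <= hi and f1 + f2 <= 1.0 + 2 * fraction_tol:
                    mom = eff_id(m.track_id, f - 1)
                    parent_of[nc.track_id] = mom
                    parent_of[sib.track_id] = mom
                    claimed.add(nc.track_id)
                    claimed.add(sib.track_id)
                    mother_locked[(m.track_id, f)] = True
                    events.append(dict(mother_track=int(mom),
                                       daughter_a=int(nc.track_id),
                                       daughter_b=int(sib.track_id),
                                       anaphase_frame=int(f),
                                       fraction_a=float(f1), fraction_b=float(f2)))
                    break
            if nc.track_id in claimed:
                continue
            # --- geometry 2: linker carried the mother onto one daughter --
            best = None
            for c in cont.itertuples():
                if c.track_id == nc.track_id or mother_locked.get((c.track_id, f)):
                    continue
                if first_frame.get(c.track_id, 0) >= f:
                    continue
                try:
                    prev = by_tf.loc[(c.track_id, f - 1)]
                except KeyError:
                    continue
                if isinstance(prev, pd.DataFrame):
                    continue
                mi = prev["h2b_integ"]
                if not np.isfinite(mi) or mi <= 0:
                    continue
                if np.hypot(nc.x_um - prev["x_um"], nc.y_um - prev["y_um"]) > adjacency_um:
                    continue
                f1 = c.h2b_integ / mi
                f2 = nc.h2b_integ / mi
                if lo <= f1 <= hi and lo <= f2 <= hi and f1 + f2 <= 1.0 + 2 * fraction_tol:
                    d = np.hypot(nc.x_um - prev["x_um"], nc.y_um - prev["y_um"])
                    if best is None or d < best[0]:
                        best = (d, c.track_id, f1, f2)
            if best is not None:
                _, c_tid, f1, f2 = best
                # split continuing track c at frame f: its tail becomes one
                # daughter under a fresh id; the newcomer is the other
                mom = eff_id(c_tid, f - 1)
                splits.setdefault(c_tid, []).append((f, next_tid))
                parent_of[next_tid] = mom
                parent_of[nc.track_id] = mom
                claimed.add(nc.track_id)
                mother_locked[(c_tid, f)] = True
                events.append(dict(mother_track=int(mom),
                                   daughter_a=int(next_tid),
                                   daughter_b=int(nc.track_id),
                                   anaphase_frame=int(f),
                                   fraction_a=float(f1), fraction_b=float(f2)))
                next_tid += 1

    # apply splits: each row takes the id of the last split at or before it
    if splits:
        raw = tracks.track_id.to_numpy().copy()
        fr = tracks.frame.to_numpy()
        final = raw.copy()
        for old, lst in splits.items():
            sel = raw == old
            for sf, nid in lst:  # ascending frames
                final[sel & (fr >= sf)] = nid
        tracks["track_id"] = final
    tracks["parent_id"] = tracks.track_id.map(parent_of).fillna(-1).astype(int)
    tracks = tracks.drop(columns="h2b_integ")
    events_df = pd.DataFrame(events) if events else pd.DataFrame(
        columns=["mother_track", "daughter_a", "daughter_b",
                 "anaphase_frame", "fraction_a", "fraction_b"])
    return (tracks.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True),
            events_df)
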