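"""End-to-end live-movie processing: frames -> tracks -> activity traces.

Streams frames one at a time (rendered on the fly for simulations, or pulled
from an :class:`~ktrcycle.io.ImageStack`), so full movies never need to be
held in memory.  Each frame is segmented on the nuclear channel, cytoplasmic
rings are built, every channel is background-corrected and summarized per
nucleus; detections are then linked, gaps bridged, mitoses detected, and
per-cell C/N activity traces assembled with bleed-through-corrected CDK4/6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quantify, segment, track
from .io import ImageStack
from .quantify import ALPHA_MCF7
from .segment import SegmentParams

__all__ = ["PipelineResult", "process_frames", "process_stack", "process_simulation"]


@dataclass
class PipelineResult:
    """Tracks (tidy per-frame rows), mitosis events, per-cell traces, and
    the anaphase times of cells whose birth was observed."""

    tracks: pd.DataFrame
    events: pd.DataFrame
    traces: pd.DataFrame
    anaphase_h: pd.Series
    frame_interval_min: float

    def final_cdk2(self) -> pd.Series:
        last = self.traces.loc[self.traces.groupby("cell_id").frame.idxmax()]
        return last.set_index("cell_id")["cdk2"]


def process_frames(frame_iter, pixel_size_um: float, frame_interval_min: float,
                   channel_roles: dict, alpha: float = ALPHA_MCF7,
                   max_step_um: float = 15.0, max_gap_frames: int = 2,
                   seg_params: SegmentParams | None = None,
                   reference_field: np.ndarray | None = None,
                   ring_inner_um: float = 0.65, ring_outer_um: float = 3.25,
                   adjacency_um: float = 25.0,
                   nuclear_floor: float = 10.0) -> PipelineResult:
    """Run the full live pipeline over an iterable of ``(C, Y, X)`` frames."""
    seg_params = seg_params or SegmentParams()
    ref = None
    if reference_field is not None:
        ref = np.asarray(reference_field, dtype=np.float64)
        ref = ref / ref.mean()

    detections = []
    for pix in frame_iter:
        pix = np.asarray(pix, dtype=np.float64)
        if ref is not None:
            pix = pix / ref[None]
        h2b = pix[channel_roles["h2b"]]
        labels = segment.segment_live(h2b, pixel_size_um, seg_params)
        rings = segment.build_rings(labels, pixel_size_um,
                                    inner_um=ring_inner_um, outer_um=ring_outer_um)
        channels = {role: pix[idx] for role, idx in channel_roles.items()}
        detections.append(quantify.measure_frame(channels, labels, rings,
                                                 pixel_size_um))

    tracks = track.link_frames(detections, max_step_um=max_step_um)
    tracks = track.bridge_gaps(tracks, max_gap_frames=max_gap_frames,
                               max_step_um=max_step_um)
    tracks, events = track.detect_mitoses(tracks, adjacency_um=adjacency_um,
                                          h2b_col="h2b_nuc_med")

    dt = frame_interval_min / 60.0
    tr = tracks.copy()
    tr["time_h"] = tr.frame * dt
    invalid = tr.ring_overlap.fillna(False).astype(bool) | tr.border.fillna(False).astype(bool)
    roles = [r for r in channel_roles if r != "h2b"]
    traces = pd.DataFrame({
        "cell_id": tr.track_id, "parent_id": tr.parent_id, "frame": tr.frame,
        "time_h": tr.time_h, "x_um": tr.x_um, "y_um": tr.y_um,
        "gap_filled": tr.gap_filled.fillna(False).astype(bool),
    })
    for role in roles:
        nuc = tr.get(f"{role}_nuc_med")
        ring = tr.get(f"{role}_ring_med")
        if nuc is None:
            continue
        if role in ("cdk2", "cdk46"):
            col = "cdk2" if role == "cdk2" else "cdk46_raw"
            traces[col] = quantify.ktr_ratio(nuc, ring, floor=nuclear_floor,
                                             invalid=invalid)
        elif role == "degron":
            traces["degron"] = nuc.to_numpy()
    if "cdk46_raw" in traces and "cdk2" in traces:
        traces["cdk46_corrected"] = quantify.correct_cdk46(
            traces.cdk46_raw, traces.cdk2, alpha=alpha)

    ana = {}
    for e in events.itertuples():
        ana[int(e.daughter_a)] = e.anaphase_frame * dt
        ana[int(e.daughter_b)] = e.anaphase_frame * dt
    return PipelineResult(tracks=tracks, events=events, traces=traces,
                          anaphase_h=pd.Series(ana, dtype=float),
                          frame_interval_min=frame_interval_min)


def process_stack(stack: ImageStack, **kw) -> PipelineResult:
    """Run the live pipeline on an in-memory image stack."""
    return process_frames((stack.pixels[t] for t in range(stack.n_frames)),
                          pixel_size_um=stack.pixel_size_um,
                          frame_interval_min=stack.frame_interval_min,
                          channel_roles=stack.channel_roles, **kw)


def process_simulation(truth, config, **kw) -> PipelineResult:
    """Render-and-process a simulation frame by frame (memory-friendly)."""
    from . import simulate

    n_px = int(round(truth.field_size_um / config.pixel_size_um))
    bias = truth.bias_field((n_px, n_px))

    def frames():
        for t in range(config.n_frames):
            yield simulate.render_frame(truth, config, t, bias=bias)

    kw.setdefault("alpha", config.cdk2_bleed_alpha)
    return process_frames(frames(), pixel_size_um=config.pixel_size_um,
                          frame_interval_min=config.frame_interval_min,
                          channel_roles=dict(simulate._CHANNEL_ROLES), **kw)
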