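"""Ground-truthed synthetic single-cell movies and traces.

This module generates the test bed for the whole pipeline: populations of
dividing and quiescent cells with prescribed G1/S/G2M duration distributions,
CDK4/6 and CDK2 sensor activities encoded as cytoplasm-to-nucleus (C/N)
ratios, a cell-cycle degron channel tied to the true phase boundaries, and a
renderer that turns those traces into multichannel images with background
offset, illumination bias, and pixel noise.

The kinetic shapes are piecewise-smooth canonical curves, not a mechanistic
ODE model: after anaphase the CDK4/6 sensor activates quickly and the CDK2
sensor rises gradually, crossing the C/N = 1 classification unit just before
the G1/S transition and climbing to ~2 at the next mitosis.  Quiescent cells
hold CDK2 below 1 throughout.  The Cdt1 degron accumulates through G1, is
degraded during S, and re-accumulates in G2; the Geminin variant instead
accumulates from G1/S onward.  Because the CDK4/6 sensor carries a degenerate
CDK2 phosphorylation motif, its *raw* rendered activity is
``true CDK4/6 + alpha * CDK2`` with a configurable bleed-through
coefficient ``alpha`` (default 0.41).

Everything is deterministic under a fixed seed: identical config in,
bit-identical tables and images out.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import ImageStack

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimGroundTruth",
    "FixedFieldTruth",
    "simulate_traces",
    "render_frame",
    "render_movie",
    "render_fixed_field",
    "render_fixed_companion",
    "CONDITIONS",
]


class SimConfigError(ValueError):
    """Raised for configurations that cannot define a valid simulation."""


# condition presets: proliferative fraction and G1 stretch relative to the
# untreated baseline.  Chronic CDK4/6 inhibition in resistant cells prolongs
# G1 roughly 2.5-fold and suppresses the true CDK4/6 sensor signal; drug
# withdrawal restores near-parental kinetics.
CONDITIONS = {
    "parental": dict(proliferating_fraction=0.98, g1_mean_h=10.0, cdk46_suppressed=False),
    "resistant_drug_maintained": dict(proliferating_fraction=0.92, g1_mean_h=25.0, cdk46_suppressed=True),
    "resistant_withdrawn": dict(proliferating_fraction=0.97, g1_mean_h=11.0, cdk46_suppressed=False),
    "quiescent_mix": dict(proliferating_fraction=0.5, g1_mean_h=10.0, cdk46_suppressed=False),
}


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Durations are hours, lengths micrometres, intensities arbitrary camera
    units.  ``frame_interval_min`` defaults to the 12-minute acquisition
    cadence the analysis assumes.  ``cdk2_bleed_alpha`` is the fraction of
    CDK2 activity that leaks into the raw CDK4/6 sensor channel.
    ``daughter_fraction_range`` bounds each daughter's share of the mother's
    integrated H2B signal at division.
    """

    n_cells: int = 100
    duration_hours: float = 48.0
    frame_interval_min: float = 12.0
    pixel_size_um: float = 1.0
    condition: str = "parental"
    g1_mean_h: float = 10.0
    g1_cv: float = 0.3
    s_mean_h: float = 8.0
    s_cv: float = 0.08
    g2m_mean_h: float = 4.0
    g2m_cv: float = 0.10
    cdk2_bleed_alpha: float = 0.41
    daughter_fraction_range: tuple = (0.45, 0.55)
    proliferating_fraction: float = 0.98
    background_offset: float = 100.0
    illumination_bias_amplitude: float = 0.0
    noise_sd: float = 10.0
    trace_noise_cn: float = 0.03
    degron_noise: float = 15.0
    degron_kind: str = "cdt1"
    cdk46_suppressed: bool = False
    motility_um_per_frame: float = 1.0
    spacing_um: float = 80.0
    field_size_um: float | None = None
    nuclear_radius_um: float = 6.0
    cyto_width_um: float = 6.0
    rng_seed: int = 0

    @classmethod
    def for_condition(cls, condition: str, **overrides) -> "SimConfig":
        """Build a config from a named treatment condition preset."""
        if condition not in CONDITIONS:
            raise SimConfigError(f"unknown condition {condition!r}")
        kw = dict(CONDITIONS[condition])
        kw.update(overrides)
        return cls(condition=condition, **kw)

    def to_yaml(self, path) -> None:
        """Write this config to a YAML file."""
        from .io import save_config
        d = asdict(self)
        d["daughter_fraction_range"] = list(self.daughter_fraction_range)
        save_config(d, path)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        from .io import load_config
        d = load_config(path)
        if "daughter_fraction_range" in d:
            d["daughter_fraction_range"] = tuple(d["daughter_fraction_range"])
        return cls(**d)

    def validate(self) -> None:
        for name in ("g1_mean_h", "s_mean_h", "g2m_mean_h", "duration_hours",
                     "frame_interval_min", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if not (0.0 <= self.proliferating_fraction <= 1.0):
            raise SimConfigError("proliferating_fraction must be in [0, 1]")
        lo, hi = self.daughter_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise SimConfigError("daughter_fraction_range must lie within (0, 1)")
        if self.n_cells < 1:
            raise SimConfigError("n_cells must be >= 1")
        if self.degron_kind not in ("cdt1", "geminin"):
            raise SimConfigError("degron_kind must be 'cdt1' or 'geminin'")

    @property
    def dt_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_hours / self.dt_h)) + 1

    def field_um(self) -> float:
        if self.field_size_um is not None:
            return float(self.field_size_um)
        side = math.ceil(math.sqrt(self.n_cells))
        return max(200.0, side * self.spacing_um + 2 * self.spacing_um)


@dataclass
class SimGroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``cells`` has one row per cell: lineage (``cell_id``, ``parent_id`` = -1
    for founders), class, birth (anaphase) time, division time (NaN if the
    cell never divides on camera), true phase durations and boundary times,
    and the H2B fraction inherited from the mother.  ``frames`` has one row
    per cell per frame: true centroid, true sensor activities, true degron
    level, H2B amount, and nuclear radius.
    """

    cells: pd.DataFrame
    frames: pd.DataFrame
    config: SimConfig
    field_size_um: float

    def bias_field(self, shape_yx: tuple) -> np.ndarray:
        """Multiplicative illumination surface used by the renderer (mean ~1)."""
        return _bias_field(shape_yx, self.config)

    def n_divisions(self) -> int:
        """Number of on-camera division events (lineage branch points)."""
        kids = self.cells[self.cells.parent_id >= 0]
        return kids.parent_id.nunique()


def _draw_lognormal(rng, mean, cv, n):
    """Lognormal samples with the requested arithmetic mean and CV."""
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _draw_truncnorm(rng, mean, cv, n, floor=0.1):
    out = rng.normal(mean, mean * cv, size=n)
    return np.maximum(out, floor)


def _draw_cycle(rng, cfg):
    g1 = float(_draw_lognormal(rng, cfg.g1_mean_h, cfg.g1_cv, 1)[0])
    s = float(_draw_truncnorm(rng, cfg.s_mean_h, cfg.s_cv, 1)[0])
    g2m = float(_draw_truncnorm(rng, cfg.g2m_mean_h, cfg.g2m_cv, 1)[0])
    return g1, s, g2m


def simulate_traces(config: SimConfig):
    """Simulate a cell population; return ``(TraceTable, SimGroundTruth)``.

    The trace table is the tidy per-cell, per-frame series the pipeline's
    quantification stage would produce from a perfect measurement, plus
    configurable measurement noise: columns ``cell_id, parent_id, frame,
    time_h, x_um, y_um, cdk46_raw, cdk2, degron, class``.  ``cdk46_raw``
    already contains the CDK2 bleed-through, so downstream correction with
    ``alpha`` is required to recover true CDK4/6 activity.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    field_um = cfg.field_um()
    margin = cfg.nuclear_radius_um + cfg.cyto_width_um + 2.0

    # --- lineage construction -------------------------------------------
    cells = []  # dict rows
    queue = []  # (cell dict) awaiting division processing, FIFO
    next_id = 0
    side = math.ceil(math.sqrt(cfg.n_cells))
    pitch = (field_um - 2 * margin) / max(side, 1)

    for i in range(cfg.n_cells):
        gx, gy = i % side, i // side
        x0 = margin + (gx + 0.5) * pitch + rng.uniform(-0.25, 0.25) * pitch
        y0 = margin + (gy + 0.5) * pitch + rng.uniform(-0.25, 0.25) * pitch
        proliferating = rng.random() < cfg.proliferating_fraction
        amount0 = 1000.0 * rng.uniform(0.9, 1.1)
        if proliferating:
            g1, s, g2m = _draw_cycle(rng, cfg)
            imt = g1 + s + g2m
            birth = -rng.uniform(0.0, imt)  # random cycle phase at t = 0
            cell = dict(cell_id=next_id, parent_id=-1, cls="proliferating",
                        birth_h=birth, g1_h=g1, s_h=s, g2m_h=g2m, imt_h=imt,
                        division_h=birth + imt, daughter_fraction=np.nan,
                        h2b_birth=amount0, x0=x0, y0=y0,
                        cdk2_base=np.nan)
        else:
            cell = dict(cell_id=next_id, parent_id=-1, cls="quiescent",
                        birth_h=min(0.0, -rng.uniform(0, 5)),
                        g1_h=np.nan, s_h=np.nan, g2m_h=np.nan, imt_h=np.nan,
                        division_h=np.nan, daughter_fraction=np.nan,
                        h2b_birth=amount0, x0=x0, y0=y0,
                        cdk2_base=rng.uniform(0.35, 0.55))
        next_id += 1
        cells.append(cell)
        queue.append(cell)

    while queue:
        mother = queue.pop(0)
        div = mother["division_h"]
        if not np.isfinite(div) or div >= cfg.duration_hours:
            continue
        f1 = rng.uniform(*cfg.daughter_fraction_range)
        f2 = rng.uniform(*cfg.daughter_fraction_range)
        if f1 + f2 > 1.0:  # daughters cannot inherit more H2B than exists
            scale = 1.0 / (f1 + f2)
            f1, f2 = f1 * scale, f2 * scale
        m_amount = 2.0 * mother["h2b_birth"]  # H2B doubles over the cycle
        theta = rng.uniform(0, 2 * math.pi)
        sep = rng.uniform(4.0, 6.0)
        for frac, sign in ((f1, 1.0), (f2, -1.0)):
            g1, s, g2m = _draw_cycle(rng, cfg)
            imt = g1 + s + g2m
            child = dict(cell_id=next_id, parent_id=mother["cell_id"],
                         cls="proliferating", birth_h=div,
                         g1_h=g1, s_h=s, g2m_h=g2m, imt_h=imt,
                         division_h=div + imt, daughter_fraction=frac,
                         h2b_birth=frac * m_amount,
                         x0=np.nan, y0=np.nan, cdk2_base=np.nan,
                         _theta=theta, _sep=sign * sep)
            next_id += 1
            cells.append(child)
            queue.append(child)

    cells_df = pd.DataFrame(cells)

    # --- kinematics: frame-synchronous random walk with nuclear exclusion
    times = np.arange(cfg.n_frames) * cfg.dt_h
    cell_by_id = {c["cell_id"]: c for c in cells}
    first_frame = {}
    last_frame = {}
    for c in cells:
        birth, div = c["birth_h"], c["division_h"]
        alive = times >= max(birth, 0.0) - 1e-9
        if np.isfinite(div):
            alive &= times < div - 1e-9
        idx = np.nonzero(alive)[0]
        c["_frames"] = idx
        if idx.size:
            first_frame.setdefault(int(idx[0]), []).append(c["cell_id"])
            last_frame[c["cell_id"]] = int(idx[-1])

    def _radius_amount(c, t):
        if np.isfinite(c["imt_h"]):
            amt = c["h2b_birth"] * (1.0 + min(max((t - c["birth_h"]) / c["imt_h"], 0.0), 1.0))
        else:
            amt = c["h2b_birth"]
        return cfg.nuclear_radius_um * math.sqrt(amt / 1000.0), amt

    pos: dict[int, np.ndarray] = {}
    traj: dict[int, list] = {c["cell_id"]: [] for c in cells}
    for f in range(cfg.n_frames):
        t = times[f]
        for cid in sorted(first_frame.get(f, [])):
            c = cell_by_id[cid]
            if c["parent_id"] < 0:
                p = np.array([c["x0"], c["y0"]], dtype=float)
            else:
                mp = pos.get(c["parent_id"])
                if mp is None:  # mother never on camera; inherit her grid spot
                    anc = cell_by_id[c["parent_id"]]
                    while anc["parent_id"] >= 0 and pos.get(anc["cell_id"]) is None:
                        anc = cell_by_id[anc["parent_id"]]
                    mp = pos.get(anc["cell_id"],
                                 np.array([anc.get("x0", field_um / 2),
                                           anc.get("y0", field_um / 2)]))
                th, sp = c["_theta"], c["_sep"]
                p = mp + np.array([sp * math.cos(th), sp * math.sin(th)])
            pos[cid] = p
        # prune divided cells
        for cid in [k for k in pos if last_frame.get(k, -1) < f]:
            del pos[cid]
        ids = sorted(pos)
        if not ids:
            continue
        steps = rng.normal(0.0, cfg.motility_um_per_frame, size=(len(ids), 2))
        radii = np.empty(len(ids))
        pts = np.empty((len(ids), 2))
        for j, cid in enumerate(ids):
            p = pos[cid] + steps[j]
            p[0] = _reflect(p[0], margin, field_um - margin)
            p[1] = _reflect(p[1], margin, field_um - margin)
            pts[j] = p
            radii[j], _ = _radius_amount(cell_by_id[cid], t)
        # nuclei cannot interpenetrate: push overlapping pairs apart
        from scipy.spatial import cKDTree
        for _ in range(3):
            tree = cKDTree(pts)
            pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
            if pairs.size == 0:
                break
            moved = False
            for a, b in pairs:
                min_sep = 0.95 * (radii[a] + radii[b])
                dvec = pts[b] - pts[a]
                d = np.hypot(*dvec)
                if d >= min_sep:
                    continue
                moved = True
                if d < 1e-6:
                    dvec = np.array([1.0, 0.0])
                    d = 1.0
                push = 0.5 * (min_sep - d) / d
                pts[a] -= dvec * push
                pts[b] += dvec * push
            np.clip(pts, margin, field_um - margin, out=pts)
            if not moved:
                break
        for j, cid in enumerate(ids):
            pos[cid] = pts[j]
            traj[cid].append((f, pts[j, 0], pts[j, 1]))

    frame_rows = []
    for cell in cells:
        cid = cell["cell_id"]
        birth = cell["birth_h"]
        tr = traj[cid]
        if not tr:
            continue
        idx = np.array([r[0] for r in tr], dtype=int)
        xs = np.array([r[1] for r in tr])
        ys = np.array([r[2] for r in tr])

        tau = times[idx] - birth  # age since this cell's anaphase
        if cell["cls"] == "proliferating":
            cdk2 = _cdk2_curve(tau, cell["g1_h"], cell["imt_h"])
            cdk46 = 0.0 * tau if cfg.cdk46_suppressed else 0.2 + 0.7 * (1 - np.exp(-tau / 1.0))
            degron = _degron_curve(tau, cell["g1_h"], cell["s_h"],
                                   cell["imt_h"], cfg.degron_kind)
        else:
            base = cell["cdk2_base"]
            cdk2 = base + 0.05 * np.sin(2 * math.pi * (times[idx] + 7 * cid % 11) / 20.0)
            cdk46 = np.full_like(tau, 0.05 if cfg.cdk46_suppressed else 0.3)
            degron = (np.full_like(tau, 800.0) if cfg.degron_kind == "cdt1"
                      else np.full_like(tau, 50.0))
        cdk46_raw = cdk46 + cfg.cdk2_bleed_alpha * cdk2
        amount = cell["h2b_birth"] * (1.0 + np.clip(tau / cell["imt_h"], 0, 1)
                                      if np.isfinite(cell["imt_h"]) else np.ones_like(tau))
        radius = cfg.nuclear_radius_um * np.sqrt(amount / 1000.0)

        frame_rows.append(pd.DataFrame({
            "cell_id": cid, "frame": idx, "time_h": times[idx],
            "x_um": xs, "y_um": ys,
            "cdk2_true": cdk2, "cdk46_true": cdk46,
            "cdk46_raw_true": cdk46_raw, "degron_true": degron,
            "h2b_amount": amount, "radius_um": radius,
        }))

    frames_df = (pd.concat(frame_rows, ignore_index=True)
                 if frame_rows else pd.DataFrame(
                     columns=["cell_id", "frame", "time_h", "x_um", "y_um",
                              "cdk2_true", "cdk46_true", "cdk46_raw_true",
                              "degron_true", "h2b_amount", "radius_um"]))

    # ground-truth boundary times
    cells_df["g1s_h"] = cells_df.birth_h + cells_df.g1_h
    cells_df["sg2_h"] = cells_df.birth_h + cells_df.g1_h + cells_df.s_h
    cells_df = cells_df.drop(columns=[c for c in ("_theta", "_sep", "x0", "y0",
                                                  "cdk2_base") if c in cells_df],
                             errors="ignore")
    truth = SimGroundTruth(cells=cells_df, frames=frames_df, config=cfg,
                           field_size_um=field_um)

    # --- measured trace table (truth + sensor noise) --------------------
    tr = frames_df.merge(cells_df[["cell_id", "parent_id", "cls"]], on="cell_id")
    noise = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    n = len(tr)
    traces = pd.DataFrame({
        "cell_id": tr.cell_id,
        "parent_id": tr.parent_id,
        "frame": tr.frame,
        "time_h": tr.time_h,
        "x_um": tr.x_um,
        "y_um": tr.y_um,
        "cdk46_raw": tr.cdk46_raw_true + noise.normal(0, cfg.trace_noise_cn, n),
        "cdk2": tr.cdk2_true + noise.normal(0, cfg.trace_noise_cn, n),
        "degron": tr.degron_true + noise.normal(0, cfg.degron_noise, n),
        "class": tr.cls,
    }).sort_values(["cell_id", "frame"], kind="stable").reset_index(drop=True)
    return traces, truth


def _reflect(v, lo, hi):
    if v < lo:
        v = 2 * lo - v
    if v > hi:
        v = 2 * hi - v
    return min(max(v, lo), hi)


def _cdk2_curve(tau, g1, imt):
    """CDK2 C/N ratio: 0.45 at anaphase, crossing 1 just before G1/S, 2 at mitosis."""
    t_cross = 0.95 * g1
    rising = 0.45 + 0.55 * np.power(np.clip(tau / t_cross, 0, 1), 1.5)
    late = 1.0 + 1.0 * np.power(np.clip((tau - t_cross) / max(imt - t_cross, 1e-6), 0, 1), 0.9)
    return np.where(tau <= t_cross, rising, late)


def _degron_curve(tau, g1, s, imt, kind):
    """Degron level vs cell age.

    Cdt1 fragment: builds through G1, degraded with a ~20-min half-life at
    S entry, low plateau through S, fast re-accumulation from S/G2.
    Geminin fragment: low in G1, accumulates from G1/S to mitosis.
    """
    if kind == "geminin":
        out = np.full_like(tau, 50.0)
        post = tau >= g1
        out[post] = 50.0 + 750.0 * (tau[post] - g1) / max(imt - g1, 1e-6)
        return out
    out = 150.0 + 850.0 * np.clip(tau / g1, 0, 1)
    in_s = (tau >= g1) & (tau < g1 + s)
    out[in_s] = np.maximum(60.0, 1000.0 * np.exp2(-(tau[in_s] - g1) / 0.3))
    in_g2 = tau >= g1 + s
    out[in_g2] = np.minimum(600.0, 60.0 + 540.0 * (tau[in_g2] - g1 - s) / 1.5)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_CHANNEL_ROLES = {"h2b": 0, "cdk46": 1, "cdk2": 2, "degron": 3}
_KTR_NUC_AMP = 300.0   # nuclear KTR brightness (camera units)
_H2B_GAIN = 18.0       # H2B amplitude = gain * amount / radius_um^2
_DEGRON_GAIN = 0.5


def _bias_field(shape_yx, cfg: SimConfig):
    """Low-order polynomial illumination surface, mean ~1, deterministic."""
    ny, nx = shape_yx
    a = cfg.illumination_bias_amplitude
    if a == 0:
        return np.ones(shape_yx, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 7]))
    c = rng.normal(size=5)
    c /= np.linalg.norm(c)
    Y, X = np.mgrid[0:ny, 0:nx]
    X = 2.0 * X / max(nx - 1, 1) - 1.0
    Y = 2.0 * Y / max(ny - 1, 1) - 1.0
    surf = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * X**2 + c[4] * Y**2
    surf = surf / max(np.abs(surf).max(), 1e-9)
    out = 1.0 + a * surf
    return np.clip(out, 0.2, None).astype(np.float32)


def render_frame(truth: SimGroundTruth, config: SimConfig, frame_index: int,
                 bias: np.ndarray | None = None) -> np.ndarray:
    """Render one multichannel frame ``(C, Y, X)`` from ground truth.

    Nuclei are smooth discs; KTR cytoplasm is an annulus whose intensity is
    ``activity x nuclear intensity``, so the measured ring-median over
    nuclear-median ratio equals the prescribed activity.  The camera model is
    ``bias * (signal + background_offset) + N(0, noise_sd)``.
    """
    cfg = config
    ps = cfg.pixel_size_um
    n_px = int(round(truth.field_size_um / ps))
    shape = (n_px, n_px)
    sig = np.zeros((4, n_px, n_px), dtype=np.float32)

    rows = truth.frames[truth.frames.frame == frame_index]
    for r in rows.itertuples():
        cx, cy = r.x_um / ps, r.y_um / ps
        rad = r.radius_um
        half = int(math.ceil((rad + cfg.cyto_width_um) / ps)) + 2
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = max(ix - half, 0), min(ix + half + 1, n_px)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, n_px)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d_um = np.hypot(xx - cx, yy - cy) * ps
        nuc = 1.0 / (1.0 + np.exp((d_um - rad) / 0.3))
        cyt = (1.0 / (1.0 + np.exp((rad - d_um) / 0.3))
               * 1.0 / (1.0 + np.exp((d_um - (rad + cfg.cyto_width_um)) / 0.5)))
        h2b_amp = _H2B_GAIN * r.h2b_amount / (r.radius_um**2)
        sig[0, y0:y1, x0:x1] += h2b_amp * nuc
        sig[1, y0:y1, x0:x1] += _KTR_NUC_AMP * (nuc + r.cdk46_raw_true * cyt)
        sig[2, y0:y1, x0:x1] += _KTR_NUC_AMP * (nuc + r.cdk2_true * cyt)
        sig[3, y0:y1, x0:x1] += _DEGRON_GAIN * r.degron_true * nuc

    if bias is None:
        bias = _bias_field(shape, cfg)
    out = bias[None] * (sig + cfg.background_offset)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.rng_seed, 2, frame_index]))
        out = out + rng.normal(0.0, cfg.noise_sd, out.shape)
    return out.astype(np.float32)


def render_movie(traces: pd.DataFrame, truth: SimGroundTruth,
                 config: SimConfig) -> ImageStack:
    """Render the full movie into an in-memory :class:`ImageStack`.

    For long, dense movies prefer iterating :func:`render_frame` and
    processing frames one at a time; this materializes ``T x 4 x Y x X``
    float32 pixels.
    """
    cfg = config
    ps = cfg.pixel_size_um
    n_px = int(round(truth.field_size_um / ps))
    bias = _bias_field((n_px, n_px), cfg)
    frames = [render_frame(truth, cfg, t, bias=bias) for t in range(cfg.n_frames)]
    return ImageStack(pixels=np.stack(frames), pixel_size_um=ps,
                      frame_interval_min=cfg.frame_interval_min,
                      channel_roles=dict(_CHANNEL_ROLES))


# ---------------------------------------------------------------------------
# fixed-cell fields
# ---------------------------------------------------------------------------

_FIXED_ROLES = {"hoechst": 0, "edu": 1, "prb": 2, "trb": 3, "fish": 4}


@dataclass
class FixedFieldTruth:
    """Ground truth for a rendered fixed-cell field (one row per cell)."""

    cells: pd.DataFrame      # cell_id, x_um, y_um, radius_um, fish_count,
    #                          edu_positive, prb_positive
    puncta: pd.DataFrame     # cell_id, x_um, y_um
    pixel_size_um: float
    background_offset: float


def render_fixed_field(n_cells: int, puncta_per_cell, prb_positive_fraction: float,
                       edu_positive_fraction: float, seed: int,
                       pixel_size_um: float = 1.0, spacing_um: float = 130.0,
                       noise_sd: float = 3.0, background_offset: float = 50.0,
                       class_sep_sd: float = 4.0,
                       puncta_min_sep_um: float = 6.0):
    """Render a fixed-cell field with known per-cell ground truth.

    Channels: Hoechst nuclei, EdU (bimodal in log10 intensity), p-Rb and
    total Rb (classification lives on the p-Rb/t-Rb ratio, bimodal with the
    two modes ``class_sep_sd`` standard deviations apart in log10), and a
    FISH channel with point-like mRNA puncta at exactly the requested
    per-cell counts, placed inside each cell's territory with a minimum
    pairwise separation so a 4-um top-hat resolves them.

    ``puncta_per_cell`` may be a scalar or a length-``n_cells`` sequence.
    Default ``spacing_um`` = 130 um keeps the 50-um dilation zones of
    neighbouring cells separate; pass a smaller spacing to exercise the
    overlap-exclusion path.
    """
    rng = np.random.default_rng(seed)
    counts = np.broadcast_to(np.asarray(puncta_per_cell, dtype=int),
                             (n_cells,)).copy()
    side = math.ceil(math.sqrt(n_cells))
    margin = spacing_um / 2.0
    field_um = side * spacing_um + spacing_um
    n_px = int(round(field_um / pixel_size_um))

    cells = []
    puncta_rows = []
    for i in range(n_cells):
        gx, gy = i % side, i // side
        x = margin + (gx + 0.5) * spacing_um + rng.uniform(-6, 6)
        y = margin + (gy + 0.5) * spacing_um + rng.uniform(-6, 6)
        rad = rng.uniform(5.5, 7.5)
        edu_pos = bool(rng.random() < edu_positive_fraction)
        prb_pos = bool(rng.random() < prb_positive_fraction)
        # log10 intensity draws; EdU modes fixed, p-Rb ratio modes separated
        # class_sep_sd * sd
        edu_log = rng.normal(3.5, 0.15) if edu_pos else rng.normal(2.0, 0.10)
        # p-Rb/t-Rb ratio modes sit class_sep_sd standard deviations either
        # side of the decision boundary (hyper- vs hypo-phosphorylated)
        ratio_sd = 0.15
        ratio_log = rng.normal(-0.1, ratio_sd) if prb_pos else rng.normal(
            -0.1 - 2 * class_sep_sd * ratio_sd, ratio_sd)
        trb = 500.0 * rng.uniform(0.85, 1.15)
        pts = _place_puncta(rng, counts[i], x, y, rad, puncta_min_sep_um,
                            max_r=min(40.0, spacing_um / 2 - 8))
        for (px, py) in pts:
            puncta_rows.append(dict(cell_id=i, x_um=px, y_um=py))
        cells.append(dict(cell_id=i, x_um=x, y_um=y, radius_um=rad,
                          fish_count=int(counts[i]), edu_positive=edu_pos,
                          prb_positive=prb_pos, hoechst_amp=900 * rng.uniform(0.9, 1.1),
                          edu_amp=10.0**edu_log, trb_amp=trb,
                          prb_amp=trb * 10.0**ratio_log))
    cells_df = pd.DataFrame(cells)
    puncta_df = (pd.DataFrame(puncta_rows) if puncta_rows
                 else pd.DataFrame(columns=["cell_id", "x_um", "y_um"]))

    sig = np.zeros((5, n_px, n_px), dtype=np.float32)
    for r in cells_df.itertuples():
        _stamp_disc(sig[0], r.x_um, r.y_um, r.radius_um, r.hoechst_amp, pixel_size_um)
        _stamp_disc(sig[1], r.x_um, r.y_um, r.radius_um, r.edu_amp, pixel_size_um)
        _stamp_disc(sig[2], r.x_um, r.y_um, r.radius_um, r.prb_amp, pixel_size_um)
        _stamp_disc(sig[3], r.x_um, r.y_um, r.radius_um, r.trb_amp, pixel_size_um)
    for p in puncta_df.itertuples():
        _stamp_spot(sig[4], p.x_um, p.y_um, 800.0, pixel_size_um, sigma_um=0.8)

    out = sig + background_offset
    if noise_sd > 0:
        out = out + rng.normal(0, noise_sd, out.shape)
    stack = ImageStack(pixels=out.astype(np.float32)[None],
                       pixel_size_um=pixel_size_um, frame_interval_min=0.0,
                       channel_roles=dict(_FIXED_ROLES))
    truth = FixedFieldTruth(cells=cells_df, puncta=puncta_df,
                            pixel_size_um=pixel_size_um,
                            background_offset=background_offset)
    return stack, truth


def _place_puncta(rng, k, cx, cy, rad, min_sep, max_r):
    pts = []
    tries = 0
    while len(pts) < k and tries < 2000:
        tries += 1
        rr = rng.uniform(rad + 2.0, max(max_r, rad + 4.0))
        th = rng.uniform(0, 2 * math.pi)
        p = (cx + rr * math.cos(th), cy + rr * math.sin(th))
        if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in pts):
            pts.append(p)
    return pts


def _stamp_disc(img, x_um, y_um, rad_um, amp, ps):
    n = img.shape[0]
    cx, cy = x_um / ps, y_um / ps
    half = int(math.ceil(rad_um / ps)) + 3
    ix, iy = int(round(cx)), int(round(cy))
    x0, x1 = max(ix - half, 0), min(ix + half + 1, n)
    y0, y1 = max(iy - half, 0), min(iy + half + 1, n)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy) * ps
    img[y0:y1, x0:x1] += amp / (1.0 + np.exp((d - rad_um) / 0.3))


def _stamp_spot(img, x_um, y_um, amp, ps, sigma_um=0.8):
    n = img.shape[0]
    cx, cy = x_um / ps, y_um / ps
    half = int(math.ceil(4 * sigma_um / ps)) + 1
    ix, iy = int(round(cx)), int(round(cy))
    x0, x1 = max(ix - half, 0), min(ix + half + 1, n)
    y0, y1 = max(iy - half, 0), min(iy + half + 1, n)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = ((xx - cx)**2 + (yy - cy)**2) * ps**2
    img[y0:y1, x0:x1] += amp * np.exp(-d2 / (2 * sigma_um**2))


def render_fixed_companion(truth: SimGroundTruth, config: SimConfig,
                           jitter_um: float = 1.0, shift_um: tuple = (6.0, -4.0),
                           seed: int = 0):
    """Render a fixed-cell image of the movie's final frame population.

    Emulates the live-then-fix protocol: the same cells, jittered slightly
    and with a global stage shift relative to the last live frame, stained
    for Hoechst/EdU/p-Rb/t-Rb.  EdU positivity reflects whether the cell is
    truly in S phase at the end of the movie (a short pulse), p-Rb
    positivity reflects CDK activity (proliferating cells past early G1).
    Live-reporter channels are absent, as after photobleaching.

    Returns ``(ImageStack, DataFrame)`` where the table maps ``cell_id`` to
    the fixed-field position and the true endpoint labels.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    last = cfg.n_frames - 1
    rows = truth.frames[truth.frames.frame == last].merge(
        truth.cells, on="cell_id")
    t_end = last * cfg.dt_h
    ps = cfg.pixel_size_um
    n_px = int(round(truth.field_size_um / ps))

    recs = []
    sig = np.zeros((4, n_px, n_px), dtype=np.float32)
    for r in rows.itertuples():
        x = r.x_um + shift_um[0] + rng.normal(0, jitter_um)
        y = r.y_um + shift_um[1] + rng.normal(0, jitter_um)
        in_s = (r.cls == "proliferating" and np.isfinite(r.g1s_h)
                and r.g1s_h <= t_end < r.sg2_h)
        prb_pos = r.cls == "proliferating" and (t_end - r.birth_h) > 2.0
        edu_amp = 10 ** rng.normal(3.5, 0.15) if in_s else 10 ** rng.normal(2.0, 0.1)
        trb = 500.0 * rng.uniform(0.85, 1.15)
        prb = trb * 10 ** (rng.normal(-0.1, 0.15) if prb_pos
                           else rng.normal(-0.7, 0.15))
        _stamp_disc(sig[0], x, y, r.radius_um, 900.0, ps)
        _stamp_disc(sig[1], x, y, r.radius_um, edu_amp, ps)
        _stamp_disc(sig[2], x, y, r.radius_um, prb, ps)
        _stamp_disc(sig[3], x, y, r.radius_um, trb, ps)
        recs.append(dict(cell_id=r.cell_id, x_um=x, y_um=y,
                         edu_positive=bool(in_s), prb_positive=bool(prb_pos)))

    out = sig + 50.0 + rng.normal(0, 3.0, sig.shape)
    stack = ImageStack(pixels=out.astype(np.float32)[None], pixel_size_um=ps,
                       frame_interval_min=0.0,
                       channel_roles={"hoechst": 0, "edu": 1, "prb": 2, "trb": 3})
    return stack, pd.DataFrame(recs)
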