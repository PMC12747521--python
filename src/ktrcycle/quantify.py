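"""Per-cell intensity quantification: KTR ratios, bleed-through correction,
fixed-cell classification, and FISH puncta counting.

Kinase activity is read out as the cytoplasmic-to-nuclear (C/N) fluorescence
ratio of a translocation sensor: median intensity in the cytoplasmic ring
divided by the median over the nuclear pixels, both background-corrected.
Because the CDK4/6 sensor carries a degenerate CDK2 site and partially
reports CDK2 activity in S/G2, corrected CDK4/6 activity is
``raw - alpha * CDK2`` with ``alpha = 0.41`` by default (0.35 for cell lines
where the cross-reporting is weaker); ``fit_bleedthrough`` re-estimates
``alpha`` by regression on cells whose true CDK4/6 activity is expected to
be zero (e.g. under saturating CDK4/6 inhibition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import gaussian_kde
from skimage.morphology import white_tophat, disk

from .io import LabelMap
from .segment import RingSet

__all__ = [
    "ktr_ratio",
    "correct_cdk46",
    "fit_bleedthrough",
    "measure_frame",
    "valley_threshold",
    "classify_edu",
    "classify_prb",
    "count_fish_puncta",
    "measure_fixed_field",
]

ALPHA_MCF7 = 0.41
ALPHA_MDAMB231 = 0.35


def ktr_ratio(nuclear_median, ring_median, floor: float = 0.0,
              invalid=None):
    """C/N ratio = ring median / nuclear median; NaN where unusable.

    ``floor`` is the minimal acceptable nuclear signal (use ~3x the
    background MAD); ratios are NaN when the nuclear median is at or below
    it, or where ``invalid`` (ring overlap / border flags) is True.  Never
    divides by a non-positive denominator.
    """
    nuc = np.asarray(nuclear_median, dtype=np.float64)
    ring = np.asarray(ring_median, dtype=np.float64)
    bad = ~np.isfinite(nuc) | ~np.isfinite(ring) | (nuc <= max(floor, 0.0))
    if invalid is not None:
        bad |= np.asarray(invalid, dtype=bool)
    out = np.full(np.broadcast(nuc, ring).shape, np.nan)
    ok = ~bad
    out[ok] = ring[ok] / nuc[ok]
    if out.ndim == 0:
        return float(out)
    return out


def correct_cdk46(raw, cdk2, alpha: float = ALPHA_MCF7):
    """CDK4/6 activity = raw sensor C/N minus ``alpha`` x CDK2 C/N.

    Linear in its inputs; NaN propagates from either input.
    """
    return np.asarray(raw, dtype=np.float64) - alpha * np.asarray(cdk2, dtype=np.float64)


def fit_bleedthrough(traces: pd.DataFrame, raw_col: str = "cdk46_raw",
                     cdk2_col: str = "cdk2", min_points: int = 50):
    """Estimate the CDK2->CDK4/6-sensor bleed-through coefficient.

    Ordinary least squares of the raw CDK4/6 sensor on the CDK2 sensor
    (with intercept) over frames where true CDK4/6 activity is expected to
    be ~0, e.g. cells under saturating CDK4/6 inhibition.  Returns
    ``(alpha, stderr)``.
    """
    df = traces[[raw_col, cdk2_col]].dropna()
    if len(df) < min_points:
        raise ValueError(f"need >= {min_points} points to fit bleed-through, "
                         f"got {len(df)}")
    x = df[cdk2_col].to_numpy()
    y = df[raw_col].to_numpy()
    if np.ptp(x) < 1e-9 or np.std(x) < 1e-9:
        raise ValueError("CDK2 values are constant; regression is rank-deficient")
    X = np.column_stack([np.ones_like(x), x])
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = len(x) - 2
    resid = y - X @ coef
    s2 = resid @ resid / max(dof, 1)
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(coef[1]), float(np.sqrt(cov[1, 1]))


def measure_frame(channels: dict, labels, rings: RingSet,
                  pixel_size_um: float, bg_subtract: bool = True,
                  floor_k_mad: float = 3.0) -> pd.DataFrame:
    """Measure one segmented frame across channels.

    ``channels`` maps role name -> 2D array (flat-field corrected).  Each
    channel is background-corrected by subtracting the 50th percentile of
    its non-nuclear pixels, then summarized per label as the nuclear median
    and (where a ring exists) the ring median.  Returns one row per label:
    ``label, x_um, y_um, area_um2, <role>_nuc_med, <role>_ring_med,
    ring_overlap, border``.
    """
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    ids = np.unique(lab)
    ids = ids[ids != 0]
    ny, nx = lab.shape
    if ids.size == 0:
        return pd.DataFrame(columns=["label", "x_um", "y_um", "area_um2"])
    cy, cx = zip(*ndi.center_of_mass(np.ones_like(lab), lab, ids))
    areas = ndi.sum_labels(np.ones_like(lab), lab, ids) * pixel_size_um**2
    out = pd.DataFrame({
        "label": ids.astype(int),
        "x_um": np.asarray(cx) * pixel_size_um,
        "y_um": np.asarray(cy) * pixel_size_um,
        "area_um2": areas,
    })
    flags = rings.flags.set_index("label") if len(rings.flags) else None
    out["ring_overlap"] = [bool(flags.ring_overlap.get(i, False)) if flags is not None
                           else False for i in out.label]
    out["border"] = [bool(flags.border.get(i, False)) if flags is not None
                     else False for i in out.label]

    flat_lab = lab.ravel()
    for role, img in channels.items():
        img = np.asarray(img, dtype=np.float64)
        if bg_subtract:
            img = img - np.median(img[lab == 0])
        flat = img.ravel()
        nuc_med = ndi.labeled_comprehension(img, lab, ids, np.median, float, np.nan)
        ring_med = np.full(ids.size, np.nan)
        for j, i in enumerate(ids):
            px = rings.pixels.get(int(i))
            if px is not None and px.size > 0:
                ring_med[j] = np.median(flat[px])
        out[f"{role}_nuc_med"] = nuc_med
        out[f"{role}_ring_med"] = ring_med
    return out


# ---------------------------------------------------------------------------
# fixed-cell classification
# ---------------------------------------------------------------------------

def valley_threshold(values: np.ndarray, bandwidth: str = "silverman",
                     n_grid: int = 512):
    """Threshold at the density minimum between the two modes of a bimodal
    log10-intensity distribution.

    Uses a fixed-bandwidth Gaussian KDE (Silverman's rule by default).
    Raises ``ValueError`` when fewer than two modes are found, instructing
    the caller to set a manual threshold.
    Returns the threshold on the original (linear) intensity scale.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v) & (v > 0)]
    logv = np.log10(v)
    kde = gaussian_kde(logv, bw_method=bandwidth)
    grid = np.linspace(logv.min(), logv.max(), n_grid)
    dens = kde(grid)
    # interior local maxima
    peaks = np.nonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    if peaks.size < 2:
        raise ValueError("distribution is unimodal; set a manual threshold")
    order = np.argsort(dens[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    valley = p1 + int(np.argmin(dens[p1:p2 + 1]))
    return float(10.0 ** grid[valley])


def classify_edu(records: pd.DataFrame, threshold: float | None = None,
                 min_cells: int = 200) -> pd.DataFrame:
    """Set ``edu_positive`` from EdU intensity (S-phase gate).

    Automatic mode requires ``min_cells`` records and a bimodal log-intensity
    distribution; the gate sits at the KDE valley between the two modes.
    Pass ``threshold`` for a manual override.  The chosen threshold is
    recorded in ``records.attrs['edu_threshold']``.
    """
    records = records.copy()
    if threshold is None:
        if len(records) < min_cells:
            raise ValueError(f"automatic thresholding needs >= {min_cells} cells")
        threshold = valley_threshold(records["edu"].to_numpy())
    records["edu_positive"] = records["edu"] > threshold
    records.attrs["edu_threshold"] = float(threshold)
    return records


def classify_prb(records: pd.DataFrame, threshold: float | None = None,
                 min_cells: int = 200, trb_floor: float = 1e-6) -> pd.DataFrame:
    """Set ``prb_positive`` from the p-Rb / total-Rb ratio.

    Cells with total Rb at or below ``trb_floor`` are excluded (reason
    ``low_trb``).  Same bimodal-valley rule as :func:`classify_edu`, applied
    to the ratio.
    """
    records = records.copy()
    if "excluded" not in records:
        records["excluded"] = False
        records["exclude_reason"] = ""
    low = records["trb"] <= trb_floor
    records.loc[low, ["excluded", "exclude_reason"]] = [True, "low_trb"]
    ratio = np.where(low, np.nan, records["prb"] / records["trb"].where(~low))
    records["prb_ratio"] = ratio
    ok = ~low
    if threshold is None:
        if ok.sum() < min_cells:
            raise ValueError(f"automatic thresholding needs >= {min_cells} cells")
        threshold = valley_threshold(records.loc[ok, "prb_ratio"].to_numpy())
    records["prb_positive"] = records["prb_ratio"] > threshold
    records.loc[low, "prb_positive"] = False
    records.attrs["prb_threshold"] = float(threshold)
    return records


# ---------------------------------------------------------------------------
# FISH puncta
# ---------------------------------------------------------------------------

def count_fish_puncta(fish_frame: np.ndarray, nuclei, pixel_size_um: float,
                      kernel_um: float = 4.0, dilation_um: float = 50.0,
                      k_mad: float = 5.0) -> pd.DataFrame:
    """Count mRNA puncta per cell within its dilated whole-cell territory.

    The FISH frame is white-top-hat filtered with a circular structuring
    element of *diameter* ``kernel_um`` (removes everything larger than a
    punctum, including any constant offset), thresholded at ``k_mad`` scaled
    MADs of the filtered background, and connected puncta are assigned to
    the cell whose nucleus is nearest, out to ``dilation_um``.  Cells whose
    50-um dilation disks overlap a neighbour's are excluded with reason
    ``overlap_neighbor`` (their counts are still reported).

    Returns one row per cell: ``label, fish_puncta, whole_cell_area_um2,
    excluded, exclude_reason``.
    """
    lab = nuclei.labels if isinstance(nuclei, LabelMap) else np.asarray(nuclei)
    frame = np.asarray(fish_frame, dtype=np.float64)
    radius_px = kernel_um / 2.0 / pixel_size_um
    if 2 * radius_px >= min(frame.shape):
        raise ValueError("top-hat kernel larger than the image")
    selem = disk(max(int(round(radius_px)), 1))
    filtered = white_tophat(frame, footprint=selem)

    bg = filtered[lab == 0]
    mad = np.median(np.abs(bg - np.median(bg))) * 1.4826
    thr = np.median(bg) + k_mad * max(mad, 1e-9)
    puncta_mask = filtered > thr
    puncta_lab, n_puncta = ndi.label(puncta_mask)

    # nearest-nucleus territory, clipped at dilation_um
    dist, (iy, ix) = ndi.distance_transform_edt(lab == 0, sampling=pixel_size_um,
                                                return_indices=True)
    owner = lab[iy, ix]
    owner[dist > dilation_um] = 0

    ids = np.unique(lab)
    ids = ids[ids != 0]
    counts = {int(i): 0 for i in ids}
    if n_puncta:
        pcy, pcx = zip(*ndi.center_of_mass(puncta_mask, puncta_lab,
                                           np.arange(1, n_puncta + 1)))
        for y, x in zip(pcy, pcx):
            o = owner[int(round(y)), int(round(x))]
            if o > 0:
                counts[int(o)] += 1

    # exclusion: a cell's unrestricted 50-um dilation overlapping another's
    # is equivalent to boundary-to-boundary distance < 2 * dilation_um
    excluded = _dilation_overlaps(lab, pixel_size_um, dilation_um)
    area = {int(i): float((owner == i).sum()) * pixel_size_um**2 for i in ids}
    rows = [dict(label=int(i), fish_puncta=counts[int(i)],
                 whole_cell_area_um2=area[int(i)],
                 excluded=bool(excluded[int(i)]),
                 exclude_reason="overlap_neighbor" if excluded[int(i)] else "")
            for i in ids]
    return pd.DataFrame(rows)


def _dilation_overlaps(lab: np.ndarray, ps: float, dilation_um: float) -> dict:
    """Flag cells whose ``dilation_um`` dilation disk meets another cell's.

    Two dilations overlap iff some pixel lies within ``dilation_um`` of both
    nuclei, i.e. the nuclei's edge-to-edge distance is < 2 x dilation_um.
    Computed exactly from per-cell distance transforms on padded crops.
    """
    ids = np.unique(lab)
    ids = ids[ids != 0]
    out = {int(i): False for i in ids}
    if ids.size < 2:
        return out
    objs = ndi.find_objects(lab)
    pad = int(np.ceil(2 * dilation_um / ps)) + 1
    ny, nx = lab.shape
    for i in ids:
        sl = objs[i - 1]
        y0, y1 = max(sl[0].start - pad, 0), min(sl[0].stop + pad, ny)
        x0, x1 = max(sl[1].start - pad, 0), min(sl[1].stop + pad, nx)
        crop = lab[y0:y1, x0:x1]
        dist = ndi.distance_transform_edt(crop != i, sampling=ps)
        near = (dist < 2 * dilation_um) & (crop != i) & (crop != 0)
        if near.any():
            out[int(i)] = True
    return out


def measure_fixed_field(stack, params=None) -> pd.DataFrame:
    """Full fixed-cell measurement: segment Hoechst, summarize channels,
    count FISH puncta if present, and return FixedCellRecord rows.

    Expects channel roles ``hoechst`` plus any of ``edu``, ``prb``, ``trb``,
    ``fish``.  Classification columns are left to :func:`classify_edu` /
    :func:`classify_prb`, which need cohort-level distributions.
    """
    from .segment import segment_fixed
    frame0 = stack.pixels[0]
    roles = stack.channel_roles
    hoechst = frame0[roles["hoechst"]]
    labels = segment_fixed(hoechst, stack.pixel_size_um, params=params)
    lab = labels.labels
    ids = np.unique(lab)
    ids = ids[ids != 0]
    if ids.size == 0:
        return pd.DataFrame(columns=["label", "x_um", "y_um"])
    cy, cx = zip(*ndi.center_of_mass(np.ones_like(lab), lab, ids))
    rec = pd.DataFrame({"label": ids.astype(int),
                        "x_um": np.asarray(cx) * stack.pixel_size_um,
                        "y_um": np.asarray(cy) * stack.pixel_size_um})
    for role in ("edu", "prb", "trb"):
        if role in roles:
            img = frame0[roles[role]].astype(np.float64)
            img = img - np.median(img[lab == 0])
            rec[role] = ndi.labeled_comprehension(img, lab, ids, np.median,
                                                  float, np.nan)
    if "fish" in roles:
        fish = count_fish_puncta(frame0[roles["fish"]], labels,
                                 stack.pixel_size_um)
        rec = rec.merge(fish, on="label", how="left")
    return rec
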