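# Methods

This note documents the models, algorithms, parameters, and design choices
behind `ktrcycle`, and what the synthetic-data validation does and does not
establish about real microscopy data.

## Sensor model and units

Kinase activity is read out as the cytoplasm-to-nucleus (C/N) fluorescence
ratio of a translocation sensor: the median intensity over a cytoplasmic
ring divided by the median over the nuclear pixels, both after background
correction.  The package adopts C/N = 1 as the unit of the classification
threshold; this is the natural scale of the ratio readout, not a calibrated
biochemical activity.  The CDK4/6 sensor carries a degenerate CDK2
phosphorylation site and partially reports CDK2 activity in S/G2, so
corrected CDK4/6 activity is `raw − α·CDK2` with α = 0.41 by default
(0.35 for lines with weaker cross-reporting).  `fit_bleedthrough`
re-estimates α as the OLS slope of the raw CDK4/6 sensor on the CDK2 sensor
over cells whose true CDK4/6 activity is expected to be ≈0 (saturating
CDK4/6 inhibition); it requires ≥50 points and a non-degenerate regressor.

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every other stage is validated.

**Cell-cycle structure.** G1 durations are lognormal (arithmetic mean and
CV configurable; default 10 h, CV 0.3 — lognormal captures the long right
tail of G1 while S and G2/M are tight); S and G2/M are normal truncated at
zero with small CV (defaults 8 h/CV 0.08 and 4 h/CV 0.10).  G1 + S + G2/M
equals the intermitotic time exactly.  Founders start at a uniformly random
cycle position; daughters inherit a fraction of the mother's H2B amount
drawn uniformly from 45–55 %, renormalized so the two fractions sum to ≤1.
H2B amount doubles linearly over the cycle and nuclear radius scales as the
square root of amount (constant chromatin concentration), so daughter
nuclei are smaller but equally bright — this is what makes the integrated
(area × median) H2B fraction the right mitosis statistic.

**Activity curves** are piecewise-smooth canonical shapes, not a
mechanistic ODE model — the pipeline needs controllable, verifiable
kinetics, not biology.  CDK2 resets to ~0.45 at anaphase, rises through 1
just before G1/S (at 95 % of G1), and reaches ~2 at the next mitosis;
quiescent cells wander below 0.6.  CDK4/6 activates within ~1 h of mitosis
to ~0.9, or is pinned at 0 under the CDK4/6i-saturated flag.  The rendered
raw CDK4/6 channel is `true + α·CDK2`.  The Cdt1 degron accumulates through
G1 (150→1000 a.u.), is degraded at S entry with a ~20-min half-life to a
60 a.u. floor, and re-accumulates from S/G2 at ~360 a.u./h; the Geminin
variant stays at 50 a.u. through G1 and accumulates linearly to mitosis.

**Kinematics.** Cells perform a reflected random walk (default 1 µm/frame
step).  Nuclei exclude each other: after each step, overlapping pairs are
pushed apart to 95 % of their summed radii (three relaxation sweeps).
Without exclusion, freely interpenetrating nuclei render as single merged
blobs that no segmentation could split, and tracking validation would be
impossible by construction.  Daughters appear one nuclear diameter apart on
opposite sides of the mother's last position.

**Rendering.** Nuclei are sigmoid-edged discs; KTR cytoplasm is an annulus
at `activity × nuclear intensity`, wide enough (6 µm) that the measurement
ring never touches the cytoplasm edge rolloff.  The camera model is
`bias × (signal + offset) + N(0, σ)` with a low-order polynomial
illumination surface — matching the flat-field correction's multiplicative
assumption.  Fixed-cell fields render Hoechst nuclei, bimodal EdU and
p-Rb/t-Rb intensities (EdU modes at log10 2.0 ± 0.1 and 3.5 ± 0.15; p-Rb
ratio modes ±4 SD either side of the decision boundary by default), and
Gaussian FISH puncta at exactly the requested per-cell counts with ≥6 µm
pairwise separation.

**What the generator does not emulate:** photobleaching, focus drift,
apoptosis and cell loss, intensity heterogeneity between cells beyond ±10 %,
segmentation-hostile morphologies (lobed or touching-and-deforming nuclei),
and 3D structure (FISH z-stacks are assumed max-projected upstream).
Passing the synthetic benchmarks therefore demonstrates the correctness of
the algorithms under the stated imaging model, not robustness to every
real-world artifact.

## Segmentation

Live frames: foreground mask at `median + max(10·MAD, 0.25·(max−median))`
of the lightly smoothed H2B frame (the MAD floor rejects blank frames; the
relative floor cuts the dim halo around nuclei).  Markers come from
scale-space Laplacian-of-Gaussian blob detection over nuclear radii
4–15 µm, run at half resolution (markers only need ~2-px accuracy);
duplicate blobs within one minimal radius are merged.  Watershed runs on
the negative Euclidean distance transform, placing splits along the
geometric neck between touching nuclei.  Regions that remain merged —
elongated, with two or more well-separated EDT maxima — are re-split, and
pieces below the 30 µm² area floor veto the split.  Objects outside
30–400 µm² are removed.

Fixed frames: the threshold sits at the maximum positive second difference
of the *log*-counts of the smoothed log10-intensity histogram, beyond the
background mode — the elbow where the background population runs out.  (On
raw counts the curvature maximum sits only ~2 SD into the background tail;
on log-counts it reaches the foot of the peak, ~3.5 SD, which keeps
background contamination negligible.)  Unimodal or flat histograms fall
back to a percentile threshold with a warning.

Rings: each cell's annulus is the set of pixels whose EDT distance from its
nucleus lies in (0.65, 3.25] µm, computed independently per cell on padded
crops; measurement rings exclude nuclear pixels of every cell.  Cells whose
raw annuli intersect are flagged `ring_overlap`, border-truncated cells
`border`; both are excluded from ratio quantification (their ratios are
NaN).  Negative values after background subtraction are retained — clipping
would bias the median-based ratios.

## Tracking and lineage

Linking solves an optimal assignment (Hungarian) per frame pair: candidate
links are gated at `max_step_um` from the track's last position and scored
by distance to the motion-predicted position (last position + half the
last displacement).  The global optimum resolves "deflection" conflicts
where greedy nearest-neighbour linking would steal a competitor's
detection.  Gap bridging joins track ends to later starts across ≤2 missing
frames (greedy, by displacement), inserting interpolated `gap_filled` rows
with NaN intensities.

Mitoses: a division is the replacement of one nucleus by two adjacent
(≤25 µm) nuclei whose integrated H2B (area × median) fractions of the
mother's last value are each "about" 45–55 %.  The configured window is
padded by a ±0.05 tolerance: measured fractions carry area-estimation
noise, and renormalization of daughter draws pushes some true fractions
slightly below 0.45, while grossly asymmetric splits (0.70/0.30) remain
rejected.  Two geometries are recognized: mother track ends and two tracks
start, or the linker carries the mother's identity onto one daughter — then
the continuing track shows an H2B drop into the daughter range and is split
at that frame (a track may divide repeatedly; splits chain).  Three or more
candidate daughters produce a warning and no event.

## Phase calling and fate classification

`classify_fate` implements the sustained-activity rule literally: a
contiguous run of frames with CDK2 strictly above threshold, of total
duration strictly greater than 2 h (≥11 frames at 12 min), inside the
30–48 h window; one sub-threshold frame breaks the run; gap-filled frames
count only when both flanking measured frames are above threshold; cells
not covering the window are unclassified.  The same rule under
drug-combination conditions yields the persister label.  An exhaustive
contiguous-window scan serves as the independent oracle in the tests.

`call_phases` (Cdt1): G1/S is the first sustained (3-frame) fall of the
median-smoothed trace below 0.5× its running pre-drop maximum, walked back
to the onset of decline; S/G2 is the first sustained rise above 2× the
trough level after the trough, back-extrapolated along the rising limb to
the trough level (the crossing itself is biased late by about one frame,
and a plateau walk-back is fragile to noise).  For Geminin, G1/S is the
back-extrapolated onset of sustained accumulation and no S/G2 is defined.
All constants (`f_drop = 0.5`, `r_rise = 2.0`, `k = 3` frames, 3-frame
median smoothing) are exposed.

Durations derive from the called boundaries and the lineage, so additivity
(G1 + S + G2M = IMT) is structural.  Summary tables report n, mean, median,
SD, and the normal-approximation 95 % CI (mean ± 1.96·SE; NaN for single
cells).

## Fixed-cell readouts

EdU and p-Rb gates sit at the density minimum between the two largest modes
of a Silverman-bandwidth Gaussian KDE of the log10 intensity (ratio
p-Rb/t-Rb for Rb phosphorylation); automatic gating requires ≥200 cells and
a detectable second mode, otherwise a manual threshold must be supplied.
FISH puncta: white top-hat with a circular structuring element of 4 µm
diameter (removes any structure larger than a punctum, hence exact
invariance to additive offsets), thresholded at 5× the scaled MAD of the
filtered background; connected components are assigned to the nearest
nucleus within 50 µm.  Cells whose 50-µm dilation disks overlap a
neighbour's — equivalently, nuclei closer than 100 µm edge-to-edge — are
excluded (`overlap_neighbor`), with counts still reported.

## Live-to-fixed transfer

Registration maximizes the phase cross-correlation of the live H2B and
fixed Hoechst channels with 1/20-px subpixel refinement, and verifies the
aligned normalized correlation exceeds 0.2 (else the fields do not
correspond).  Matching is mutual-nearest-centroid, one-to-one, within 10 µm
by default; non-mutual candidates stay unmatched (`ambiguous`).  Matched
fixed records inherit time-since-anaphase (movie end − anaphase) and final
CDK2 activity; binned summaries use 1-h time bins and 10 quantile bins of
CDK2 with normal-approximation 95 % CIs.  Fixed channels are rendered
independently of the live reporters, mirroring the photobleaching step that
precedes fixed staining.

## Dose-response

`ic50_from_sphase` fits `bottom + (top−bottom)/(1+(d/IC50)^h)` to S-phase
fractions relative to the drug-naive control, in linear dose (dose 0
anchors the top plateau), with bounded least squares; it refuses data with
no detectable inhibition.  The IC50 CI is the ±1.96·SE Wald interval from
the fit covariance.

## Problem sizes and numerical choices

The validation suite runs at sizes chosen to give stable statistics on a
single CPU: 10,000 random traces for the classification oracle; ~1,200
fully observed cycles for phase calling; a 100-founder, 240-frame movie
(growing to ~470 cells) for tracking; and two 42-h conditions of 56 and 80
founders (≈450 and 280 tracked cells) for the end-to-end 3× G1 effect.
Assignment ties break deterministically (Hungarian solution; stable sorts;
smaller displacement first in bridging).  All randomness flows from a
single integer seed per run; identical seeds give bit-identical tables and
images.

## Known limitations

The tracker has no explicit apoptosis model; vanished cells simply end
their tracks.  The mitosis rule cannot see divisions whose daughters leave
the field within a frame.  The histogram-curvature threshold and the degron
boundary constants are documented operationalizations of methods usually
tuned per dataset; on real data they should be inspected against the
echoed thresholds in the logs.  Phase-duration means from finite movies are
right-censored (the longest cycles never complete on camera), which biases
condition contrasts slightly toward 1; the end-to-end benchmark quantifies
this at its stated sizes.
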