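# ktrcycle

Single-cell cell-cycle analysis for kinase-translocation-reporter (KTR)
time-lapse imaging, with a ground-truthed synthetic-movie generator.

## The problem

Live-cell studies of CDK4/6-inhibitor response track thousands of individual
cells through the cell cycle: an H2B nuclear marker for segmentation and
tracking, KTR sensors whose cytoplasm-to-nucleus translocation reads out
CDK4/6 and CDK2 activity, and a fluorescent Cdt1 (or Geminin) degron whose
degradation and re-accumulation mark the G1/S and S/G2 transitions.  After
the movie, the same fields can be fixed and stained (EdU, phospho-Rb, mRNA
FISH), and each fixed cell inherits its live history.  `ktrcycle` implements
this analysis chain as a tested Python library:

- **simulate** — generate dividing/quiescent cell populations with known
  phase boundaries, render them as multichannel movies and fixed-cell
  fields, so every downstream stage has an oracle;
- **segment** — flat-field correction, background subtraction (50th
  percentile of non-nuclear pixels), LoG + watershed nuclear segmentation
  (live H2B), histogram-curvature thresholding (fixed Hoechst), and
  cytoplasmic sampling rings 0.65–3.25 µm outside the nuclear boundary;
- **track** — optimal-assignment frame linking with motion prediction, gap
  bridging, and mitosis detection by the appearance of two adjacent
  daughters each carrying ~45–55 % of the mother's integrated H2B signal;
- **quantify** — C/N activity ratios, the CDK4/6 bleed-through correction,
  EdU / p-Rb bimodal gating, and top-hat FISH puncta counting;
- **cycle_metrics** — proliferative-fate classification, anaphase
  alignment, degron-based phase calling, duration statistics, and 4PL IC50
  fitting;
- **livefixed** — registration and matching of the final live frame to the
  fixed-cell image.

## The core quantities

Kinase activity is the cytoplasm/nucleus sensor ratio; ratios are median
intensities over the cytoplasmic ring and the nuclear pixels, both
background-corrected.  Because the CDK4/6 sensor carries a degenerate CDK2
motif and partially reports CDK2 activity in S/G2,

```
CDK4/6 activity = (CDK4/6 reporter) − α · (CDK2 reporter),   α = 0.41
```

(α = 0.35 for cell lines with weaker cross-reporting; `fit_bleedthrough`
re-estimates α by regression on CDK4/6-inhibited cells).  A cell is
classified **proliferating** when CDK2 > 1 continuously for more than 2 h
within the 30–48 h analysis window; under drug combinations the same rule
yields the **persister** label.  Phase durations follow from the degron
boundaries: G1 = G1/S − anaphase, S = S/G2 − G1/S, G2/M = next anaphase −
S/G2, and G1 + S + G2/M equals the intermitotic time by construction.

## Worked example

`examples/03_track_and_lineage.py` simulates a 12-cell, 24-hour movie,
renders and processes every frame, and scores the result against the
generator's ground truth:

```
simulated 38 cells over 121 frames; 13 true divisions
pipeline found 39 tracks and 13 division events
frame-to-frame link recovery: 99.9% (2135/2137)
division recall: 100.0%, false events: 0
  mitosis at frame 21: mother 9 -> daughters 27/12 (H2B fractions 0.53/0.48)
```

Each mitosis line reports the anaphase frame and the daughters' measured
shares of the mother's integrated H2B signal — inside the 45–55 % window
that distinguishes true divisions from segmentation artifacts.  The other
examples cover fate classification (01), per-cell activity measurement
(02), phase durations under drug-resistance presets (04), fixed-cell
EdU/p-Rb/FISH readouts (05), IC50 fitting (06), and live-to-fixed matching
(07); each prints the measured quantities next to the generator's truth.

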