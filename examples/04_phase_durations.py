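"""Call G1/S and S/G2 boundaries from Cdt1-degron traces and summarize
phase durations.

The Cdt1 fragment accumulates through G1, is degraded at S entry, and
re-accumulates from S/G2; its drop and re-rise mark the two boundaries.
Durations are G1 = boundary minus anaphase, etc., so G1 + S + G2M equals
the intermitotic time by construction.  Two conditions are compared: the
drug-maintained resistant preset has a ~2.5x longer generator G1 mean.
"""

import numpy as np

from ktrcycle import SimConfig, simulate_traces
from ktrcycle.cycle_metrics import annotate_phases, duration_stats

frames = []
for condition in ("parental", "resistant_drug_maintained"):
    cfg = SimConfig.for_condition(condition, n_cells=80, duration_hours=60.0,
                                  rng_seed=5)
    traces, truth = simulate_traces(cfg)
    obs = truth.cells[(truth.cells.birth_h >= 0)
                      & np.isfinite(truth.cells.division_h)
                      & (truth.cells.division_h < cfg.duration_hours)]
    ann = annotate_phases(
        traces,
        anaphase_times=obs.set_index("cell_id").birth_h.to_dict(),
        division_times=obs.set_index("cell_id").division_h.to_dict())
    ann["group"] = condition
    frames.append(ann)

import pandas as pd

stats = duration_stats(pd.concat(frames), group_col="group")
print(stats.to_string(index=False,
                      float_format=lambda v: f"{v:.2f}"))
g1 = stats[stats.metric == "g1_h"].set_index("group")["mean"]
print(f"\nG1 mean ratio (resistant / parental): "
      f"{g1['resistant_drug_maintained'] / g1['parental']:.2f} "
      f"(generator: 2.50)")
# S and G2M means should match across conditions; only G1 is stretched.
# The measured ratio runs a little below the generator's because cells with
# the longest G1 have not completed a full observable cycle by the end of
# the movie (right-censoring) -- longer acquisitions close the gap.
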