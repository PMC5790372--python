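"""DICS source imaging of envelope coherence: parameter recovery.

For each subject of a reduced cohort, beamforms the 4-9 Hz envelope
coherence onto the source grid (6 +/- 2 and 7 +/- 2 Hz windows averaged)
and measures how far the map maximum lies from the nearest planted
source. Writes results/source_localization.csv.
"""

import csv
from pathlib import Path

import numpy as np

from speechtrack.beamformer import source_coherence_map
from speechtrack.simulate import (SimulationConfig, SimulationContext,
                                  condition_subset, synth_cohort)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SimulationConfig(n_trials_per_condition=40,
                           n_subjects_per_group={"EB": 4, "SI": 4},
                           conditions=("nat", "1ch"), n_sensors=64,
                           grid_spacing=0.012, seed=SEED)
    ctx = SimulationContext(cfg)
    ds = synth_cohort(cfg, ctx=ctx)

    planted = {lab: ctx.grid.masked_points[ctx.grid.nearest_inside(pos)]
               for lab, pos in cfg.source_positions.items()}
    rows = []
    for subj in ds.subjects:
        for cond in cfg.conditions:
            m = source_coherence_map(condition_subset(subj, cond), ctx.leadfield)
            peak = m.argmax_point()
            # the coupled sources for this subject x condition
            active = [lab for lab in cfg.source_positions
                      if cfg.coupling_alpha[(subj.group, cond, lab)] > 0]
            dists = {lab: 1000 * np.linalg.norm(peak - planted[lab]) for lab in active}
            nearest = min(dists, key=dists.get)
            rows.append((subj.subject_id, subj.group, cond, nearest,
                         round(dists[nearest], 1), round(m.values.max(), 4)))

    OUT.mkdir(exist_ok=True)
    with open(OUT / "source_localization.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["subject", "group", "condition", "nearest_planted_source",
                    "distance_mm", "max_z"])
        w.writerows(rows)

    errs = [r[4] for r in rows]
    within = sum(e <= 1000 * cfg.grid_spacing for e in errs)
    print(f"{within}/{len(rows)} subject x condition maps peak within one "
          f"grid step ({1000 * cfg.grid_spacing:.0f} mm) of a planted source; "
          f"median error {np.median(errs):.1f} mm.")
    print(f"Table: {OUT / 'source_localization.csv'}")


if __name__ == "__main__":
    main()
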