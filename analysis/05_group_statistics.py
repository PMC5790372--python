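"""Group-level TFCE permutation inference on the interaction contrast.

Tests the headline contrast shape [(nat_EB - 1ch_EB) - (nat_SI -
1ch_SI)] on a synthetic cohort where extra envelope coupling is planted
at the calcarine locus only in the EB group during intelligible (nat)
speech, and checks that the most significant voxel recovers the planted
locus. Writes results/group_statistics.csv.
"""

import csv
from pathlib import Path

import numpy as np

from speechtrack.beamformer import source_coherence_map
from speechtrack.simulate import (SimulationConfig, SimulationContext,
                                  condition_subset, synth_cohort)
from speechtrack.stats import (TfceParams, interaction_contrast, peak_voxel,
                               permutation_fwe)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SimulationConfig(n_trials_per_condition=40,
                           n_subjects_per_group={"EB": 8, "SI": 8},
                           conditions=("nat", "1ch"), n_sensors=64,
                           grid_spacing=0.012, seed=SEED)
    ctx = SimulationContext(cfg)
    ds = synth_cohort(cfg, ctx=ctx)

    maps = {}
    for subj in ds.subjects:
        for cond in cfg.conditions:
            m = source_coherence_map(condition_subset(subj, cond), ctx.leadfield)
            maps[(subj.subject_id, subj.group, cond)] = m.values
    da, db = interaction_contrast(
        [v for (s, g, c), v in maps.items() if g == "EB" and c == "nat"],
        [v for (s, g, c), v in maps.items() if g == "EB" and c == "1ch"],
        [v for (s, g, c), v in maps.items() if g == "SI" and c == "nat"],
        [v for (s, g, c), v in maps.items() if g == "SI" and c == "1ch"])
    res = permutation_fwe(da, db, design="independent",
                          params=TfceParams(n_steps=25), n_perms=500,
                          seed=SEED, grid=ctx.grid, fwhm_mm=15.0)

    cs = ctx.grid.masked_points[ctx.grid.nearest_inside(cfg.source_positions["CS"])]
    best_idx = peak_voxel(res)
    best = ctx.grid.masked_points[best_idx]
    dist_mm = 1000 * np.linalg.norm(best - cs)
    n_sig = int((res.fwe_p <= 0.05).sum())

    OUT.mkdir(exist_ok=True)
    with open(OUT / "group_statistics.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["quantity", "value"])
        w.writerows([
            ("min_fwe_p", res.fwe_p.min()),
            ("n_voxels_fwe_p_le_0.05", n_sig),
            ("peak_distance_to_planted_cs_mm", round(dist_mm, 1)),
            ("peak_t", round(float(res.observed_t[best_idx]), 3)),
            ("n_permutations", res.n_perms),
        ])

    print(f"Interaction contrast: min FWE p = {res.fwe_p.min():.4f} over "
          f"{len(res.fwe_p)} voxels ({n_sig} voxels at p <= 0.05).")
    print(f"Most significant voxel lies {dist_mm:.0f} mm from the planted "
          f"calcarine locus (grid step {1000 * cfg.grid_spacing:.0f} mm).")
    print(f"Table: {OUT / 'group_statistics.csv'}")


if __name__ == "__main__":
    main()
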