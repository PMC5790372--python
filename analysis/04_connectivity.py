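"""Occipito-temporal connectivity: PLV and directed phase slope index.

Extracts LCMV virtual sensors at the planted CS (calcarine) and STG
(auditory) loci for each subject, computes theta-band (4-8 Hz)
phase locking between them and the jackknife-normalized phase slope
index CS -> STG, and validates the PSI sign convention on directed
pairs with known lag. Writes results/connectivity.csv.
"""

import csv
from pathlib import Path

import numpy as np

from speechtrack.beamformer import lcmv_virtual_sensor
from speechtrack.connectivity import band_mean, phase_slope_index, plv_spectrum
from speechtrack.simulate import (SimulationConfig, SimulationContext,
                                  condition_subset, directed_pair, synth_cohort)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SimulationConfig(n_trials_per_condition=40,
                           n_subjects_per_group={"EB": 4, "SI": 4},
                           conditions=("nat", "1ch"), n_sensors=64,
                           grid_spacing=0.012, seed=SEED)
    ctx = SimulationContext(cfg)
    ds = synth_cohort(cfg, ctx=ctx)
    i_cs = ctx.grid.nearest_inside(cfg.source_positions["CS"])
    i_stg = ctx.grid.nearest_inside(cfg.source_positions["STG"])

    rows = []
    for subj in ds.subjects:
        nat = condition_subset(subj, "nat")
        vs_cs = lcmv_virtual_sensor(nat, ctx.leadfield, i_cs, label="CS")
        vs_stg = lcmv_virtual_sensor(nat, ctx.leadfield, i_stg, label="STG")
        plv_theta = float(np.tanh(band_mean(plv_spectrum(vs_cs, vs_stg), 4.0, 8.0)))
        psi = phase_slope_index(vs_cs, vs_stg, band_center=6.0, halfwidth=5.0)
        rows.append((subj.subject_id, subj.group, round(plv_theta, 4),
                     round(psi.psi_norm, 3)))

    # sign-convention validation: known 20 ms lead of x1 over x2
    hits = sum(phase_slope_index(*directed_pair(cfg, 20.0, n_trials=60,
                                                seed=SEED * 100 + k)).psi_norm > 0
               for k in range(50))

    OUT.mkdir(exist_ok=True)
    with open(OUT / "connectivity.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["subject", "group", "plv_theta_cs_stg", "psi_norm_cs_to_stg"])
        w.writerows(rows)

    eb = [r[2] for r in rows if r[1] == "EB"]
    si = [r[2] for r in rows if r[1] == "SI"]
    print(f"Theta PLV (CS-STG, nat): EB mean {np.mean(eb):.3f}, "
          f"SI mean {np.mean(si):.3f}.")
    print(f"PSI direction recovery on 20 ms directed pairs: {hits}/50 positive "
          f"(positive = first series leads).")
    print(f"Table: {OUT / 'connectivity.csv'}")


if __name__ == "__main__":
    main()
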