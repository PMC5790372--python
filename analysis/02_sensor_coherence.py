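"""Sensor-level cerebro-acoustic coherence spectrum of a synthetic cohort.

Simulates a reduced cohort, computes each subject's envelope-coherence
spectrum (1-30 Hz, Fisher z) across all sensors, and locates the
tracking peak. Writes results/sensor_coherence.csv.
"""

import csv
from pathlib import Path

import numpy as np

from speechtrack.coherence import peak_frequency, sensor_coherence_spectrum
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

    rows = []
    spectra = []
    for subj in ds.subjects:
        for cond in cfg.conditions:
            spec = sensor_coherence_spectrum(condition_subset(subj, cond))
            rows.append((subj.subject_id, subj.group, cond,
                         peak_frequency(spec), spec.z.max()))
            spectra.append(spec.z)
    mean_z = np.mean(spectra, axis=0)
    freqs = np.arange(1.0, 31.0)

    OUT.mkdir(exist_ok=True)
    with open(OUT / "sensor_coherence.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["subject", "group", "condition", "peak_hz", "max_z"])
        w.writerows(rows)
    with open(OUT / "sensor_coherence_spectrum.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["freq_hz", "mean_z"])
        w.writerows(zip(freqs, mean_z))

    peaks = [r[3] for r in rows]
    print(f"Median tracking peak across {len(rows)} subject x condition "
          f"spectra: {np.median(peaks):.1f} Hz (planted syllable rate 7 Hz).")
    print(f"Grand-mean z-coherence at 7 Hz: {mean_z[freqs == 7.0][0]:.3f} vs "
          f"{np.median(mean_z):.3f} at the median frequency.")
    print(f"Tables: {OUT / 'sensor_coherence.csv'}, "
          f"{OUT / 'sensor_coherence_spectrum.csv'}")


if __name__ == "__main__":
    main()
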