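# speechtrack

Cerebro-acoustic speech-envelope tracking at desk scale: a tested
pipeline for asking *where and how strongly neural activity follows the
syllabic rhythm of speech*, and whether that tracking reorganizes across
listener groups and intelligibility conditions.

The package is written for auditory/neuroimaging researchers who want
every stage of an envelope-tracking MEG analysis — stimulus
manipulation, envelope extraction, preprocessing, source imaging,
connectivity, and group statistics — as importable, individually tested
operations with exact or simulation-based oracles, plus a synthetic-data
generator that plants known effects so the whole chain can be validated
by parameter recovery.

## What it computes

- **Noise vocoding** (`speechtrack.audio`): band-pass a stimulus into
  *n* logarithmically spaced bands, replace each band's fine structure
  with envelope-modulated Gaussian noise, RMS-match and sum. One band
  destroys intelligibility; eight preserve it. Both keep the slow
  amplitude envelope.
- **Speech envelope** (`speechtrack.envelope`): nine zero-phase
  Butterworth bands between 100 and 1000 Hz, spaced equally along the
  basilar membrane via the Greenwood map F(x) = A(10^{ax} − k); the
  envelope is the summed Hilbert analytic amplitude, scaled to max 1.
- **Preprocessing** (`speechtrack.preprocess`): 1 Hz high-pass, 170 Hz
  low-pass, 50/100/150 Hz line filters, downsampling to 256 Hz, 1 s
  epochs, and robust-z variance/range artifact screening. The envelope
  passes the identical chain so epochs stay aligned.
- **Cerebro-acoustic coherence** (`speechtrack.coherence`):
  Hanning-tapered cross-spectra of the 1 s epochs on the integer-Hz grid
  1–30 Hz; coherence C(f) = |⟨S_xy⟩| / √(⟨S_xx⟩⟨S_yy⟩), variance-
  stabilized as z = atanh C.
- **Source imaging** (`speechtrack.forward`, `speechtrack.beamformer`):
  analytic spherical-conductor leadfields on a regular 3-D grid (radial
  dipoles exactly silent — a built-in oracle) and DICS spatial filters
  w = S⁻¹Lη / (ηᵀLᵀS⁻¹Lη) imaging envelope coherence in the 6±2 and
  7±2 Hz windows, averaged into one 4–9 Hz map; LCMV + SVD for
  virtual-sensor time series.
- **Connectivity** (`speechtrack.connectivity`): phase-locking value
  (0–50 Hz, 2 s zero-padding) and the jackknife-normalized phase slope
  index Ψ = Im Σ_f C*(f) C(f+δf), whose sign gives the lead/lag
  direction between two virtual sensors.
- **Group inference** (`speechtrack.stats`): pseudo-t maps with 15 mm
  FWHM variance smoothing, threshold-free cluster enhancement
  TFCE(v) = Σ_h e(h)^E h^H dh, and max-statistic permutation FWE
  correction for independent (group) and dependent (condition) designs,
  including the interaction contrast
  [(nat_EB − 1ch_EB) − (nat_SI − 1ch_SI)].
- **Synthetic study** (`speechtrack.simulate`): speech-like stimuli
  (jittered 7 Hz syllable trains on noise carriers), cortical sources
  s(t) = α·g(env_θ(t−τ)) + √(1−α²)·n(t) coupled to the 4–9 Hz envelope
  component with known strength α and lag τ, projected through the
  sphere model onto a hemispheric magnetometer array at a chosen SNR,
  for a two-group (EB/SI) × three-condition (nat/8ch/1ch) cohort with
  embedded ground truth.

## Worked example

```python
import numpy as np
from speechtrack.simulate import (SimulationConfig, SimulationContext,
                                  condition_subset, synth_subject)
from speechtrack.coherence import peak_frequency, sensor_coherence_spectrum
from speechtrack.beamformer import source_coherence_map

cfg = SimulationConfig(n_trials_per_condition=60, seed=5)
ctx = SimulationContext(cfg)             # geometry, leadfield, stimuli
subj = synth_subject(cfg, "EB", 123, ctx=ctx)
nat = condition_subset(subj, "nat")

spec = sensor_coherence_spectrum(nat)    # 1-30 Hz envelope coherence
print(peak_frequency(spec), round(spec.z.max(), 2))

m = source_coherence_map(nat, ctx.leadfield)   # DICS 4-9 Hz image
err = np.linalg.norm(m.argmax_point() - np.array(cfg.source_positions["STG"]))
print(m.band_label, round(1000 * err, 1))
```

prints

```
7.0 1.46
4-9 Hz 4.6
```

meaning the sensor-level coherence spectrum peaks at the planted 7 Hz
syllable rate (max Fisher-z 1.46), and the 4–9 Hz DICS map maximum lies
4.6 mm — within one 8 mm grid step — of the planted auditory source.

The numbered drivers in `analysis/` run the full study narrative
(stimulus construction → sensor coherence → source localization →
connectivity → group statistics) and write their tables under
`results/`:

```bash
python analysis/01_stimuli_and_vocoding.py
python analysis/02_sensor_coherence.py
...
```

A YAML-configurable end-to-end run with a provenance manifest is
available as `speechtrack pipeline run config.yaml` (see
`speechtrack --help` for the `vocode`, `envelope`, and `simulate`
subcommands).

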