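# Methods

This note documents the models, estimators, numerical choices and
limitations of the `speechtrack` pipeline, in the order data flows
through it.

## Stimuli and vocoding

`synth_stimulus` emulates the amplitude statistics of narrated speech,
not its phonetics: a Gaussian noise carrier band-limited to 100–9000 Hz
is multiplied by a syllable-train modulator — gamma-shaped bursts
(shape 2, width ≈ half a syllable period) at a mean rate of 7 Hz with
15% CV inter-onset jitter — and peak-normalized. 7 Hz is the syllabic
rate of fluent speech; the jitter spreads the modulation spectrum over
roughly 4–9 Hz, which is what makes the theta-band analysis windows
meaningful. Rates ≥ 20 Hz are rejected as outside the speech-like
regime.

The channel vocoder splits the input into n logarithmically spaced
bands between 70 and 9000 Hz (band_lo/band_hi and the 30 Hz envelope
cutoff are package defaults in the Shannon vocoder tradition; the range
and cutoff are not dictated by any measurement), extracts each band's
envelope by half-wave rectification + zero-phase 4th-order Butterworth
low-pass, modulates a seeded band-limited noise carrier, RMS-matches
each synthesized band to its analysis band, and sums. The RMS match is
exact per band before summation (exposed via `vocode_bands`); after
summation, re-filtering the output through the analysis bands shows a
few percent cross-band leakage through the 4th-order slopes, which is
expected and harmless. Inside the vocoder the classic
rectify-and-smooth envelope is used (not Hilbert), mirroring hardware
channel vocoders; the Hilbert envelope is reserved for the
cerebro-acoustic reference signal below.

## Speech envelope

The reference envelope band-passes the stimulus into nine 4th-order
Butterworth bands between 100 and 1000 Hz applied forward-backward
(zero phase), with edges equally spaced in cochlear position under the
human Greenwood map F(x) = A(10^{a·x} − k), A = 165.4 Hz, a = 2.1,
k = 0.88. The envelope is the sum of the bands' analytic (Hilbert)
amplitudes, scaled to a maximum of 1. It is computed on the whole
stimulus before epoching so Hilbert edge effects stay at stimulus
boundaries. The envelope is then passed through exactly the same filter
chain and resampling as the sensor data — including the line-noise
filters, an interpretation we adopt for "processed identically" — so
that envelope and sensor epochs remain sample-aligned.

## Preprocessing

Zero-phase 4th-order Butterworth high-pass at 1 Hz and low-pass at
170 Hz (orders are package defaults; only the cutoffs are prescribed),
then line-noise removal at 50/100/150 Hz implemented as a least-squares
fit-and-subtract of each stationary sinusoid (a DFT filter). This is
exactly zero-phase and linear and avoids the 1-second ring-in a
1 Hz-wide IIR notch would need. Downsampling to 256 Hz uses polyphase
resampling after an extra anti-alias low-pass at 0.8 × (target/2)
≈ 102 Hz, because the 128–170 Hz band would otherwise alias. Epochs are
contiguous non-overlapping 1 s segments (trailing partial discarded).

Artifact screening replaces interactive inspection with a fully
automatic rule: per trial × channel, variance and peak-to-peak range
are computed; a trial (or channel) is rejected when the robust z-score
(median/MAD) of its mean metric exceeds z_thresh (default 5). The
screen is idempotent on clean data and recovers planted amplitude
outliers in tests.

## Coherence

Each 1 s epoch is Hanning-tapered and Fourier-transformed; with 1 s
epochs the native resolution is 1 Hz and the analysis grid is the
integer bins 1–30 Hz (no implicit padding — requesting finer steps is
an error). Cross-spectra are averaged across trials and coherence is
the magnitude form |⟨S_xy⟩| / √(⟨S_xx⟩⟨S_yy⟩), Fisher z-transformed
with atanh. Perfect coherence maps to +inf and is surfaced, not
clipped. The estimator is verified to 1e-10 against an explicit-DFT
brute-force implementation, and its small-sample null bias matches the
Rayleigh expectation √π/(2√n).

## Forward model

Sensors are ideal point magnetometers on a Fibonacci lattice over the
upper hemisphere (default 102 at 12 cm radius), radially oriented.
Sources live on an axis-aligned grid (default 8 mm) masked to
‖p‖ < 0.9 × conductor radius (9 cm). Fields use the closed-form
homogeneous-sphere solution; in this geometry radial dipoles and
central dipoles are *exactly* silent and the measured (radial) field
component equals the primary-current term — these identities are the
model's test oracles, and the far field converges to the free-space
dipole form. Units are SI throughout (m, T, A·m); simulated dipoles
default to 10 nAm. A realistic-anatomy (single-shell/BEM) model would
change leadfields but not the beamformer code, which only consumes an
`L` matrix per grid point.

## Beamforming

DICS builds, per grid point, a unit-gain minimum-variance filter from
the real part of the band-averaged CSD, regularized by λ = 5% of mean
sensor power (a common default, exposed as config). Because a sphere is
blind to radial dipoles, the 3×3 matrix LᵀS⁻¹L has rank 2; the scalar
filter uses the max-output-power orientation restricted to the visible
subspace (the eigenvector with the smallest *visible* eigenvalue), and
vector filters use the pseudo-inverse, giving unit gain on the
tangential plane. Source coherence maps are computed per window (6±2,
7±2 Hz), z-transformed, then averaged — averaging z rather than raw
coherence, consistent with the atanh normalization applied before
imaging. LCMV uses the trial-averaged covariance (one common filter for
all trials), applies it to single trials, and reduces the three
orientation components to one series via the dominant left singular
vector of the concatenated 3×time matrix; the sign is fixed by making
the largest-magnitude sensor weight positive. Localization bias is
within one grid step for tangential sources at 0.3–0.8 × conductor
radius in the acceptance sweep.

## Connectivity

PLV: per-trial spectra of the 1 s virtual-sensor epochs, Hanning-
tapered and zero-padded to 2 s (0.5 Hz grid, 0–50 Hz); the per-trial
cross-spectrum is normalized to a unit phasor and PLV is the magnitude
of its trial mean, z-transformed with atanh. Zero-amplitude trial/bin
pairs are excluded with a recorded count.

PSI uses the same spectral pipeline: complex coherency C(f), then
Ψ = Im Σ_f C*(f) C(f + δf) over the band (default center 6 Hz,
halfwidth 5 Hz, clipped at 1 Hz; δf = one 0.5 Hz bin), normalized by
the delete-one-trial jackknife standard error. Positive Ψ means the
first series temporally leads, a convention fixed by delayed-copy
simulations. Two caveats are worth knowing. First, Ψ is exactly
antisymmetric and exactly zero for zero lag. Second, under strict
independence the coherency is ≈ 0 and Ψ becomes a degenerate
(quadratic) statistic; the delete-1 jackknife then overestimates its
standard deviation by roughly √2, so |Ψ/SE| > 2 occurs in well under
5% of null runs. The normalized PSI is therefore conservative at the
null — fine for direction inference, but its null distribution should
not be treated as standard normal.

## Group statistics

Voxelwise contrasts use pseudo-t statistics: the (pooled or paired)
variance map is Gaussian-smoothed at 15 mm FWHM before forming t,
suppressing high-spatial-frequency noise in beamformer images;
fwhm = 0 recovers the textbook t exactly. Smoothing is mask-normalized
so the sphere boundary does not bleed zeros inward. TFCE integrates
e(h)^E · h^H · dh with canonical E = 0.5, H = 2, 26-connectivity, and
dh = max|t|/n_steps (n_steps = 100 default; reduced-scale studies use
25 — the permutation ranking is insensitive to the step count since dh
is frozen across permutations). Negative values are enhanced on the
negated map and re-negated.

FWE correction uses the permutation maximum statistic: group-label
shuffles for independent designs, sign flips of within-subject
condition differences (equivalent to condition swaps) for dependent
ones; when fewer distinct permutations exist than requested they are
enumerated exhaustively with a warning. p(v) = (1 + #{null max ≥
|TFCE(v)|}) / (1 + n_perms), two-sided via |TFCE|. With a strong
effect, many voxels sit at the permutation floor 1/(1 + n_perms);
`peak_voxel` breaks those ties by observed TFCE. Small-volume tests
restrict only which voxels feed the max statistic (`sphere_mask`),
never the per-voxel t values. The interaction contrast forms
per-subject (nat − control) differences and compares them between
groups as an independent design.

## Synthetic study generator

The generator is the ground truth against which every downstream stage
is validated. Per subject × condition, each labeled source emits
s(t) = α · g(env_θ(t − τ)) + √(1 − α²) · n(t), where env_θ is the
stimulus envelope band-passed 4–9 Hz (coupling injected only in the
analysis band keeps α interpretable as the coupled fraction of source
SD), g is unit-variance normalization, τ a per-source lag (defaults
20–40 ms, physiological latencies), and n pink (1/f) noise, the
canonical spectral profile of ongoing neural activity. Sources have
fixed tangential orientations (radial components are invisible in the
sphere), are projected through the leadfield, and white sensor noise is
added at the configured SNR (default 0 dB, rms-matched to the projected
signal). The default effect structure plants: STG coupling in everyone
(α 0.6 for intelligible nat/8ch, 0.45 for 1ch), parieto-occipital
coupling only in the EB group (α 0.4, all conditions), and calcarine
coupling only in EB × nat (α 0.5) — the group × intelligibility
interaction. Default cohort: 17 EB and 16 SI subjects, three
conditions; every subject hears the same stimuli (as in a real study),
with per-subject seeds spawned from the master seed.

What the generator does *not* emulate: real speech phonetics,
anatomical cortical geometry or realistic head conductors, correlated
sensor noise, eye/cardiac artifacts, inter-subject anatomical
variability, or head movement. Passing tests therefore demonstrate the
*estimators'* correctness and calibration under known ground truth, not
robustness to the full messiness of empirical MEG.

`synth_null_maps` generates spatially smooth Gaussian random fields on
the masked grid (independent across subjects) for permutation-
calibration studies at scale, where running the full sensor-level
pipeline hundreds of times would add nothing: exchangeability, the only
property permutation validity rests on, holds by construction.

## Problem sizes

Desk-scale studies in the tests and drivers use reduced sizes chosen to
keep each study in the minutes range while leaving all planted effects
comfortably recoverable: 8 subjects per group, 40 trials per condition,
64 sensors, a 12 mm grid, 500 permutations, and 20–200 replicates
depending on the question; the single-source localization sweep uses
the full 102 sensors, 200 trials and the 8 mm grid. Full-size runs (33
subjects, 8 mm grid, 1000 permutations) are configuration changes, not
code changes.

## Known limitations

- The sphere conductor makes radial source components invisible;
  effective SNR depends on source orientation and depth.
- Coherence/PLV bins are tied to the 1 s epoch length; other epoch
  lengths change the grid.
- The PSI null is conservative (jackknife degeneracy, above).
- Pseudo-t maps are not t-distributed voxelwise; inference is only via
  the permutation null, never parametric.
- `screen_artifacts` averages metrics across the other dimension, so a
  single extreme channel×trial cell is attributed to whichever margin
  is more extreme.
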