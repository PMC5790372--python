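"""Synthetic cerebro-acoustic study generator.

Generates the full design with known ground truth: speech-like stimuli
(band-limited noise carriers modulated by a jittered syllable train at
~7 Hz), their 1- and 8-channel vocoded versions, cortical dipole
sources whose activity is partially coupled — with adjustable strength
alpha and lag tau — to the 4-9 Hz component of the stimulus envelope,
projection through the spherical forward model onto a hemispheric
magnetometer array with additive sensor noise, and a cohort of two
groups (EB: early blind, SI: sighted) x three conditions (nat,
8-channel, 1-channel).

Planted effect structure, mirroring the phenomena under study:
"STG" (auditory cortex) tracks the envelope in everyone, more strongly
for intelligible speech; "POC" (parieto-occipital) tracks only in the
EB group; "CS" (calcarine) tracks only in EB listening to intelligible
(nat) speech — the group x intelligibility interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .audio import AudioSignal, VocoderSpec, vocode
from .beamformer import VirtualSensorSeries
from .envelope import (EnvelopeSignal, FilterbankSpec, align_envelope_to_recording,
                       extract_speech_envelope)
from .forward import (Leadfield, SensorArray, SourceGrid, make_grid,
                      make_sensor_array, sphere_leadfield)
from .preprocess import EpochSet

CONDITIONS = ("nat", "8ch", "1ch")


def default_source_positions() -> dict[str, tuple[float, float, float]]:
    # simulation head frame (meters), all within 0.9 x conductor radius
    return {
        "STG": (0.055, -0.010, 0.020),
        "CS": (-0.045, 0.010, 0.030),
        "POC": (-0.030, 0.000, 0.055),
    }


def default_coupling() -> dict[tuple[str, str, str], float]:
    """alpha[(group, condition, source)] — the planted effect structure."""
    alpha: dict[tuple[str, str, str], float] = {}
    for group in ("EB", "SI"):
        for cond in CONDITIONS:
            alpha[(group, cond, "STG")] = 0.6 if cond in ("nat", "8ch") else 0.45
            alpha[(group, cond, "POC")] = 0.4 if group == "EB" else 0.0
            alpha[(group, cond, "CS")] = 0.5 if (group == "EB" and cond == "nat") else 0.0
    return alpha


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic study."""

    syllable_rate_hz: float = 7.0
    n_trials_per_condition: int = 60
    coupling_alpha: dict = field(default_factory=default_coupling)
    lag_tau_ms: dict = field(default_factory=lambda: {"STG": 20.0, "CS": 40.0, "POC": 30.0})
    snr_db: float = 0.0
    source_positions: dict = field(default_factory=default_source_positions)
    n_subjects_per_group: dict = field(default_factory=lambda: {"EB": 17, "SI": 16})
    seed: int = 0
    conditions: tuple = CONDITIONS
    meg_rate: float = 256.0
    audio_rate: float = 22050.0
    n_sensors: int = 102
    sensor_radius: float = 0.12
    conductor_radius: float = 0.09
    grid_spacing: float = 0.008
    source_moment: float = 1e-8  # A·m, typical cortical dipole strength

    def __post_init__(self) -> None:
        for key, a in self.coupling_alpha.items():
            if not 0 <= a <= 1:
                raise ValueError(f"coupling alpha out of [0,1] at {key}")
        if self.syllable_rate_hz <= 0 or self.meg_rate <= 0:
            raise ValueError("rates must be positive")
        for label, pos in self.source_positions.items():
            if np.linalg.norm(pos) >= self.conductor_radius:
                raise ValueError(f"source {label} outside the conductor")


@dataclass
class SyntheticDataset:
    """Cohort of per-subject epoch sets with embedded ground truth."""

    subjects: list[EpochSet]
    stimuli: dict[str, AudioSignal]
    ground_truth: SimulationConfig


def synth_stimulus(rate_hz: float = 7.0, duration_s: float = 60.0,
                   seed: int = 0, audio_rate: float = 22050.0) -> AudioSignal:
    """Speech-like stimulus: noise carrier with a syllabic envelope.

    A band-limited (100-9000 Hz) Gaussian noise carrier is multiplied by
    a modulator of gamma-shaped bursts at the given mean syllable rate
    with 15% CV inter-burst jitter, then peak-normalized.
    """
    if rate_hz >= 20:
        raise ValueError("syllable rate >= 20 Hz is outside the speech-like regime")
    if duration_s < 2:
        raise ValueError("duration must be at least 2 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * audio_rate))

    # jittered syllable onsets: gamma-distributed intervals, CV = 15%
    cv = 0.15
    shape = 1.0 / cv**2
    mean_int = 1.0 / rate_hz
    intervals = rng.gamma(shape, mean_int / shape, size=int(duration_s * rate_hz * 2) + 8)
    onsets = np.cumsum(intervals)
    onsets = onsets[onsets < duration_s]
    train = np.zeros(n)
    idx = np.round(onsets * audio_rate).astype(int)
    train[idx[idx < n]] = 1.0

    # gamma-shaped burst kernel, width ~ half a syllable period
    t = np.arange(0, 1.5 * mean_int, 1 / audio_rate)
    scale = mean_int / 8.0
    kernel = (t / scale) ** 2 * np.exp(-t / scale)
    modulator = signal.fftconvolve(train, kernel)[:n]
    modulator /= modulator.max() if modulator.max() > 0 else 1.0

    sos = signal.butter(4, [100.0, 9000.0], btype="bandpass", fs=audio_rate, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
    samples = modulator * carrier
    samples /= np.max(np.abs(samples))
    return AudioSignal(samples=samples, rate=audio_rate)


def stimulus_modulator_rate(x: AudioSignal, lo: float = 2.0, hi: float = 12.0):
    """Spectral peak (Hz) of a stimulus's broadband envelope in [lo, hi]."""
    from .audio import broadband_envelope
    env = broadband_envelope(x)
    env = env - env.mean()
    freqs, p = signal.periodogram(env, fs=x.rate)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(freqs[sel][np.argmax(p[sel])])


def _pink_noise(n: int, rng) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    F = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        F *= np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
    x = np.fft.irfft(F, n)
    return (x - x.mean()) / x.std()


def _tangential_orientation(pos: np.ndarray) -> np.ndarray:
    """A deterministic unit vector tangential to the sphere at pos
    (radial dipoles are silent in a spherical conductor)."""
    p = np.asarray(pos, dtype=float)
    ref = np.array([0.0, 0.0, 1.0])
    if np.linalg.norm(np.cross(ref, p)) < 1e-9:
        ref = np.array([1.0, 0.0, 0.0])
    t = np.cross(ref, p)
    return t / np.linalg.norm(t)


class SimulationContext:
    """Cohort-level fixtures shared across subjects: geometry, leadfield,
    and the per-condition aligned stimulus envelopes (every subject
    hears the same stories)."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.sensors: SensorArray = make_sensor_array(config.n_sensors, config.sensor_radius)
        self.grid: SourceGrid = make_grid(config.grid_spacing, config.conductor_radius)
        self.leadfield: Leadfield = sphere_leadfield(
            self.grid, self.sensors, conductor_radius=config.conductor_radius)
        self.stimuli: dict[str, AudioSignal] = {}
        self.envelopes: dict[str, EnvelopeSignal] = {}
        self._build_stimuli()
        self.source_gain: dict[str, np.ndarray] = {}
        self.set_sources(config.source_positions)

    def set_sources(self, positions: dict) -> None:
        """(Re)bind labeled sources to grid points; stimuli, geometry and
        leadfield are reused (e.g. when sweeping source positions)."""
        self.config.source_positions = dict(positions)
        self.source_gain = {}
        for label, pos in positions.items():
            s = self.grid.nearest_inside(pos)
            ori = _tangential_orientation(self.grid.masked_points[s])
            self.source_gain[label] = self.leadfield.L[s] @ ori * self.config.source_moment

    def _build_stimuli(self) -> None:
        cfg = self.config
        duration = cfg.n_trials_per_condition * 1.0
        nat = synth_stimulus(cfg.syllable_rate_hz, duration, seed=cfg.seed,
                             audio_rate=cfg.audio_rate)
        stims = {"nat": nat}
        if "8ch" in cfg.conditions:
            stims["8ch"] = vocode(nat, VocoderSpec(n_channels=8, noise_seed=cfg.seed + 1))
        if "1ch" in cfg.conditions:
            stims["1ch"] = vocode(nat, VocoderSpec(n_channels=1, noise_seed=cfg.seed + 2))
        fb = FilterbankSpec()
        for cond in cfg.conditions:
            env = extract_speech_envelope(stims[cond], fb)
            self.envelopes[cond] = align_envelope_to_recording(env, cfg.meg_rate)
        self.stimuli = stims


def _theta_component(env: np.ndarray, rate: float, lo: float = 4.0, hi: float = 9.0):
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, env)
    return (x - x.mean()) / x.std()


def synth_subject(config: SimulationConfig, group: str, subject_seed: int,
                  ctx: SimulationContext | None = None,
                  subject_id: str = "") -> EpochSet:
    """One subject's epoched sensor data across all conditions.

    Per condition, each labeled source emits
    ``alpha * g(env_theta(t - tau)) + sqrt(1 - alpha^2) * pink_noise``
    (g: unit-variance normalization of the 4-9 Hz envelope component);
    sources project through the sphere leadfield and white sensor noise
    is added at the configured SNR. Trials of all conditions are
    concatenated with condition labels and the aligned true envelope.
    """
    for label in config.source_positions:
        for cond in config.conditions:
            if (group, cond, label) not in config.coupling_alpha:
                raise KeyError(f"no coupling alpha for {(group, cond, label)}")
    ctx = ctx or SimulationContext(config)
    rng = np.random.default_rng(subject_seed)
    fs = config.meg_rate
    n_samp = int(round(config.n_trials_per_condition * fs))

    all_epochs, all_env, labels = [], [], []
    for cond in config.conditions:
        env = ctx.envelopes[cond].samples[:n_samp]
        if len(env) < n_samp:
            raise ValueError("stimulus envelope shorter than the trial span")
        env_theta = _theta_component(env, fs)
        sensor = np.zeros((ctx.sensors.n_sensors, n_samp))
        for label in config.source_positions:
            alpha = config.coupling_alpha[(group, cond, label)]
            tau = config.lag_tau_ms.get(label, 0.0)
            shift = int(round(tau * fs / 1000.0))
            drive = np.roll(env_theta, shift)
            noise = _pink_noise(n_samp, rng)
            s = alpha * drive + np.sqrt(1 - alpha**2) * noise
            sensor += np.outer(ctx.source_gain[label], s)
        sig_rms = np.sqrt(np.mean(sensor**2))
        noise_std = sig_rms * 10 ** (-config.snr_db / 20.0)
        sensor = sensor + noise_std * rng.standard_normal(sensor.shape)

        n_trials = config.n_trials_per_condition
        eps = sensor[:, : n_trials * int(fs)].reshape(
            ctx.sensors.n_sensors, n_trials, int(fs)).transpose(1, 0, 2)
        env_ep = env[: n_trials * int(fs)].reshape(n_trials, int(fs))
        all_epochs.append(eps)
        all_env.append(env_ep)
        labels += [cond] * n_trials

    return EpochSet(epochs=np.concatenate(all_epochs), rate=fs, epoch_len_s=1.0,
                    condition_labels=labels, subject_id=subject_id, group=group,
                    envelope_epochs=np.concatenate(all_env))


def condition_subset(e: EpochSet, cond: str) -> EpochSet:
    """The trials of one condition, with their envelope epochs."""
    idx = [i for i, c in enumerate(e.condition_labels) if c == cond]
    if not idx:
        raise ValueError(f"no trials with condition {cond!r}")
    return EpochSet(epochs=e.epochs[idx], rate=e.rate, epoch_len_s=e.epoch_len_s,
                    condition_labels=[cond] * len(idx), subject_id=e.subject_id,
                    group=e.group, envelope_epochs=e.envelope_epochs[idx],
                    channel_ids=e.channel_ids)


def synth_cohort(config: SimulationConfig,
                 ctx: SimulationContext | None = None) -> SyntheticDataset:
    """The full two-group cohort, reproducible from (config, seed)."""
    ctx = ctx or SimulationContext(config)
    ss = np.random.SeedSequence(config.seed)
    subjects = []
    groups = [g for g, n in config.n_subjects_per_group.items() for _ in range(n)]
    child_seeds = ss.spawn(len(groups))
    for i, (group, child) in enumerate(zip(groups, child_seeds)):
        seed = int(child.generate_state(1)[0] % (2**31))
        subjects.append(synth_subject(config, group, seed, ctx=ctx,
                                      subject_id=f"{group}{i:02d}"))
    return SyntheticDataset(subjects=subjects, stimuli=dict(ctx.stimuli),
                            ground_truth=config)


def synth_null_maps(grid: SourceGrid, n_subjects: int, seed: int = 0,
                    smooth_vox: float = 1.0) -> np.ndarray:
    """Per-subject source maps with no group or condition effect.

    Spatially smooth Gaussian random fields sampled on the masked grid
    (smoothness emulating the intrinsic blur of beamformer images),
    independent across subjects — the exchangeable null for calibrating
    permutation inference at scale. Returns n_subjects x n_voxels.
    """
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    shape, idx = grid.shape3d()
    mi = idx[grid.inside_mask]
    out = np.empty((n_subjects, grid.n_inside))
    for i in range(n_subjects):
        vol = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_vox)
        out[i] = vol[mi[:, 0], mi[:, 1], mi[:, 2]]
    return out


def directed_pair(config: SimulationConfig, lag_tau_ms: float,
                  n_trials: int = 60, seed: int = 0,
                  noise_level: float = 1.0) -> tuple[VirtualSensorSeries, VirtualSensorSeries]:
    """Two virtual-sensor series with known lead/lag for PSI validation.

    x2 is a copy of x1 delayed by ``lag_tau_ms`` and mixed with
    independent noise; positive PSI(x1, x2) is expected for positive lag.
    """
    fs = config.meg_rate
    n_samp_trial = int(fs)
    if abs(lag_tau_ms) / 1000.0 >= 1.0:
        raise ValueError("lag exceeds the epoch length")
    rng = np.random.default_rng(seed)
    total = n_trials * n_samp_trial + n_samp_trial  # one spare second for the shift
    x1 = _pink_noise(total, rng)
    shift = int(round(lag_tau_ms * fs / 1000.0))
    x2 = np.roll(x1, shift) + noise_level * _pink_noise(total, rng)

    def cut(x):
        eps = x[: n_trials * n_samp_trial].reshape(n_trials, n_samp_trial)
        return VirtualSensorSeries(epochs=eps, rate=fs)

    return cut(x1), cut(x2)
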