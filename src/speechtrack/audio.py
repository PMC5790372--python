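"""Audio I/O and noise vocoding.

A channel vocoder splits a sound into logarithmically spaced frequency
bands, extracts each band's slow amplitude envelope, re-imposes the
envelopes on band-limited Gaussian noise carriers, and sums the bands.
The result preserves the slow amplitude fluctuations of the original
(the syllabic rhythm) while destroying spectral fine structure: with a
single band speech becomes unintelligible, with eight bands it remains
intelligible but heavily distorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile


@dataclass
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitude values, finite.
    rate : float
        Sampling frequency in Hz, > 0.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal samples must be 1-D (mono)")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class VocoderSpec:
    """Parameters of the noise vocoder.

    ``n_channels`` is 1 or 8 for the unintelligible / intelligible control
    conditions; any value >= 1 is accepted. Band edges are geometrically
    (log-) spaced between ``band_lo_hz`` and ``band_hi_hz``.
    """

    n_channels: int = 1
    band_lo_hz: float = 70.0
    band_hi_hz: float = 9000.0
    env_cutoff_hz: float = 30.0
    filter_order: int = 4
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError("need 0 < band_lo_hz < band_hi_hz")
        if self.env_cutoff_hz <= 0:
            raise ValueError("env_cutoff_hz must be positive")


def read_wav(path) -> AudioSignal:
    """Read a PCM or float WAV file as a mono AudioSignal in [-1, 1].

    Multi-channel files are averaged to mono. Integer PCM is scaled by
    the full-scale value of its dtype.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(float) / scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, rate=float(rate))


def write_wav(path, x: AudioSignal, *, dtype: str = "float32") -> None:
    """Write an AudioSignal as float32 or PCM16 WAV."""
    if dtype == "float32":
        wavfile.write(path, int(x.rate), x.samples.astype(np.float32))
    elif dtype == "int16":
        peak = np.max(np.abs(x.samples)) or 1.0
        scaled = np.clip(x.samples / max(peak, 1.0), -1, 1)
        wavfile.write(path, int(x.rate), (scaled * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def log_band_edges(spec: VocoderSpec) -> list[tuple[float, float]]:
    """Contiguous logarithmically spaced band edges (lo, hi) in Hz.

    Edges are geometric between ``band_lo_hz`` and ``band_hi_hz``; band
    i's upper edge equals band i+1's lower edge.
    """
    edges = np.geomspace(spec.band_lo_hz, spec.band_hi_hz, spec.n_channels + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(spec.n_channels)]


def _bandpass_sos(lo: float, hi: float, rate: float, order: int):
    nyq = rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def _band_envelope(x: np.ndarray, cutoff: float, rate: float, order: int) -> np.ndarray:
    # classic channel-vocoder envelope: half-wave rectify + zero-phase low-pass
    rect = np.maximum(x, 0.0)
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    env = signal.sosfiltfilt(sos, rect)
    return np.maximum(env, 0.0)


def vocode_bands(x: AudioSignal, spec: VocoderSpec) -> list[dict]:
    """Per-band vocoder synthesis, before summation.

    Each entry holds the analysis band of the input, its envelope, and
    the RMS-matched noise-modulated synthesis band. Exposed so the
    band-energy match (synthesis RMS = analysis RMS) can be verified.
    """
    rng = np.random.default_rng(spec.noise_seed)
    bands = []
    for lo, hi in log_band_edges(spec):
        sos = _bandpass_sos(lo, hi, x.rate, spec.filter_order)
        band = signal.sosfiltfilt(sos, x.samples)
        env = _band_envelope(band, spec.env_cutoff_hz, x.rate, spec.filter_order)
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(len(x.samples)))
        voc = env * carrier
        rms_in = np.sqrt(np.mean(band**2))
        rms_out = np.sqrt(np.mean(voc**2))
        if rms_out > 0:
            voc *= rms_in / rms_out
        bands.append({"edges": (lo, hi), "analysis": band, "envelope": env,
                      "synthesis": voc})
    return bands


def vocode(x: AudioSignal, spec: VocoderSpec) -> AudioSignal:
    """Noise-vocode a signal.

    Per band: band-pass the input, extract its envelope (rectification +
    zero-phase low-pass at ``env_cutoff_hz``), modulate a band-limited
    Gaussian noise carrier with it, RMS-match the band to the original
    band, and sum all bands. Deterministic given ``noise_seed``.
    """
    out = np.zeros_like(x.samples)
    for b in vocode_bands(x, spec):
        out += b["synthesis"]
    return AudioSignal(samples=out, rate=x.rate)


def broadband_envelope(x: AudioSignal, cutoff_hz: float = 30.0, order: int = 4) -> np.ndarray:
    """Slow (<= cutoff) broadband amplitude envelope, for comparing a
    stimulus with its vocoded version (rectify + zero-phase low-pass)."""
    return _band_envelope(x.samples, cutoff_hz, x.rate, order)
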