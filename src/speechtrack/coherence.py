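"""Cross-spectral density and cerebro-acoustic coherence.

Each 1 s epoch is Hanning-tapered and Fourier-transformed; cross-spectra
between every channel and the stimulus envelope are averaged across
trials on an integer-Hz grid from 1 to 30 Hz. Coherence is the
magnitude of the averaged cross-spectrum normalized by the auto-spectra,
Fisher z-transformed with atanh for variance stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet

ENVELOPE = "envelope"


@dataclass
class CrossSpectralDensity:
    """Trial-averaged cross-spectral matrices.

    ``S`` has shape (n_freqs, n_signals, n_signals); the last signal is
    the stimulus envelope when the epochs carried one. Hermitian per
    frequency with real nonnegative diagonal.
    """

    freqs: np.ndarray
    S: np.ndarray
    n_trials: int
    taper: str = "hann"
    signal_names: list[str] | None = None

    @property
    def envelope_index(self) -> int:
        if self.signal_names and self.signal_names[-1] == ENVELOPE:
            return len(self.signal_names) - 1
        raise ValueError("CSD has no envelope signal")

    def band_average(self, lo: float, hi: float) -> np.ndarray:
        """Mean of S over frequencies in [lo, hi] inclusive."""
        sel = (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"no CSD frequencies in [{lo}, {hi}] Hz")
        return self.S[sel].mean(axis=0)


@dataclass
class CoherenceSpectrum:
    """Coherence (and its atanh z-transform) of one pair over frequency."""

    freqs: np.ndarray
    coh: np.ndarray
    z: np.ndarray
    n_trials: int


def csd(e: EpochSet, fmin: float = 1.0, fmax: float = 30.0,
        step: float = 1.0) -> CrossSpectralDensity:
    """Hanning-tapered cross-spectral density averaged over trials.

    The frequency grid runs from ``fmin`` to ``fmax`` inclusive in steps
    of ``step``; with 1 s epochs the native resolution is 1 Hz and the
    step must be a multiple of it (no implicit padding).
    """
    n = e.epochs.shape[2]
    res = e.rate / n
    if step < res - 1e-9:
        raise ValueError(f"step {step} Hz finer than resolution {res} Hz")
    freqs = np.arange(fmin, fmax + step / 2, step)
    bins = freqs / res
    if np.max(np.abs(bins - np.round(bins))) > 1e-6:
        raise ValueError("requested frequencies do not fall on FFT bins")
    bins = np.round(bins).astype(int)

    sigs = e.epochs
    names = list(e.channel_ids) if e.channel_ids else [f"ch{i:03d}" for i in range(e.n_channels)]
    if e.envelope_epochs is not None:
        sigs = np.concatenate([sigs, e.envelope_epochs[:, None, :]], axis=1)
        names = names + [ENVELOPE]

    window = np.hanning(n)
    F = np.fft.rfft(sigs * window, axis=2)[:, :, bins]  # trials x signals x freqs
    S = np.einsum("tif,tjf->fij", F, np.conj(F)) / e.n_trials
    return CrossSpectralDensity(freqs=freqs, S=S, n_trials=e.n_trials,
                                signal_names=names)


def coherence(c: CrossSpectralDensity, x: int, y: int) -> CoherenceSpectrum:
    """Magnitude coherence |S_xy| / sqrt(S_xx S_yy) with atanh z.

    Perfect coherence (self-pairs, single trials) maps to +inf in z and
    is left as such rather than silently clipped.
    """
    Sxy = c.S[:, x, y]
    Sxx = c.S[:, x, x].real
    Syy = c.S[:, y, y].real
    denom = np.sqrt(Sxx * Syy)
    if np.any(denom == 0):
        raise ValueError("zero power at some frequency; coherence undefined")
    coh = np.abs(Sxy) / denom
    coh = np.minimum(coh, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(coh)
    return CoherenceSpectrum(freqs=c.freqs, coh=coh, z=z, n_trials=c.n_trials)


def sensor_coherence_spectrum(e: EpochSet, roi: list[int] | None = None,
                              fmin: float = 1.0, fmax: float = 30.0,
                              step: float = 1.0) -> CoherenceSpectrum:
    """Mean envelope z-coherence across an ROI of channels per frequency.

    ``roi`` holds channel indices (default: all channels). Use
    ``peak_frequency`` on the result to locate the tracking peak.
    """
    if roi is not None and len(roi) == 0:
        raise ValueError("roi must be non-empty")
    c = csd(e, fmin=fmin, fmax=fmax, step=step)
    env = c.envelope_index
    idx = roi if roi is not None else list(range(e.n_channels))
    zs = np.array([coherence(c, i, env).z for i in idx])
    z_mean = zs.mean(axis=0)
    return CoherenceSpectrum(freqs=c.freqs, coh=np.tanh(z_mean), z=z_mean,
                             n_trials=c.n_trials)


def peak_frequency(spec: CoherenceSpectrum) -> float:
    """Frequency of the coherence maximum."""
    return float(spec.freqs[int(np.argmax(spec.z))])
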