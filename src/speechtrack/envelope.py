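"""Speech amplitude envelope via a basilar-membrane-spaced filterbank.

The broadband envelope is the sum of analytic (Hilbert) amplitudes of
nine band-pass channels between 100 and 1000 Hz whose edges are spaced
at equal intervals of cochlear position under the Greenwood
frequency-position map, scaled to a maximum of 1. This envelope carries
the syllabic rhythm of speech and is the acoustic reference signal for
cerebro-acoustic coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio import AudioSignal


@dataclass
class FilterbankSpec:
    """Nine-band cochlear filterbank between 100 and 1000 Hz.

    Greenwood map: F(x) = A * (10**(a*x) - k) with x the relative
    position along the basilar membrane (0 = apex). Standard human
    constants A=165.4 Hz, a=2.1, k=0.88.
    """

    n_bands: int = 9
    lo_hz: float = 100.0
    hi_hz: float = 1000.0
    filter_order: int = 4
    greenwood_A: float = 165.4
    greenwood_a: float = 2.1
    greenwood_k: float = 0.88

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError("need 0 < lo_hz < hi_hz")


@dataclass
class EnvelopeSignal:
    """A nonnegative envelope time series at a given rate."""

    samples: np.ndarray
    rate: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def _greenwood(x: np.ndarray, spec: FilterbankSpec) -> np.ndarray:
    return spec.greenwood_A * (10.0 ** (spec.greenwood_a * x) - spec.greenwood_k)


def _greenwood_inv(f: np.ndarray, spec: FilterbankSpec) -> np.ndarray:
    return np.log10(np.asarray(f) / spec.greenwood_A + spec.greenwood_k) / spec.greenwood_a


def basilar_edges(spec: FilterbankSpec) -> np.ndarray:
    """Band edges equally spaced in cochlear position.

    Returns ``n_bands + 1`` strictly increasing frequencies whose images
    under the inverse Greenwood map form an arithmetic sequence; the
    first and last edges equal ``lo_hz`` and ``hi_hz`` exactly.
    """
    x = np.linspace(_greenwood_inv(spec.lo_hz, spec),
                    _greenwood_inv(spec.hi_hz, spec), spec.n_bands + 1)
    edges = _greenwood(x, spec)
    edges[0], edges[-1] = spec.lo_hz, spec.hi_hz
    return edges


def extract_speech_envelope(x: AudioSignal, spec: FilterbankSpec | None = None) -> EnvelopeSignal:
    """Nine-band Hilbert envelope, summed and scaled to max 1.

    Each band is filtered with a zero-phase (forward-backward)
    Butterworth band-pass of the stated order; the analytic amplitude is
    the absolute value of the Hilbert transform.
    """
    spec = spec or FilterbankSpec()
    if x.rate <= 2 * spec.hi_hz:
        raise ValueError(f"sampling rate {x.rate} too low for hi_hz={spec.hi_hz}")
    min_len = 3 * 3 * (2 * spec.filter_order + 1)  # filtfilt default padlen
    if len(x.samples) <= min_len:
        raise ValueError("signal too short for stable zero-phase filtering")
    edges = basilar_edges(spec)
    total = np.zeros(len(x.samples))
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = signal.butter(spec.filter_order, [lo, hi], btype="bandpass",
                            fs=x.rate, output="sos")
        band = signal.sosfiltfilt(sos, x.samples)
        total += np.abs(signal.hilbert(band))
    peak = total.max()
    if peak > 0:
        total /= peak
    return EnvelopeSignal(samples=total, rate=x.rate, normalized=True)


def align_envelope_to_recording(e: EnvelopeSignal, target_rate: float,
                                chain=None) -> EnvelopeSignal:
    """Pass the envelope through the sensor preprocessing chain.

    The envelope must be processed identically to the recording it
    accompanies: same filters, same downsampling, so that epoch grids
    align sample-for-sample. ``chain`` maps ``(samples, rate) ->
    samples_at_target_rate``; by default the standard filter chain
    (1 Hz HP, 170 Hz LP, 50/100/150 Hz notches) plus polyphase
    resampling is applied.
    """
    if e.rate < target_rate:
        raise ValueError("envelope rate below target rate")
    if chain is None:
        from .preprocess import SensorRecording, apply_standard_filters, downsample

        def chain(samples, rate):
            rec = SensorRecording(data=samples[None, :], rate=rate)
            rec = apply_standard_filters(rec)
            rec = downsample(rec, target_rate)
            return rec.data[0]

    out = chain(e.samples, e.rate)
    return EnvelopeSignal(samples=out, rate=target_rate, normalized=False)
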