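"""Virtual-sensor connectivity: phase-locking value and phase slope index.

PLV measures symmetric phase consistency between two source series
across trials; PSI measures directed coupling from the slope of the
cross-phase spectrum — if the phase lead of x1 over x2 grows with
frequency, x1 temporally precedes (and by the method's reading, drives)
x2. PSI is normalized by its jackknife standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .beamformer import VirtualSensorSeries


@dataclass
class ConnectivitySpectrum:
    freqs: np.ndarray
    plv: np.ndarray
    z: np.ndarray
    n_trials: int
    pair_labels: tuple[str, str] = ("x1", "x2")
    n_excluded: int = 0


@dataclass
class PsiEstimate:
    """Normalized phase slope index.

    ``psi_norm = psi_raw / se_jackknife``; positive values mean x1
    temporally precedes x2.
    """

    psi_raw: float
    se_jackknife: float
    psi_norm: float
    band_center: float
    bandwidth: float
    direction_convention: str = "positive => x1 leads x2"


def _trial_spectra(x: VirtualSensorSeries, pad_s: float = 2.0,
                   fmax: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Hanning-tapered trial spectra, zero-padded to ``pad_s`` seconds."""
    n = x.epochs.shape[1]
    n_pad = int(round(pad_s * x.rate))
    window = np.hanning(n)
    F = np.fft.rfft(x.epochs * window, n=n_pad, axis=1)
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / x.rate)
    sel = freqs <= fmax + 1e-9
    return freqs[sel], F[:, sel]


def plv_spectrum(x1: VirtualSensorSeries, x2: VirtualSensorSeries) -> ConnectivitySpectrum:
    """Phase-locking value over 0-50 Hz (0.5 Hz grid from 2 s padding).

    Per trial the cross-spectrum is amplitude-normalized to a unit
    phasor; the PLV is the magnitude of the phasor mean over trials.
    Trials with zero amplitude in a bin are excluded from that bin.
    """
    if x1.epochs.shape[0] != x2.epochs.shape[0]:
        raise ValueError("trial counts differ")
    freqs, F1 = _trial_spectra(x1)
    _, F2 = _trial_spectra(x2)
    S12 = F1 * np.conj(F2)
    amp = np.abs(S12)
    ok = amp > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} zero-amplitude trial/bin pairs excluded from PLV")
    phasor = np.where(ok, S12 / np.where(ok, amp, 1.0), 0.0)
    counts = ok.sum(axis=0)
    plv = np.abs(phasor.sum(axis=0)) / np.maximum(counts, 1)
    plv = np.minimum(plv, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(plv)
    return ConnectivitySpectrum(freqs=freqs, plv=plv, z=z,
                                n_trials=x1.epochs.shape[0],
                                pair_labels=(x1.location_label or "x1",
                                             x2.location_label or "x2"),
                                n_excluded=n_excluded)


def band_mean(c: ConnectivitySpectrum, lo: float, hi: float) -> float:
    """Mean z value over bins in [lo, hi] inclusive (e.g. theta, 4-8 Hz)."""
    sel = (c.freqs >= lo - 1e-9) & (c.freqs <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"no frequency bins in [{lo}, {hi}] Hz")
    return float(c.z[sel].mean())


def _psi_from_sums(S12: np.ndarray, P1: np.ndarray, P2: np.ndarray,
                   band_sel: np.ndarray) -> float:
    denom = np.sqrt(P1 * P2)
    C = np.where(denom > 0, S12 / np.where(denom > 0, denom, 1.0), 0.0)
    Cb = C[band_sel]
    return float(np.imag(np.sum(np.conj(Cb[:-1]) * Cb[1:])))


def phase_slope_index(x1: VirtualSensorSeries, x2: VirtualSensorSeries,
                      band_center: float = 6.0, halfwidth: float = 5.0) -> PsiEstimate:
    """PSI over [center - halfwidth, center + halfwidth], jackknifed.

    psi_raw = Im( sum_f conj(C(f)) C(f + df) ) with C the complex
    coherency and df one bin (0.5 Hz); the band is clipped to
    [1 Hz, Nyquist]. The standard error comes from leave-one-trial-out
    recomputation; ``psi_norm`` is psi_raw / se.
    """
    n = x1.epochs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials for jackknife")
    freqs, F1 = _trial_spectra(x1)
    _, F2 = _trial_spectra(x2)
    lo = max(band_center - halfwidth, 1.0)
    hi = min(band_center + halfwidth, x1.rate / 2)
    band_sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if band_sel.sum() < 2:
        raise ValueError("fewer than 2 frequency bins in PSI band")

    cross = F1 * np.conj(F2)
    p1 = np.abs(F1) ** 2
    p2 = np.abs(F2) ** 2
    S12, P1, P2 = cross.sum(axis=0), p1.sum(axis=0), p2.sum(axis=0)
    psi_raw = _psi_from_sums(S12, P1, P2, band_sel)

    loo = np.array([_psi_from_sums(S12 - cross[i], P1 - p1[i], P2 - p2[i], band_sel)
                    for i in range(n)])
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    if se == 0:
        # exactly identical leave-one-out estimates (e.g. noiseless copies)
        psi_norm = 0.0 if psi_raw == 0 else np.sign(psi_raw) * np.inf
    else:
        psi_norm = psi_raw / se
    return PsiEstimate(psi_raw=psi_raw, se_jackknife=se, psi_norm=float(psi_norm),
                       band_center=band_center, bandwidth=halfwidth)
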