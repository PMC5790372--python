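"""DICS and LCMV beamforming on the source grid.

DICS (dynamic imaging of coherent sources) builds, per grid point, a
unit-gain minimum-variance spatial filter from the band-averaged sensor
cross-spectral density and images coherence with the stimulus envelope
on the grid. Source maps are computed in two overlapping windows
(6 +/- 2 and 7 +/- 2 Hz by default), z-transformed and averaged into a
single 4-9 Hz image. LCMV is the time-domain analogue: a vector filter
from the broadband covariance whose three orientation components are
reduced to one virtual-sensor time series by SVD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coherence import CrossSpectralDensity, csd
from .forward import Leadfield, SourceGrid
from .preprocess import EpochSet


@dataclass
class SpatialFilter:
    """Unit-gain beamformer weights at one grid point.

    ``weights`` is 3 x n_sensors for a vector filter or 1 x n_sensors
    for a scalar (fixed-orientation) filter; ``orientation`` is the
    dominant source orientation for scalar filters.
    """

    weights: np.ndarray
    regularization: float
    orientation: np.ndarray | None = None


@dataclass
class SourceMap:
    """One scalar (z-coherence or statistic) per masked grid point."""

    values: np.ndarray
    grid: SourceGrid
    band_label: str = ""

    def argmax_point(self) -> np.ndarray:
        return self.grid.masked_points[int(np.argmax(self.values))]


@dataclass
class VirtualSensorSeries:
    """Single-component source time series (trials x samples)."""

    epochs: np.ndarray
    rate: float
    location_label: str = ""
    svd_gain: float = 1.0


def _regularized_inverse(S: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    Sr = np.real(S).copy()
    mu = lam * np.trace(Sr) / Sr.shape[0]
    Sr[np.diag_indices_from(Sr)] += mu
    return np.linalg.inv(Sr), mu


def dics_filter(S: np.ndarray, lf: Leadfield, point: int,
                lam: float = 0.05, scalar: bool = True) -> SpatialFilter:
    """Unit-gain DICS filter at one masked grid point.

    ``S`` is the band-averaged sensor CSD (n_sensors x n_sensors); its
    real part is used for the filter. The scalar variant fixes the
    orientation that maximizes output power (the eigenvector of
    L^T S^-1 L with the smallest eigenvalue) and returns a 1 x n filter.
    """
    Sinv, _ = _regularized_inverse(S, lam)
    L = lf.L[point]                                  # n_sensors x 3
    G = L.T @ Sinv @ L                               # 3 x 3
    if not np.all(np.isfinite(G)) or np.abs(G).max() == 0:
        raise ValueError(f"degenerate leadfield at grid point {point}")
    if scalar:
        ori = _max_power_orientation(G)
        lo = L @ ori
        w = (Sinv @ lo) / (lo @ Sinv @ lo)
        return SpatialFilter(weights=w[None, :], regularization=lam, orientation=ori)
    # a spherical conductor is blind to radial dipoles, so L has rank 2
    # and G is singular; the pseudo-inverse restricts gain to the
    # visible (tangential) subspace
    W = np.linalg.pinv(G, rcond=1e-10) @ L.T @ Sinv  # 3 x n_sensors
    return SpatialFilter(weights=W, regularization=lam)


def _max_power_orientation(G: np.ndarray) -> np.ndarray:
    """Orientation maximizing beamformer output power: the eigenvector of
    G = L^T S^-1 L with the smallest eigenvalue, restricted to the
    subspace the sensors can see (eigenvalues ~0 mean silent
    orientations, e.g. radial dipoles in a sphere)."""
    evals, evecs = np.linalg.eigh(G)
    visible = evals > 1e-10 * evals[-1]
    k = int(np.argmax(visible))                      # smallest visible eigenvalue
    return evecs[:, k]


def source_coherence_map(e: EpochSet, lf: Leadfield,
                         windows: tuple = ((6.0, 2.0), (7.0, 2.0)),
                         lam: float = 0.05,
                         csd_cache: CrossSpectralDensity | None = None) -> SourceMap:
    """DICS image of envelope coherence, averaged over frequency windows.

    For each (center, halfwidth) window the CSD is band-averaged, a
    scalar filter is built per grid point, and the source-envelope
    coherence is Fisher z-transformed; the per-window z maps are then
    arithmetically averaged into one image.
    """
    lo_all = min(c - h for c, h in windows)
    hi_all = max(c + h for c, h in windows)
    if lo_all < 1.0 - 1e-9 or hi_all > 30.0 + 1e-9:
        raise ValueError("frequency windows must lie within 1-30 Hz")
    c = csd_cache if csd_cache is not None else csd(e, fmin=1.0, fmax=30.0, step=1.0)
    env = c.envelope_index
    n_ch = env                                        # channels precede envelope

    z_maps = []
    for center, half in windows:
        Sband = c.band_average(center - half, center + half)
        Sss = Sband[:n_ch, :n_ch]
        Sse = Sband[:n_ch, env]
        See = Sband[env, env].real
        Sinv, _ = _regularized_inverse(Sss, lam)
        z = np.empty(lf.n_sources)
        for s in range(lf.n_sources):
            L = lf.L[s]
            G = L.T @ Sinv @ L
            if not np.all(np.isfinite(G)) or np.abs(G).max() == 0:
                z[s] = 0.0
                continue
            ori = _max_power_orientation(G)
            lo = L @ ori
            denom = lo @ Sinv @ lo
            if denom <= 0 or not np.isfinite(denom):
                z[s] = 0.0
                continue
            w = (Sinv @ lo) / denom
            p_src = np.real(w @ Sss @ np.conj(w))
            cross = np.abs(w @ Sse)
            coh = cross / np.sqrt(p_src * See) if p_src > 0 and See > 0 else 0.0
            z[s] = np.arctanh(min(coh, 1.0 - 1e-12))
        z_maps.append(z)
    label = f"{lo_all:g}-{hi_all:g} Hz"
    return SourceMap(values=np.mean(z_maps, axis=0), grid=lf.grid, band_label=label)


def lcmv_virtual_sensor(e: EpochSet, lf: Leadfield, point: int,
                        lam: float = 0.05, label: str = "") -> VirtualSensorSeries:
    """Common-filter LCMV virtual sensor with SVD orientation reduction.

    The spatial filter is computed once from the trial-averaged
    covariance (a common filter for all trials) and applied to every
    trial; the three orientation components are reduced to a single
    series by keeping the dominant left singular vector of the
    concatenated 3 x time matrix. Sign convention: the scalar filter's
    largest-magnitude sensor weight is made positive.
    """
    demeaned = e.epochs - e.epochs.mean(axis=2, keepdims=True)
    C = np.einsum("tcs,tds->cd", demeaned, demeaned) / (e.n_trials * e.epochs.shape[2])
    Cinv, mu = _regularized_inverse(C, lam)
    if lam == 0 and np.linalg.cond(C) > 1e12:
        raise ValueError("rank-deficient covariance; use regularization lam > 0")
    L = lf.L[point]
    G = L.T @ Cinv @ L
    # pinv: the sphere model is blind to radial dipoles, so G has rank 2
    W = np.linalg.pinv(G, rcond=1e-10) @ L.T @ Cinv   # 3 x n_sensors

    src3 = np.einsum("on,tns->tos", W, demeaned)      # trials x 3 x samples
    concat = src3.transpose(1, 0, 2).reshape(3, -1)
    U, svals, _ = np.linalg.svd(concat, full_matrices=False)
    u = U[:, 0]
    w_scalar = u @ W
    if w_scalar[np.argmax(np.abs(w_scalar))] < 0:
        u = -u
    series = np.einsum("o,tos->ts", u, src3)
    gain = float(svals[0] / svals.sum()) if svals.sum() > 0 else 1.0
    return VirtualSensorSeries(epochs=series, rate=e.rate,
                               location_label=label, svd_gain=gain)
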