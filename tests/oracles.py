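"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check (explicit DFT
sums instead of FFT-based cross-spectra).
"""

import numpy as np


def brute_force_coherence(epochs_x, epochs_y, rate, freqs):
    """Trial-averaged magnitude coherence by explicit DFT sums."""
    n_trials, n = epochs_x.shape
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / (n - 1))  # symmetric Hann
    out = []
    for f in freqs:
        k = int(round(f * n / rate))
        sxy = sxx = syy = 0.0
        for tr in range(n_trials):
            X = 0.0 + 0.0j
            Y = 0.0 + 0.0j
            for t in range(n):
                ph = np.exp(-2j * np.pi * k * t / n)
                X += w[t] * epochs_x[tr, t] * ph
                Y += w[t] * epochs_y[tr, t] * ph
            sxy += X * np.conj(Y)
            sxx += abs(X) ** 2
            syy += abs(Y) ** 2
        out.append(abs(sxy / n_trials) / np.sqrt(sxx / n_trials * syy / n_trials))
    return np.array(out)
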