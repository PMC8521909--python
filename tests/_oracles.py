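"""Independent brute-force oracles used only by the tests.

Spectral features are recomputed from an explicit DFT summation (no FFT
call) and first-principles definitions; the Student-t upper tail is
recomputed by numerical quadrature of the closed-form density.  These
implementations deliberately share no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def dft_magnitude(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitudes by explicit summation, with bin indices."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_bins = n // 2 + 1
    k = np.arange(n_bins)[:, None]
    t = np.arange(n)[None, :]
    basis = np.exp(-2j * np.pi * k * t / n)
    return np.abs(basis @ x), np.arange(n_bins)


def hann(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)


def spectral_features_bruteforce(x: np.ndarray, fs: float,
                                 prev: np.ndarray | None = None,
                                 rolloff_fraction: float = 0.85,
                                 band: tuple[float, float] = (250.0, 10_000.0)) -> dict:
    """All spectral features of one frame from the explicit DFT."""
    n = len(x)
    w = hann(n)
    mag, bins = dft_magnitude(np.asarray(x, dtype=float) * w)
    power = mag ** 2
    freqs = bins * fs / n
    total = power.sum()

    centroid = (freqs * power).sum() / total
    spread = math.sqrt(((freqs - centroid) ** 2 * power).sum() / total)

    cum = np.cumsum(power)
    roll_idx = next(i for i in range(len(cum)) if cum[i] >= rolloff_fraction * total)
    rolloff = freqs[roll_idx]

    p = power / total
    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)

    psd = power / (fs * (w ** 2).sum())
    in_band = [(f >= band[0]) and (f <= min(band[1], fs / 2)) for f in freqs]
    density = float(np.mean(psd[np.array(in_band)])) if any(in_band) else 0.0

    if prev is None:
        flux = 0.0
    else:
        mag_p, _ = dft_magnitude(np.asarray(prev, dtype=float) * w)
        m1 = mag / mag.sum()
        m0 = mag_p / mag_p.sum()
        flux = float(((m1 - m0) ** 2).sum())

    return {
        "spectral_centroid": centroid,
        "spectral_spread": spread,
        "spectral_rolloff": rolloff,
        "spectral_entropy": entropy,
        "spectral_density": density,
        "spectral_flux": flux,
    }


def student_t_upper_tail_quadrature(t: float, dof: int) -> float:
    """P(T > t) for Student-t by quadrature of the closed-form density."""
    c = math.gamma((dof + 1) / 2) / (math.sqrt(dof * math.pi) * math.gamma(dof / 2))

    def pdf(u):
        return c * (1 + u * u / dof) ** (-(dof + 1) / 2)

    val, _ = quad(pdf, t, np.inf, epsabs=1e-12, epsrel=1e-12)
    return val
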