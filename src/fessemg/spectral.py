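"""Shared spectral estimators (Welch PSD, median/mean power frequency, line ratios)."""

from __future__ import annotations

import numpy as np
from scipy.signal import welch


def welch_psd(x: np.ndarray, fs: float, nperseg: int = 1024,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with a Hann taper; nperseg is capped at the signal length."""
    x = np.asarray(x, dtype=float)
    nperseg = int(min(nperseg, x.size))
    return welch(x, fs=fs, window="hann", nperseg=nperseg,
                 noverlap=int(nperseg * overlap))


def _band_psd(x, fs, band_hz, kw):
    f, p = welch_psd(x, fs, **kw)
    if band_hz is not None:
        keep = (f >= band_hz[0]) & (f <= band_hz[1])
        f, p = f[keep], p[keep]
    return f, p


def median_frequency(x: np.ndarray, fs: float,
                     band_hz: tuple[float, float] | None = None, **kw) -> float:
    """Frequency splitting the (optionally band-limited) PSD into equal halves."""
    f, p = _band_psd(x, fs, band_hz, kw)
    total = np.trapezoid(p, f)
    if total <= 0:
        return 0.0
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(f))])
    return float(np.interp(0.5 * total, cum, f))


def mean_power_frequency(x: np.ndarray, fs: float,
                         band_hz: tuple[float, float] | None = None, **kw) -> float:
    """Power-weighted mean frequency of the (optionally band-limited) Welch PSD."""
    f, p = _band_psd(x, fs, band_hz, kw)
    total = p.sum()
    if total <= 0:
        return 0.0
    return float((f * p).sum() / total)


def harmonic_line_ratios(x: np.ndarray, fs: float, f0: float,
                         n_harmonics: int = 5, nperseg: int = 4000,
                         continuum_halfwidth_hz: float = 20.0) -> np.ndarray:
    """Line-to-continuum power ratio at each harmonic k*f0, k = 1..n_harmonics.

    The line estimate is the PSD bin nearest the harmonic; the continuum is the
    median PSD over +-continuum_halfwidth_hz around it (line bins excluded by
    the median's robustness). Welch averaging keeps the continuum estimate
    stable enough that a clean signal scores ~1.
    """
    f, p = welch_psd(x, fs, nperseg=nperseg)
    df = f[1] - f[0]
    ratios = []
    for k in range(1, n_harmonics + 1):
        i = int(round(k * f0 / df))
        lo = max(0, i - int(round(continuum_halfwidth_hz / df)))
        hi = min(p.size, i + int(round(continuum_halfwidth_hz / df)) + 1)
        continuum = np.median(p[lo:hi])
        ratios.append(p[i] / continuum if continuum > 0 else np.inf)
    return np.asarray(ratios)


def band_power(x: np.ndarray, fs: float, center_hz: float,
               halfwidth_hz: float = 1.0, nperseg: int | None = None) -> float:
    """Integrated periodogram power within +-halfwidth_hz of center_hz."""
    x = np.asarray(x, dtype=float)
    n = x.size if nperseg is None else min(nperseg, x.size)
    spec = np.abs(np.fft.rfft(x[:n])) ** 2 / n
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = np.abs(f - center_hz) <= halfwidth_hz
    return float(spec[mask].sum())
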