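"""Time-frequency imaging of 500 ms sEMG windows.

Three transforms turn a window into an energy distribution over the
time-frequency plane:

* **STFT spectrogram** |X(t,f)|^2 - windowed DFT magnitude squared.
* **CWT scalogram** |W(tau,s)|^2 with the *bump* mother wavelet, an analytic
  band-limited window in the frequency domain,
  Psi(s w) = exp(1 - 1/(1 - ((s w - mu)/sigma)^2)) on |s w - mu| < sigma,
  L2-normalized by 1/sqrt(s).
* **Hilbert spectrum** - per intrinsic mode function, the analytic signal's
  instantaneous amplitude a(t) is deposited at (t, w(t)) where w(t) is the
  unwrapped-phase derivative; contributions of all modes are summed. Energy
  accumulation (a^2) is the default; plain amplitude accumulation is
  selectable.

All transforms are deterministic. ``render_image`` turns any of them into a
256 x 256 x 3 image by min-max normalization, optional log scaling, bilinear
resizing and a fixed perceptually-uniform colormap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy.signal import get_window, hilbert
from skimage.transform import resize

from .preprocess import IMFSet, SignalWindow, emd

METHODS = ("STFT", "CWT", "HHT")

#: display band for sEMG images (Hz); voluntary sEMG lives below ~450-500 Hz
DISPLAY_BAND_HZ = (2.0, 500.0)


@dataclass
class TFImage:
    """One rendered time-frequency image with its provenance."""

    pixels: np.ndarray          # 256 x 256 x 3, float in [0, 1]
    method: str
    channel_id: int
    motion_label: str
    fatigue_label: str
    freq_axis: np.ndarray       # 256 ascending positive Hz values
    time_axis: np.ndarray       # 256 ascending seconds
    recording_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixels must be finite")


def stft_spectrogram(window: SignalWindow, fft_window_len: int = 256,
                     hop: int = 32, taper: str = "hann"
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided spectrogram |X(t,f)|^2 of a window.

    The signal is zero-padded by one taper length minus hop on both sides so
    every sample is covered by the full set of taper positions; with a taper
    whose *squared* form satisfies the constant-overlap-add condition at this
    hop, total spectrogram energy equals ``sum(w^2)/hop * sum(x^2)`` exactly
    (Parseval).

    Returns ``(spec, freqs_hz, times_s)`` with ``spec`` shaped
    (n_freqs, n_frames).
    """
    x = window.samples
    if fft_window_len > x.size:
        raise ValueError("fft_window_len longer than the window")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    try:
        w = get_window(taper, fft_window_len, fftbins=True)
    except ValueError as exc:
        raise ValueError(f"unknown taper {taper!r}") from exc
    pad = fft_window_len - hop
    # last frame start: largest hop multiple still touching the final sample
    n_frames = (pad + x.size - 1) // hop + 1
    total = (n_frames - 1) * hop + fft_window_len
    xp = np.concatenate([np.zeros(pad), x, np.zeros(total - pad - x.size)])
    idx = np.arange(fft_window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = xp[idx] * w
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (frames, freqs)
    fs = window.sampling_rate_hz
    freqs = np.fft.rfftfreq(fft_window_len, 1.0 / fs)
    times = (hop * np.arange(n_frames) - pad + fft_window_len / 2) / fs
    return spec.T, freqs, times


def _bump_kernel(scaled_omega: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Bump window evaluated at s*omega (rad/sample units are fine)."""
    z = (scaled_omega - mu) / sigma
    out = np.zeros_like(scaled_omega)
    inside = np.abs(z) < 1.0
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - z[inside] ** 2))
    return out


def cwt_scalogram(window: SignalWindow, n_scales: int = 128,
                  freq_range_hz: tuple[float, float] = (4.0, 500.0),
                  mu: float = 5.0, sigma: float = 0.6
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bump-wavelet scalogram |W(tau,s)|^2 over log-spaced scales.

    Scales map to center frequencies ``f = mu * fs / (2 pi s)`` spanning
    ``freq_range_hz``; the wavelet is applied in the frequency domain with
    1/sqrt(s) (L2) normalization, i.e. FT[psi_s](w) = sqrt(s) Psi(s w).

    Returns ``(scalogram, center_freqs_hz, times_s)``, rows ordered by
    ascending frequency.
    """
    lo, hi = freq_range_hz
    fs = window.sampling_rate_hz
    if not 0.0 < lo < hi <= 0.5 * fs:
        raise ValueError(f"freq_range_hz must satisfy 0 < low < high <= Nyquist, got {freq_range_hz}")
    x = window.samples
    n = x.size
    freqs = np.geomspace(lo, hi, n_scales)
    scales = mu * fs / (2 * np.pi * freqs)   # in samples
    omega = 2 * np.pi * np.fft.fftfreq(n)    # rad/sample
    xf = np.fft.fft(x)
    out = np.empty((n_scales, n))
    for i, s in enumerate(scales):
        kern = np.sqrt(s) * _bump_kernel(s * omega, mu, sigma)
        out[i] = np.abs(np.fft.ifft(xf * kern)) ** 2
    times = np.arange(n) / fs
    return out, freqs, times


def instantaneous_amplitude_frequency(imf: np.ndarray, fs: float
                                      ) -> tuple[np.ndarray, np.ndarray]:
    """Hilbert analytic amplitude and instantaneous frequency of one mode.

    Frequency is the central-difference derivative of the unwrapped analytic
    phase, clipped above at Nyquist; negative estimates (edge artifacts) are
    returned as-is for the caller to mask.
    """
    z = hilbert(imf)
    a = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = np.gradient(phase) * fs / (2 * np.pi)
    return a, np.minimum(freq, 0.5 * fs)


def hht_spectrum(imfs: IMFSet, sampling_rate_hz: float,
                 n_freq_bins: int = 256, n_time_bins: int = 256,
                 freq_range_hz: tuple[float, float] = (0.0, 500.0),
                 mode: str = "energy"
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hilbert (marginal-free) spectrum of a set of IMFs on a binned grid.

    Each mode contributes its instantaneous amplitude (``mode='amplitude'``)
    or squared amplitude (``mode='energy'``, default) at its instantaneous
    (time, frequency) location; all modes are summed. Samples with negative
    frequency estimates (unwrap edge artifacts) are dropped.

    Returns ``(H, freq_centers_hz, time_centers_s)`` with ``H`` shaped
    (n_freq_bins, n_time_bins), rows ascending in frequency.
    """
    if imfs.n_imfs < 1:
        raise ValueError("hht_spectrum requires at least one IMF")
    if mode not in ("energy", "amplitude"):
        raise ValueError(f"mode must be 'energy' or 'amplitude', got {mode!r}")
    fs = sampling_rate_hz
    lo, hi = freq_range_hz
    if not 0.0 <= lo < hi <= 0.5 * fs:
        raise ValueError(f"invalid freq_range_hz {freq_range_hz}")
    n = imfs.imfs[0].size
    t_edges = np.linspace(0, n, n_time_bins + 1)
    f_edges = np.linspace(lo, hi, n_freq_bins + 1)
    H = np.zeros((n_freq_bins, n_time_bins))
    t_bin = np.clip(np.digitize(np.arange(n), t_edges) - 1, 0, n_time_bins - 1)
    for imf in imfs.imfs:
        a, f = instantaneous_amplitude_frequency(imf, fs)
        valid = (f >= lo) & (f <= hi)
        fb = np.clip(np.digitize(f[valid], f_edges) - 1, 0, n_freq_bins - 1)
        weights = a[valid] ** 2 if mode == "energy" else a[valid]
        np.add.at(H, (fb, t_bin[valid]), weights)
    f_centers = 0.5 * (f_edges[:-1] + f_edges[1:])
    t_centers = 0.5 * (t_edges[:-1] + t_edges[1:]) / fs
    return H, f_centers, t_centers


def render_image(tf: np.ndarray, freq_axis: np.ndarray, time_axis: np.ndarray,
                 window: SignalWindow, method: str,
                 out_size: tuple[int, int] = (256, 256),
                 colormap: str = "viridis", scaling: str = "linear") -> TFImage:
    """Render a time-frequency matrix as a colormapped image.

    Per-image min-max normalization (so rendering is invariant to positive
    rescaling of the matrix), optional ``log1p`` dynamic-range compression,
    bilinear resize, 3-channel colormap. A constant matrix renders as a
    constant image. Rows are flipped so frequency increases upward.
    """
    tf = np.asarray(tf, dtype=float)
    if tf.size == 0:
        raise ValueError("empty time-frequency matrix")
    if not np.all(np.isfinite(tf)):
        raise ValueError("time-frequency matrix contains non-finite values")
    if scaling not in ("linear", "log"):
        raise ValueError(f"scaling must be 'linear' or 'log', got {scaling!r}")
    m = tf - tf.min()
    if scaling == "log":
        peak = m.max()
        if peak > 0:
            # fixed 60 dB dynamic range relative to the per-image peak
            m = np.log1p(m * (1e3 / peak))
    peak = m.max()
    norm = m / peak if peak > 0 else m
    resized = resize(norm, out_size, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    resized = np.clip(resized, 0.0, 1.0)
    cmap = colormaps[colormap]
    pixels = cmap(resized[::-1, :])[:, :, :3]
    return TFImage(
        pixels=pixels,
        method=method,
        channel_id=window.channel_id,
        motion_label=window.motion_label,
        fatigue_label=window.fatigue_label,
        freq_axis=np.linspace(freq_axis[0], freq_axis[-1], out_size[0]),
        time_axis=np.linspace(time_axis[0], time_axis[-1], out_size[1]),
        recording_id=window.recording_id,
    )


def window_to_image(window: SignalWindow, method: str = "HHT",
                    out_size: tuple[int, int] = (256, 256),
                    colormap: str = "viridis", scaling: str = "log",
                    display_band_hz: tuple[float, float] = DISPLAY_BAND_HZ,
                    max_imfs: int = 10) -> TFImage:
    """Full window -> image conversion for one of the three methods."""
    method = method.upper()
    if method == "STFT":
        spec, freqs, times = stft_spectrogram(window)
        lo, hi = display_band_hz
        keep = (freqs > 0) & (freqs >= lo) & (freqs <= hi)
        return render_image(spec[keep], freqs[keep], times, window, method,
                            out_size, colormap, scaling)
    if method == "CWT":
        lo = max(display_band_hz[0], 2.0)
        spec, freqs, times = cwt_scalogram(
            window, freq_range_hz=(lo, display_band_hz[1]))
        return render_image(spec, freqs, times, window, method,
                            out_size, colormap, scaling)
    if method == "HHT":
        modes = emd(window.samples, max_imfs=max_imfs)
        if modes.n_imfs == 0:
            modes.imfs.append(window.samples.copy())
        spec, freqs, times = hht_spectrum(
            modes, window.sampling_rate_hz,
            n_freq_bins=out_size[0], n_time_bins=out_size[1],
            freq_range_hz=(0.0, display_band_hz[1]))
        return render_image(spec, freqs, times, window, method,
                            out_size, colormap, scaling)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
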