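"""STFT / bump-CWT / Hilbert-spectrum transforms and image rendering."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import chirp, get_window

from fessemg.imaging import (cwt_scalogram, hht_spectrum, render_image,
                             stft_spectrogram, window_to_image)
from fessemg.preprocess import IMFSet, segment
from fessemg.simulate import generate_recording
from tests.conftest import FS, make_window


# -- STFT ----------------------------------------------------------------------

def test_stft_peak_at_tone_frequency(tone_window):
    spec, freqs, _ = stft_spectrogram(tone_window)
    peak = freqs[np.argmax(spec.mean(axis=1))]
    assert abs(peak - 100.0) <= freqs[1] - freqs[0]


def test_stft_zero_input_all_zero():
    spec, _, _ = stft_spectrogram(make_window(np.zeros(4000)))
    assert not spec.any()


def test_stft_parseval():
    """Total spectrogram energy equals sum(w^2)/hop * sum(x^2) exactly."""
    rng = np.random.default_rng(0)
    x = np.sin(2 * np.pi * 100 * np.arange(4000) / FS) + 0.3 * rng.standard_normal(4000)
    L, hop = 256, 64  # hann^2 satisfies constant overlap-add at hop L/4
    spec, _, _ = stft_spectrogram(make_window(x), L, hop, "hann")
    two_sided = spec.copy()
    two_sided[1:-1] *= 2  # one-sided spectrum doubling (even L)
    lhs = two_sided.sum() / L
    w = get_window("hann", L)
    rhs = (w**2).sum() / hop * (x**2).sum()
    assert abs(lhs - rhs) / rhs < 1e-6


def test_stft_unknown_taper_rejected(tone_window):
    with pytest.raises(ValueError, match="taper"):
        stft_spectrogram(tone_window, taper="not_a_taper")


# -- CWT -----------------------------------------------------------------------

def test_cwt_ridge_within_one_scale_step():
    t = np.arange(4000) / FS
    win = make_window(np.sin(2 * np.pi * 150.0 * t))
    scal, freqs, _ = cwt_scalogram(win)
    ridge = freqs[np.argmax(scal.mean(axis=1))]
    step = freqs[1] / freqs[0]  # log-spaced
    assert ridge / step <= 150.0 <= ridge * step


def test_cwt_two_tone_ridges_recovered():
    t = np.arange(4000) / FS
    win = make_window(np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 200 * t))
    scal, freqs, _ = cwt_scalogram(win)
    prof = scal.mean(axis=1)
    peaks = [freqs[i] for i in range(1, len(prof) - 1)
             if prof[i] > prof[i - 1] and prof[i] > prof[i + 1]
             and prof[i] > 0.2 * prof.max()]
    assert len(peaks) == 2
    step = freqs[1] / freqs[0]
    for target, found in zip((60.0, 200.0), sorted(peaks)):
        assert found / step <= target <= found * step


def test_cwt_squared_magnitude_homogeneity(tone_window):
    base, _, _ = cwt_scalogram(tone_window)
    doubled, _, _ = cwt_scalogram(make_window(2.0 * tone_window.samples))
    assert np.allclose(doubled, 4.0 * base, rtol=1e-10)


def test_cwt_invalid_frequency_range(tone_window):
    with pytest.raises(ValueError, match="Nyquist"):
        cwt_scalogram(tone_window, freq_range_hz=(10.0, 9000.0))


# -- HHT -----------------------------------------------------------------------

def test_hht_tone_energy_localized_with_accurate_amplitude():
    t = np.arange(4000) / FS
    amp = 1.7
    imfs = IMFSet(imfs=[amp * np.sin(2 * np.pi * 100.0 * t)],
                  residue=np.zeros(4000))
    from fessemg.imaging import instantaneous_amplitude_frequency
    a, f = instantaneous_amplitude_frequency(imfs.imfs[0], FS)
    interior = slice(400, 3600)
    assert np.max(np.abs(a[interior] - amp)) / amp < 0.01
    H, freqs, _ = hht_spectrum(imfs, FS)
    tbin = H.shape[1] // 10
    core = H[:, tbin:-tbin]
    near = core[np.abs(freqs - 100.0) <= 5.0].sum()
    assert near / core.sum() >= 0.90


def test_hht_chirp_ridge_monotone_with_matching_endpoints():
    t = np.arange(4000) / FS
    x = chirp(t, 50.0, t[-1], 200.0)
    H, freqs, _ = hht_spectrum(IMFSet(imfs=[x], residue=np.zeros(4000)), FS,
                               n_freq_bins=128, n_time_bins=64)
    ridge = freqs[np.argmax(H, axis=0)]
    binw = freqs[1] - freqs[0]
    assert abs(ridge[2] - 50.0) <= 2 * binw
    assert abs(ridge[-3] - 200.0) <= 2 * binw
    assert np.all(np.diff(ridge[2:-2]) >= -binw)  # monotone up to bin noise


def test_hht_zero_content_gives_zero_matrix():
    H, _, _ = hht_spectrum(IMFSet(imfs=[np.zeros(4000)], residue=np.zeros(4000)), FS)
    assert not H.any()


def test_hht_requires_imfs_and_valid_mode():
    with pytest.raises(ValueError, match="at least one IMF"):
        hht_spectrum(IMFSet(imfs=[], residue=np.zeros(10)), FS)
    with pytest.raises(ValueError, match="mode"):
        hht_spectrum(IMFSet(imfs=[np.ones(100)], residue=np.zeros(100)), FS,
                     mode="phase")


def test_hht_mean_frequency_drops_with_fatigue(quiet_config):
    """Links the imaging stage to the generator's fatigue model."""
    def mean_freq(fatigue, seed):
        rec = generate_recording(replace(quiet_config, seed=seed),
                                 "cycling", fatigue, 0.5)
        win = segment(rec, 0.5, 0.0)[0]
        from fessemg.preprocess import emd
        H, freqs, _ = hht_spectrum(emd(win.samples), FS, n_freq_bins=64,
                                   n_time_bins=32)
        return (freqs * H.sum(axis=1)).sum() / H.sum()

    fresh = [mean_freq("no_fatigue", 600 + s) for s in range(10)]
    tired = [mean_freq("extreme", 600 + s) for s in range(10)]
    assert np.mean(tired) < np.mean(fresh)


# -- rendering ------------------------------------------------------------------

def test_render_shape_range_and_axes(tone_window):
    spec, freqs, times = stft_spectrogram(tone_window)
    img = render_image(spec[1:], freqs[1:], times, tone_window, "STFT")
    assert img.pixels.shape == (256, 256, 3)
    assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
    assert img.freq_axis[0] > 0 and np.all(np.diff(img.freq_axis) > 0)
    assert len(img.freq_axis) == len(img.time_axis) == 256


def test_render_constant_matrix_gives_constant_image(tone_window):
    img = render_image(np.full((10, 10), 3.3), np.linspace(1, 500, 10),
                       np.linspace(0, 0.5, 10), tone_window, "STFT")
    assert np.all(img.pixels == img.pixels[0, 0])


def test_render_invariant_to_positive_rescaling(tone_window):
    rng = np.random.default_rng(1)
    m = rng.random((30, 40))
    args = (np.linspace(1, 500, 30), np.linspace(0, 0.5, 40), tone_window, "STFT")
    a = render_image(m, *args, scaling="linear")
    b = render_image(250.0 * m, *args, scaling="linear")
    assert np.allclose(a.pixels, b.pixels, atol=1e-12)


def test_render_monotone_luminance_under_linear_scaling(tone_window):
    """Brighter colormap output follows larger matrix values."""
    values = np.linspace(0, 1, 64).reshape(8, 8)
    img = render_image(values, np.linspace(1, 500, 8), np.linspace(0, 0.5, 8),
                       tone_window, "STFT", out_size=(8, 8), scaling="linear")
    lum = img.pixels @ np.array([0.299, 0.587, 0.114])
    flat = lum[::-1].ravel()  # undo the display row flip
    assert np.all(np.diff(flat) > -1e-9)


def test_render_rejects_nan(tone_window):
    m = np.ones((4, 4))
    m[1, 1] = np.nan
    with pytest.raises(ValueError, match="finite"):
        render_image(m, np.linspace(1, 500, 4), np.linspace(0, 0.5, 4),
                     tone_window, "STFT")


@pytest.mark.parametrize("method", ["STFT", "CWT", "HHT"])
def test_window_to_image_deterministic(method, sim_config):
    rec = generate_recording(sim_config, "walking", "no_fatigue", 0.5)
    win = segment(rec, 0.5, 0.0)[0]
    a = window_to_image(win, method, out_size=(32, 32))
    b = window_to_image(win, method, out_size=(32, 32))
    assert np.array_equal(a.pixels, b.pixels)
    assert a.method == method
    assert a.pixels.shape == (32, 32, 3)
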