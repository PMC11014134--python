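"""Seeded simulator for FES-contaminated multi-channel surface EMG.

The generator replaces a private lab recording session: four bipolar sEMG
channels (left/right tibialis anterior and gastrocnemius) sampled at 8 kHz
while a functional-electrical-stimulation (FES) unit delivers a 20 Hz train
of 300 microsecond biphasic pulses to the same leg.

The voluntary sEMG carrier is band-shaped Gaussian noise whose power spectrum
follows the classic two-pole surface-EMG model

    P(f) ~ fh^4 f^2 / ((f^2 + fl^2) (f^2 + fh^2)^2),   fl = 60, fh = 120 Hz,

soft-limited to ~20-450 Hz support. Muscle fatigue is modelled as a
compression of the frequency axis (median frequency drops) together with an
RMS gain (amplitude grows) and a slowing of the contraction bursts - the
three canonical fatigue manifestations in dynamic sEMG. Motions are encoded
as per-channel activation envelopes (tonic level plus smoothed bursting);
dorsiflexion and plantarflexion are deliberately near-mirror patterns so they
remain the most confusable pair downstream.

The stimulation artifact is an ideal biphasic rectangle at the stimulator
settings followed by an exponentially damped 80 Hz oscillation standing in
for the evoked M-wave. Units are arbitrary (normalized); every quantity that
matters downstream is scale-covariant or normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .labels import (
    DAILY_MOTIONS,
    FATIGUE_LEVELS,
    MOTIONS,
    validate_fatigue,
    validate_motion,
)

WINDOW_S = 0.5  # analysis window length used throughout the pipeline


@dataclass(frozen=True)
class ChannelEnvelope:
    """Activation envelope of one channel during one motion.

    tonic: constant baseline activation level.
    burst: amplitude of the rhythmic burst component added on top.
    rate_hz: burst repetition rate (0 disables bursting).
    duty: fraction of the cycle spent bursting.
    phase: burst phase offset in cycles (0.5 = antiphase).
    """

    tonic: float
    burst: float = 0.0
    rate_hz: float = 0.0
    duty: float = 0.5
    phase: float = 0.0


def _gait_pattern(tonic, burst, rate, duty):
    # TA fires in swing, GA in stance; left and right legs alternate.
    return (
        ChannelEnvelope(tonic, burst, rate, duty, 0.0),
        ChannelEnvelope(tonic, burst, rate, duty, 0.5),
        ChannelEnvelope(tonic, burst, rate, duty, 0.5),
        ChannelEnvelope(tonic, burst, rate, duty, 0.0),
    )


def default_motion_envelopes() -> dict[str, tuple[ChannelEnvelope, ...]]:
    """Per-motion, per-channel envelope table (channels: L-TA, L-GA, R-TA, R-GA)."""
    ankle_rate, ankle_duty = 1.6, 0.5
    return {
        "sitting": tuple(ChannelEnvelope(0.25) for _ in range(4)),
        "walking": _gait_pattern(0.30, 1.00, 2.0, 0.35),
        "climbing_stairs": _gait_pattern(0.45, 1.30, 1.2, 0.55),
        # Dorsi/plantarflexion: same rhythm, mirrored dominant channels with a
        # weak antagonist co-contraction - the most confusable pair.
        "ankle_dorsiflexion": (
            ChannelEnvelope(0.20, 1.40, ankle_rate, ankle_duty, 0.0),
            ChannelEnvelope(0.15, 0.30, ankle_rate, ankle_duty, 0.0),
            ChannelEnvelope(0.20, 1.40, ankle_rate, ankle_duty, 0.0),
            ChannelEnvelope(0.15, 0.30, ankle_rate, ankle_duty, 0.0),
        ),
        "ankle_plantarflexion": (
            ChannelEnvelope(0.15, 0.30, ankle_rate, ankle_duty, 0.0),
            ChannelEnvelope(0.20, 1.40, ankle_rate, ankle_duty, 0.0),
            ChannelEnvelope(0.15, 0.30, ankle_rate, ankle_duty, 0.0),
            ChannelEnvelope(0.20, 1.40, ankle_rate, ankle_duty, 0.0),
        ),
        "cycling": _gait_pattern(0.35, 1.10, 3.0, 0.40),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic acquisition session."""

    sampling_rate_hz: float = 8000.0
    n_channels: int = 4
    stim_freq_hz: float = 20.0
    stim_pulse_width_s: float = 300e-6
    #: artifact peak as a multiple of the clean-signal RMS
    stim_amplitude_ratio: float = 10.0
    motion_envelopes: Mapping[str, tuple[ChannelEnvelope, ...]] = field(
        default_factory=default_motion_envelopes
    )
    fatigue_spectral_scale: Mapping[str, float] = field(
        default_factory=lambda: {"no_fatigue": 1.0, "medium": 0.82, "extreme": 0.66}
    )
    fatigue_amplitude_gain: Mapping[str, float] = field(
        default_factory=lambda: {"no_fatigue": 1.0, "medium": 1.25, "extreme": 1.55}
    )
    #: fatigue slows the contraction rhythm (burst-rate multiplier)
    fatigue_rate_scale: Mapping[str, float] = field(
        default_factory=lambda: {"no_fatigue": 1.0, "medium": 0.80, "extreme": 0.65}
    )
    #: depth of the ~10 Hz tremor-band amplitude modulation that appears as a
    #: muscle fatigues (visible as AM texture in time-frequency images, nearly
    #: invisible to window-aggregate amplitude/spectral summary features)
    fatigue_tremor_depth: Mapping[str, float] = field(
        default_factory=lambda: {"no_fatigue": 0.0, "medium": 0.20, "extreme": 0.40}
    )
    tremor_freq_hz: float = 10.0
    noise_rms: float = 0.03
    # Per-recording variability (electrode placement, effort, physiology):
    # lognormal sigma of per-channel gain, lognormal sigma of the global gain,
    # and additive normal sd of the fatigue spectral-compression factor.
    channel_gain_jitter: float = 0.25
    amplitude_jitter: float = 0.30
    spectral_jitter: float = 0.07
    # carrier spectral shape (Hz, before fatigue compression)
    carrier_fl_hz: float = 60.0
    carrier_fh_hz: float = 120.0
    carrier_support_hz: tuple[float, float] = (20.0, 450.0)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.sampling_rate_hz <= 0 or self.n_channels < 1:
            raise ValueError("sampling_rate_hz and n_channels must be positive")
        if self.stim_freq_hz <= 0 or self.stim_pulse_width_s <= 0:
            raise ValueError("stimulation parameters must be positive")
        if self.stim_amplitude_ratio < 0 or self.noise_rms < 0:
            raise ValueError("stim_amplitude_ratio and noise_rms must be >= 0")
        for m in MOTIONS:
            if m not in self.motion_envelopes:
                raise ValueError(f"motion_envelopes missing entry for {m!r}")
        for f in FATIGUE_LEVELS:
            for table in (self.fatigue_spectral_scale, self.fatigue_amplitude_gain):
                if f not in table:
                    raise ValueError(f"fatigue table missing entry for {f!r}")
        s = [self.fatigue_spectral_scale[f] for f in FATIGUE_LEVELS]
        if not (s[0] > s[1] > s[2] > 0):
            raise ValueError(
                "fatigue_spectral_scale must be strictly decreasing over "
                "(no_fatigue, medium, extreme) and positive"
            )
        g = [self.fatigue_amplitude_gain[f] for f in FATIGUE_LEVELS]
        if not (1.0 <= g[0] <= g[1] <= g[2]):
            raise ValueError(
                "fatigue_amplitude_gain must be non-decreasing and >= 1"
            )
        return self


@dataclass
class RawRecording:
    """One labelled multi-channel trace (channels x samples)."""

    samples: np.ndarray
    sampling_rate_hz: float
    motion_label: str
    fatigue_label: str
    stim_params: tuple[float, float, float]
    seed: int
    #: artifact-free ground truth (voluntary sEMG + sensor noise)
    clean: np.ndarray | None = None
    recording_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz


def _carrier(rng: np.random.Generator, n: int, fs: float, scale: float,
             cfg: SimulationConfig) -> np.ndarray:
    """Unit-RMS band-shaped Gaussian noise with fatigue-compressed spectrum."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # evaluate the target PSD on the *decompressed* frequency axis so that
    # compression by `scale` shifts all spectral mass down by that factor
    f = freqs / scale
    fl, fh = cfg.carrier_fl_hz, cfg.carrier_fh_hz
    psd = (fh**4 * f**2) / ((f**2 + fl**2) * (f**2 + fh**2) ** 2 + 1e-30)
    lo, hi = cfg.carrier_support_hz
    # raised-cosine band edges for finite support
    edge_lo = np.clip((f - 0.5 * lo) / (0.5 * lo), 0.0, 1.0)
    edge_hi = np.clip((1.1 * hi - f) / (0.2 * hi), 0.0, 1.0)
    taper = np.sin(0.5 * np.pi * edge_lo) ** 2 * np.sin(0.5 * np.pi * edge_hi) ** 2
    amp = np.sqrt(psd) * taper
    white = rng.standard_normal(n)
    x = np.fft.irfft(np.fft.rfft(white) * amp, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _envelope(desc: ChannelEnvelope, t: np.ndarray, fs: float,
              rate_scale: float, phase_jitter: float) -> np.ndarray:
    env = np.full(t.shape, desc.tonic)
    if desc.burst > 0 and desc.rate_hz > 0:
        cycle = (t * desc.rate_hz * rate_scale + desc.phase + phase_jitter) % 1.0
        gate = (cycle < desc.duty).astype(float)
        # ~20 ms rise/fall so bursts look physiological, not square
        gate = gaussian_filter1d(gate, sigma=0.02 * fs, mode="wrap")
        env = env + desc.burst * gate
    return env


def _mwave_template(fs: float) -> np.ndarray:
    """Damped 80 Hz oscillation following each stimulus (M-wave surrogate)."""
    t = np.arange(int(round(0.05 * fs))) / fs
    return 0.4 * np.exp(-t / 0.02) * np.sin(2 * np.pi * 80.0 * t)


def _artifact_train(rng: np.random.Generator, n: int, fs: float,
                    cfg: SimulationConfig) -> np.ndarray:
    """Unit-amplitude biphasic pulse train plus M-wave surrogates."""
    period = fs / cfg.stim_freq_hz
    width = max(1, int(round(cfg.stim_pulse_width_s * fs)))
    t0 = rng.uniform(0.0, period)
    template = _mwave_template(fs)
    out = np.zeros(n)
    pos = t0
    while pos < n:
        i = int(round(pos))
        out[i:i + width] += 1.0
        out[i + width:i + 2 * width] += -1.0
        j0 = i + 2 * width
        seg = template[: max(0, n - j0)]
        out[j0:j0 + len(seg)] += seg
        pos += period
    return out


def generate_recording(config: SimulationConfig, motion: str, fatigue: str,
                       duration_s: float) -> RawRecording:
    """Simulate one labelled recording under the configured study conditions.

    Deterministic given ``(config.seed, motion, fatigue, duration_s)``.
    """
    config.validate()
    validate_motion(motion)
    validate_fatigue(fatigue)
    if duration_s < WINDOW_S:
        raise ValueError(
            f"duration_s={duration_s} shorter than one {WINDOW_S} s window"
        )
    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed), MOTIONS.index(motion), FATIGUE_LEVELS.index(fatigue)]
        )
    )
    t = np.arange(n) / fs

    scale = config.fatigue_spectral_scale[fatigue]
    if config.spectral_jitter > 0:
        scale = float(np.clip(scale + config.spectral_jitter * rng.standard_normal(),
                              0.3, 1.1))
    amp_gain = config.fatigue_amplitude_gain[fatigue] * np.exp(
        config.amplitude_jitter * rng.standard_normal()
    )
    rate_scale = config.fatigue_rate_scale.get(fatigue, 1.0)
    tremor_depth = config.fatigue_tremor_depth.get(fatigue, 0.0)
    envelopes = config.motion_envelopes[motion]
    phase_jitter = rng.uniform()
    tremor_phase = rng.uniform(0, 2 * np.pi)

    clean = np.empty((config.n_channels, n))
    tremor = 1.0
    if tremor_depth > 0:
        tremor = 1.0 + tremor_depth * np.sin(
            2 * np.pi * config.tremor_freq_hz * t + tremor_phase)
    for c in range(config.n_channels):
        desc = envelopes[c % len(envelopes)]
        gain = amp_gain * np.exp(config.channel_gain_jitter * rng.standard_normal())
        carrier = _carrier(rng, n, fs, scale, config)
        env = _envelope(desc, t, fs, rate_scale, phase_jitter) * tremor
        clean[c] = gain * env * carrier
    if config.noise_rms > 0:
        clean = clean + config.noise_rms * rng.standard_normal(clean.shape)

    samples = clean.copy()
    if config.stim_amplitude_ratio > 0:
        train = _artifact_train(rng, n, fs, config)
        for c in range(config.n_channels):
            coupling = np.exp(0.1 * rng.standard_normal())
            a = config.stim_amplitude_ratio * np.sqrt(np.mean(clean[c] ** 2))
            samples[c] = clean[c] + a * coupling * train

    return RawRecording(
        samples=samples,
        sampling_rate_hz=fs,
        motion_label=motion,
        fatigue_label=fatigue,
        stim_params=(config.stim_freq_hz, config.stim_pulse_width_s,
                     config.stim_amplitude_ratio),
        seed=int(config.seed),
        clean=clean,
    )


def generate_dataset(config: SimulationConfig, n_windows_per_class: int,
                     duration_s: float = WINDOW_S) -> list[RawRecording]:
    """Balanced labelled dataset: ``n_windows_per_class`` recordings per motion.

    Rehabilitation motions cycle through the three fatigue levels (uniform
    when the count divides by 3); daily-task motions are always unfatigued.
    Each recording gets its own child seed, so the collection is deterministic
    for a given ``(config, config.seed)``.
    """
    if n_windows_per_class < 1:
        raise ValueError("n_windows_per_class must be >= 1")
    config.validate()
    child_seeds = np.random.SeedSequence(int(config.seed)).generate_state(
        len(MOTIONS) * n_windows_per_class
    ) & 0x7FFFFFFF
    recordings: list[RawRecording] = []
    k = 0
    for motion in MOTIONS:
        for i in range(n_windows_per_class):
            fatigue = (
                "no_fatigue" if motion in DAILY_MOTIONS
                else FATIGUE_LEVELS[i % len(FATIGUE_LEVELS)]
            )
            sub = replace(config, seed=int(child_seeds[k]))
            rec = generate_recording(sub, motion, fatigue, duration_s)
            rec.recording_id = f"{motion}_{fatigue}_{i:05d}"
            recordings.append(rec)
            k += 1
    return recordings
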