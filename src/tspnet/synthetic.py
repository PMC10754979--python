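"""Synthetic six-class motor-imagery EEG generator.

Every downstream stage (training, evaluation, band attribution) is testable
without recorded data: epochs are a 1/f "pink" background plus a
class-specific band-limited oscillation injected on a small set of target
electrodes, mimicking ERD/ERS-style band-power modulation over the scalp.

Two built-in profiles mirror the study dimensions: ``dataset_I_16ch``
(16 channels, 500 Hz, 1500 samples, 300 trials/class × 10 subjects → 18,000
epochs) and ``dataset_II_61ch`` (61 channels, 60 trials/class × 15 subjects
→ 5,400 epochs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (N_CLASSES, PROFILE_16, PROFILE_61, ConfigurationError,
                   EpochSet, default_montage)
from .occlusion import BandDefinition, BANDS


@dataclass(frozen=True)
class ClassSignature:
    """One class's discriminative fingerprint: where, which band, which sign."""

    electrodes: tuple[str, ...]
    band: BandDefinition
    sign: int = 1
    tone_hz: float | None = None  # pure-tone frequency for visualization mode


@dataclass(frozen=True)
class ClassSignatureTable:
    signatures: tuple[ClassSignature, ...]

    def __post_init__(self):
        if len(self.signatures) != N_CLASSES:
            raise ConfigurationError(f"need {N_CLASSES} class signatures")
        keys = {(s.electrodes, s.band.name, s.sign) for s in self.signatures}
        if len(keys) != N_CLASSES:
            raise ConfigurationError("class signatures must be pairwise distinct")

    def __getitem__(self, class_index: int) -> ClassSignature:
        if not 0 <= class_index < N_CLASSES:
            raise ConfigurationError(f"no signature for class {class_index}")
        return self.signatures[class_index]


def default_signatures(profile: str = PROFILE_16) -> ClassSignatureTable:
    """Six distinct (electrode, band) pairs with in-band tone frequencies.

    Target electrodes are chosen on distinct spatial-pooling rows of the
    16-channel layout so each class keeps a unique scalp focus after the
    network's 2:1 spatial reduction.
    """
    if profile == PROFILE_16:
        picks = ["C3", "P7", "O1", "F7", "F3", "T7"]
    elif profile == PROFILE_61:
        picks = ["C3", "C4", "Cz", "FC3", "CP4", "Pz"]
    else:
        raise ConfigurationError(f"unknown profile {profile!r}")
    bands = [BANDS["alpha"], BANDS["beta"], BANDS["theta"],
             BANDS["alpha"], BANDS["beta"], BANDS["delta"]]
    tones = [10.0, 20.0, 5.0, 10.0, 20.0, 2.0]
    return ClassSignatureTable(tuple(
        ClassSignature((e,), b, 1, t) for e, b, t in zip(picks, bands, tones)))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the seed fully determines the output."""

    profile: str = PROFILE_16
    n_subjects: int = 10
    trials_per_class: int = 300
    fs: float = 500.0
    n_samples: int = 1500
    effect_size: float = 1.0   # class-band amplitude relative to background SD
    noise_exponent: float = 1.0  # 1/f^x background slope
    line_noise_amplitude: float = 0.0  # 50 Hz mains; off (notch at acquisition)
    pure_tone: bool = False    # sinusoid instead of narrowband noise
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be nonnegative")
        if self.n_samples <= 0 or self.fs <= 0:
            raise ConfigurationError("n_samples and fs must be positive")

    @property
    def n_channels(self) -> int:
        return len(default_montage(self.profile))


def dataset_profile(profile: str) -> SynthConfig:
    """The study-scale generator settings for a built-in profile."""
    if profile == PROFILE_16:
        return SynthConfig(profile=PROFILE_16, n_subjects=10,
                           trials_per_class=300, fs=500.0, n_samples=1500)
    if profile == PROFILE_61:
        return SynthConfig(profile=PROFILE_61, n_subjects=15,
                           trials_per_class=60, fs=500.0, n_samples=1500)
    raise ConfigurationError(f"unknown profile {profile!r}")


def generate_background(n_channels: int, n_samples: int, fs: float,
                        noise_exponent: float, seed) -> np.ndarray:
    """Zero-mean 1/f^x background noise, unit SD per channel.

    Synthesized in the frequency domain: Gaussian spectral coefficients are
    shaped by f^(−x/2) (power ∝ f^(−x)) and inverse-transformed, so the
    periodogram slope is −x by construction.
    """
    if n_channels <= 0 or n_samples <= 0 or fs <= 0:
        raise ConfigurationError("all counts must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-noise_exponent / 2.0)
    coeffs = (rng.standard_normal((n_channels, freqs.size))
              + 1j * rng.standard_normal((n_channels, freqs.size))) * amp
    x = np.fft.irfft(coeffs, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband(band: BandDefinition, n_samples: int, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-SD random-phase narrowband process inside ``band``."""
    low = band.low
    high = min(band.high, 0.45 * fs)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    # generous padding so filter transients do not leak into the epoch
    pad = n_samples
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples + 2 * pad))
    x = x[pad:pad + n_samples]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_class_signal(class_index: int, signatures: ClassSignatureTable,
                          n_channels: int, n_samples: int, fs: float,
                          effect_size: float, seed, *,
                          montage=None, pure_tone: bool = False) -> np.ndarray:
    """Band-limited class signal on the class's target electrodes only.

    Returns a [n_channels × n_samples] array that is exactly zero when
    ``effect_size`` is 0 and zero on off-target channels always.
    """
    sig = signatures[class_index]
    out = np.zeros((n_channels, n_samples))
    if effect_size == 0:
        return out
    montage = montage or default_montage(PROFILE_16 if n_channels == 16 else PROFILE_61)
    rng = np.random.default_rng(seed)
    if pure_tone:
        f0 = sig.tone_hz if sig.tone_hz is not None else 0.5 * (sig.band.low + sig.band.high)
        t = np.arange(n_samples) / fs
        wave = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    else:
        wave = _narrowband(sig.band, n_samples, fs, rng)
    for name in sig.electrodes:
        out[montage.index(name)] = sig.sign * effect_size * wave
    return out


def generate_epoch_set(config: SynthConfig,
                       signatures: ClassSignatureTable | None = None,
                       dtype=np.float32) -> EpochSet:
    """Balanced labeled epochs: background + class signal (+ optional mains).

    Trials are ordered subject-major, then class, then repetition; the
    experiment protocol reshuffles them anyway.  Total epochs =
    n_subjects × 6 × trials_per_class.
    """
    signatures = signatures or default_signatures(config.profile)
    montage = default_montage(config.profile)
    n_ch, n_s = len(montage), config.n_samples
    n_total = config.n_subjects * N_CLASSES * config.trials_per_class
    data = np.empty((n_total, n_ch, n_s), dtype=dtype)
    labels = np.empty(n_total, dtype=np.int64)
    root = np.random.SeedSequence(config.seed)
    trial_seeds = root.spawn(n_total)
    mains = 0.0
    if config.line_noise_amplitude:
        t = np.arange(n_s) / config.fs
        mains = config.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t)
    i = 0
    for _ in range(config.n_subjects):
        for cls in range(N_CLASSES):
            for _ in range(config.trials_per_class):
                ss = trial_seeds[i].spawn(2)
                x = generate_background(n_ch, n_s, config.fs,
                                        config.noise_exponent, ss[0])
                x = x + generate_class_signal(
                    cls, signatures, n_ch, n_s, config.fs,
                    config.effect_size, ss[1], montage=montage,
                    pure_tone=config.pure_tone)
                data[i] = x + mains
                labels[i] = cls
                i += 1
    return EpochSet(data=data, labels=labels, fs=config.fs,
                    channel_names=montage.channel_names)
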