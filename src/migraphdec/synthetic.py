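"""Synthetic motor-imagery EEG with controllable ERD, coupling and 1/f noise.

Real MI trials differ between classes mainly through event-related
desynchronisation (ERD): imagining a movement suppresses band power of the
mu (8-12 Hz) and beta (18-26 Hz) rhythms over the contralateral sensorimotor
cortex.  The generator emulates exactly the statistics the decoder relies
on: a 1/f^exponent coloured-noise background, narrow-band oscillations whose
amplitude is scaled by sqrt(erd_factor) on class-specific channels, and
optional coupling blocks of channels sharing a common oscillatory phase so
that phase-locking-value graphs have controllable structure.

Oscillations are amplitude-modulated sinusoids with a random-walk phase —
far simpler than a neural-mass model, but sufficient to exercise the filter
bank, PLV graphs and ERD-driven classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .eeg_data import BCI2A_CHANNELS, TrialSet

__all__ = ["ClassRecipe", "SynthSpec", "generate", "make_separable_benchmark"]

#: sensorimotor channel groups of the 22-electrode montage
LEFT_MOTOR = [6, 7, 13]      # C5, C3, CP3
RIGHT_MOTOR = [11, 12, 17]   # C4, C6, CP4
MIDLINE_MOTOR = [3, 9, 15]   # FCz, Cz, CPz
PARIETAL = [19, 20, 21]      # Pz, P2, POz

MU_BAND = (8.0, 12.0)
BETA_BAND = (18.0, 26.0)


@dataclass
class ClassRecipe:
    """How one MI class modulates the background rhythms.

    ``erd_factor`` multiplies the band power of the oscillation on
    ``target_channels`` (< 1 = desynchronisation).  ``coupling_blocks`` are
    channel groups that share a common phase process, mixed with each
    channel's private phase by ``coupling_strength``.
    """

    name: str
    target_band: tuple[float, float] = MU_BAND
    target_channels: list[int] = field(default_factory=list)
    erd_factor: float = 1.0
    coupling_blocks: list[list[int]] = field(default_factory=list)
    coupling_strength: float = 0.0

    def __post_init__(self):
        if not self.erd_factor > 0:
            raise ValueError("erd_factor must be positive")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")


@dataclass
class SynthSpec:
    """Full description of a synthetic MI recording."""

    classes: list[ClassRecipe]
    n_trials_per_class: int = 50
    C: int = 22
    T: int = 1000
    fs: float = 250.0
    noise_exponent: float = 1.0
    snr_db: float = 6.0
    seed: int = 0

    def __post_init__(self):
        for r in self.classes:
            lo, hi = r.target_band
            if hi >= self.fs / 2:
                raise ValueError(f"band {r.target_band} exceeds Nyquist")
            for ch in r.target_channels:
                if ch >= self.C:
                    raise ValueError(f"channel index {ch} >= C={self.C}")
            for block in r.coupling_blocks:
                for ch in block:
                    if ch >= self.C:
                        raise ValueError(f"channel index {ch} >= C={self.C}")


def _colored_noise(rng: np.random.Generator, C: int, T: int, fs: float,
                   exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent,
    unit variance per channel."""
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((C, freqs.size))
            + 1j * rng.standard_normal((C, freqs.size))) * amp
    x = np.fft.irfft(spec, n=T, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    return x / np.maximum(std, 1e-12)


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean per-channel power of x inside the band (periodogram sum)."""
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    X = np.fft.rfft(x, axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    # Parseval: variance contribution of the selected bins
    return float((2.0 * np.abs(X[..., sel]) ** 2).sum() /
                 (x.shape[-1] ** 2 * x.shape[0]))


def _phase_process(rng: np.random.Generator, T: int, fs: float,
                   band: tuple[float, float], step_std: float = 0.1
                   ) -> np.ndarray:
    """Full oscillation phase: a carrier drawn uniformly inside the band
    plus a slow random walk, so the component is band-limited rather than a
    pure tone and independent processes decorrelate."""
    f0 = rng.uniform(band[0] + 0.5, band[1] - 0.5)
    tt = np.arange(T) / fs
    return (2 * np.pi * f0 * tt + rng.uniform(-np.pi, np.pi)
            + np.cumsum(rng.standard_normal(T) * step_std))


def _envelope(rng: np.random.Generator, T: int, fs: float) -> np.ndarray:
    slow = gaussian_filter1d(rng.standard_normal(T), sigma=fs / 8.0)
    slow = slow / max(slow.std(), 1e-12) * 0.3
    return np.clip(1.0 + slow, 0.1, None)


def generate(spec: SynthSpec) -> TrialSet:
    """Draw a fully seeded TrialSet realising the given recipe."""
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.classes)
    n = spec.n_trials_per_class * n_classes
    signals = np.empty((n, spec.C, spec.T), dtype=np.float64)
    labels = np.empty(n, dtype=np.int64)

    # every class's target channels carry their band's rhythm in every trial;
    # the trial's own class applies its erd_factor on its target set
    baseline = [(r.target_band, tuple(r.target_channels)) for r in spec.classes
                if r.target_channels]

    trial = 0
    for ci, recipe in enumerate(spec.classes):
        for _ in range(spec.n_trials_per_class):
            noise = _colored_noise(rng, spec.C, spec.T, spec.fs,
                                   spec.noise_exponent)
            x = noise.copy()

            # channel -> (shared phase process, strength) for this trial
            block_phase: dict[int, tuple[np.ndarray, float]] = {}
            for block in recipe.coupling_blocks:
                shared = _phase_process(rng, spec.T, spec.fs,
                                        recipe.target_band)
                for ch in block:
                    block_phase[ch] = (shared, recipe.coupling_strength)

            for band, channels in baseline:
                p_noise = _band_power(noise[list(channels)], spec.fs, band)
                amp = np.sqrt(2.0 * p_noise * 10.0 ** (spec.snr_db / 10.0))
                for ch in channels:
                    a = amp
                    if (band, channels) == (recipe.target_band,
                                            tuple(recipe.target_channels)):
                        a = amp * np.sqrt(recipe.erd_factor)
                    priv = _phase_process(rng, spec.T, spec.fs, band)
                    if ch in block_phase:
                        shared, cs = block_phase[ch]
                        phase = cs * shared + (1.0 - cs) * priv
                    else:
                        phase = priv
                    env = _envelope(rng, spec.T, spec.fs)
                    x[ch] += a * env * np.cos(phase)

            # coupled channels outside any baseline set still need a rhythm
            for ch, (shared, cs) in block_phase.items():
                if not any(ch in chans for _, chans in baseline):
                    p_noise = _band_power(noise[[ch]], spec.fs,
                                          recipe.target_band)
                    amp = np.sqrt(2.0 * p_noise * 10 ** (spec.snr_db / 10.0))
                    priv = _phase_process(rng, spec.T, spec.fs,
                                          recipe.target_band)
                    phase = cs * shared + (1.0 - cs) * priv
                    env = _envelope(rng, spec.T, spec.fs)
                    x[ch] += amp * env * np.cos(phase)

            signals[trial] = x
            labels[trial] = ci
            trial += 1

    names = (BCI2A_CHANNELS if spec.C == len(BCI2A_CHANNELS)
             else [f"ch{i:02d}" for i in range(spec.C)])
    return TrialSet(
        signals=signals,
        labels=labels,
        fs=spec.fs,
        channel_names=names,
        class_names=[r.name for r in spec.classes],
    )


_DIFFICULTY = {
    # (erd_factor, snr_db): contrast shrinks and noise grows with difficulty
    "easy": (0.2, 6.0),
    "medium": (0.45, 3.0),
    "hard": (0.7, 0.0),
}


def two_class_spec(difficulty: str = "easy", seed: int = 0,
                   n_trials_per_class: int = 100) -> SynthSpec:
    """Left/right-hand MI: mu-ERD over the contralateral motor cortex."""
    erd, snr = _DIFFICULTY[difficulty]
    classes = [
        ClassRecipe("left_hand", MU_BAND, RIGHT_MOTOR, erd_factor=erd),
        ClassRecipe("right_hand", MU_BAND, LEFT_MOTOR, erd_factor=erd),
    ]
    return SynthSpec(classes=classes, n_trials_per_class=n_trials_per_class,
                     snr_db=snr, seed=seed)


def four_class_spec(difficulty: str = "easy", seed: int = 0,
                    n_trials_per_class: int = 72) -> SynthSpec:
    erd, snr = _DIFFICULTY[difficulty]
    classes = [
        ClassRecipe("left_hand", MU_BAND, RIGHT_MOTOR, erd_factor=erd),
        ClassRecipe("right_hand", MU_BAND, LEFT_MOTOR, erd_factor=erd),
        ClassRecipe("feet", BETA_BAND, MIDLINE_MOTOR, erd_factor=erd),
        ClassRecipe("tongue", BETA_BAND, PARIETAL, erd_factor=erd),
    ]
    return SynthSpec(classes=classes, n_trials_per_class=n_trials_per_class,
                     snr_db=snr, seed=seed)


def make_separable_benchmark(
    difficulty: str = "easy",
    seed: int = 0,
    n_classes: int = 2,
    n_train_per_class: int = 100,
    n_test_per_class: int = 50,
) -> tuple[TrialSet, TrialSet]:
    """Canned class-balanced train/test TrialSets at C=22, T=1000, fs=250."""
    if difficulty not in _DIFFICULTY:
        raise ValueError(f"difficulty must be one of {sorted(_DIFFICULTY)}")
    maker = two_class_spec if n_classes == 2 else four_class_spec
    train = generate(maker(difficulty, seed=seed,
                           n_trials_per_class=n_train_per_class))
    test = generate(maker(difficulty, seed=seed + 10_000,
                          n_trials_per_class=n_test_per_class))
    return train, test
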