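"""Synthetic multi-class motor-imagery-like EEG with controllable
spatial discriminability.

Each trial mixes band-limited (8-30 Hz) stochastic oscillations — filtered
Gaussian noise, not pure sinusoids, so downstream decompositions and
covariance estimates behave as they would on real rhythms — through a
class-specific spatial gain pattern, then adds channel-independent pink
background noise.  Classes differ only in how strongly each latent source
projects to the channels, i.e. in their spatial covariance, which is
exactly the structure CSP is built to exploit.  A ``discriminability`` knob
scales the between-class gain differences; zero makes all classes
identically distributed (the null preset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from lmdcsp.dataset import EEGTrialSet
from lmdcsp.preprocess import RawTrial

DEFAULT_CLASSES = ("abduction", "extension", "flexion")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings mirroring a 14-channel, 128 Hz recording with 20
    trials per class.

    ``snr`` is the ratio of mean per-channel rhythm power to background
    noise power; ``discriminability`` scales the log-gain contrast between
    class mixing patterns (0 = null data).  ``artifact_amplitude`` adds an
    optional low-frequency (< 4 Hz) common artifact for testing that the
    band-pass front end suppresses it.
    """

    n_channels: int = 14
    sampling_rate: float = 128.0
    trial_seconds: float = 4.0
    trials_per_class: int = 20
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    discriminability: float = 1.0
    snr: float = 4.0
    rhythm_band: tuple[float, float] = (8.0, 30.0)
    artifact_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_channels, self.trials_per_class, len(self.class_names)) < 1:
            raise ValueError("counts must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.discriminability < 0:
            raise ValueError("discriminability must be >= 0")


def _mixing_structure(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Shared orthogonal source-to-channel basis Q and per-class source
    gains g_c (classes x sources), both deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    M = config.n_channels
    Q, _ = np.linalg.qr(rng.standard_normal((M, M)))
    patterns = rng.standard_normal((len(config.class_names), M))
    patterns -= patterns.mean(axis=0, keepdims=True)  # contrasts, not offsets
    norms = np.linalg.norm(patterns, axis=1, keepdims=True)
    patterns = patterns / np.where(norms > 0, norms, 1.0) * np.sqrt(M)
    gains = np.exp(0.5 * config.discriminability * patterns)
    return Q, gains


def _noise_power(config: SynthConfig, gains: np.ndarray) -> float:
    mean_rhythm_power = float(np.mean(gains**2))
    return mean_rhythm_power / config.snr


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Channel-independent 1/f-shaped noise with unit variance per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    weight = np.ones_like(freqs)
    weight[1:] = 1.0 / np.sqrt(freqs[1:])
    weight[0] = 0.0
    shaped = np.fft.irfft(spectrum * weight, n=n, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    return shaped / np.where(std > 0, std, 1.0)


def generate(config: SynthConfig = SynthConfig()) -> EEGTrialSet:
    """Draw a balanced, labelled trial set; bit-identical under one seed."""
    rng = np.random.default_rng(config.seed + 1)  # trial noise stream
    Q, gains = _mixing_structure(config)
    noise_var = _noise_power(config, gains)
    fs = config.sampling_rate
    n = int(round(config.trial_seconds * fs))
    sos = sps.butter(4, list(config.rhythm_band), btype="bandpass", fs=fs, output="sos")
    trials: list[RawTrial] = []
    for label, g in zip(config.class_names, gains):
        A = Q * g  # mixing: channel c gets sum_j Q[c,j] * g[j] * source_j
        for _ in range(config.trials_per_class):
            raw_sources = rng.standard_normal((config.n_channels, n))
            sources = sps.sosfiltfilt(sos, raw_sources, axis=1)
            # symmetric (ZCA) whitening gives the latent sources an exactly
            # identity sample covariance, so the per-class channel covariance
            # of the rhythm part is exactly A_c A_c^T every trial
            cs = sources @ sources.T / n
            evals, evecs = np.linalg.eigh(cs)
            sources = (evecs / np.sqrt(evals)) @ evecs.T @ sources
            x = A @ sources
            x += np.sqrt(noise_var) * _pink_noise(rng, (config.n_channels, n))
            if config.artifact_amplitude > 0:
                sos_lo = sps.butter(4, 4.0, btype="lowpass", fs=fs, output="sos")
                drift = sps.sosfiltfilt(sos_lo, rng.standard_normal(n))
                drift /= max(drift.std(), 1e-12)
                x += config.artifact_amplitude * drift[None, :]
            trials.append(
                RawTrial(data=x, sampling_rate=fs, label=label)
            )
    return EEGTrialSet(trials=tuple(trials), class_names=config.class_names, subject="synthetic")


def ground_truth_covariances(config: SynthConfig = SynthConfig()) -> dict[str, np.ndarray]:
    """Analytic class covariances implied by the mixing structure:
    ``Q diag(g_c^2) Q^T + noise_var * I`` (unit-variance sources)."""
    Q, gains = _mixing_structure(config)
    noise_var = _noise_power(config, gains)
    M = config.n_channels
    return {
        label: Q @ np.diag(g**2) @ Q.T + noise_var * np.eye(M)
        for label, g in zip(config.class_names, gains)
    }


PRESETS = {
    # the study conditions: 14 channels, 128 Hz, 20 trials/class, strongly
    # class-specific spatial structure
    "paper14": SynthConfig(),
    # identically distributed classes: any decoder should sit at chance
    "null": SynthConfig(discriminability=0.0),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)
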