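"""Synthetic two-class motor-imagery EEG with a known linear forward model.

The generator realizes the standard instantaneous-mixing picture behind CSP:
observed channels are a fixed linear combination of latent sources plus
sensor noise,

    X = A S + E,

where ``A`` (channels x sources) holds the spatial patterns.  Two latent mu
rhythm sources (~10 Hz amplitude-modulated sinusoids) carry the class
information: in a trial of class k the class-k source's amplitude is scaled
by ``sqrt(1 - erd_depth)``, i.e. its band power is attenuated by the factor
``1 - erd_depth`` — event-related desynchronization expressed purely as a
variance change, which is exactly the quantity CSP contrasts.  Additional
common sources (band-limited noise) and white sensor noise are identically
distributed across classes.

The true mixing matrix is returned alongside the data so that recovery
tests can compare fitted CSP patterns against ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .dataset import MIEEGDataset

__all__ = ["SynthConfig", "ForwardModel", "generate_mi_dataset"]


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for a two-class motor-imagery dataset.

    Defaults describe a small sensorimotor montage: 8 channels, 2-second
    epochs at 250 Hz (500 samples), 100 trials per class, a 10 Hz mu rhythm
    of 2 Hz bandwidth, and moderate ERD.
    """

    n_channels: int = 8
    n_samples_per_trial: int = 500
    sampling_rate: float = 250.0
    n_trials_per_class: int = 100
    mu_freq: float = 10.0
    mu_bandwidth: float = 2.0
    erd_depth: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0
    n_common_sources: int = 2

    def validate(self) -> None:
        if self.n_channels >= self.n_samples_per_trial:
            raise ValueError(
                "channel count must be smaller than samples per trial "
                f"({self.n_channels} >= {self.n_samples_per_trial}); the trial "
                "covariance would otherwise be rank deficient"
            )
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must lie in [0, 1]; got {self.erd_depth}")
        if self.sampling_rate <= 2.0 * (self.mu_freq + self.mu_bandwidth):
            raise ValueError(
                "sampling_rate must exceed twice the top of the mu band "
                f"({self.sampling_rate} <= 2*({self.mu_freq} + {self.mu_bandwidth}))"
            )
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be at least 1")
        total_sources = 2 + self.n_common_sources
        if self.n_channels < total_sources:
            raise ValueError(
                f"need n_channels >= {total_sources} to mix 2 class sources "
                f"and {self.n_common_sources} common sources"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclasses.dataclass(frozen=True)
class ForwardModel:
    """Ground-truth linear mixing used to synthesize a dataset.

    ``mixing`` columns are spatial patterns: columns 0 and 1 belong to the
    class-1 and class-2 mu sources, the rest to common sources shared by
    both classes.
    """

    mixing: np.ndarray
    n_class_sources_1: int
    n_class_sources_2: int
    n_common_sources: int

    def __post_init__(self) -> None:
        n_sources = self.n_class_sources_1 + self.n_class_sources_2 + self.n_common_sources
        if self.mixing.shape[1] != n_sources:
            raise ValueError("mixing column count inconsistent with source counts")
        if self.mixing.shape[0] < n_sources:
            raise ValueError("need at least as many channels as sources")
        if np.linalg.matrix_rank(self.mixing) < n_sources:
            raise ValueError("mixing matrix must have full column rank")

    @property
    def class_pattern(self) -> dict[int, np.ndarray]:
        """Spatial pattern (mixing column) of each class's mu source."""
        return {1: self.mixing[:, 0], 2: self.mixing[:, 1]}

    def unmix(self, trials: np.ndarray) -> np.ndarray:
        """Recover source signals via the pseudoinverse of the mixing."""
        pinv = np.linalg.pinv(self.mixing)
        return np.einsum("sc,tcn->tsn", pinv, trials)


def _mu_source(
    rng: np.random.Generator, n: int, fs: float, freq: float, bandwidth: float
) -> np.ndarray:
    """Unit-RMS amplitude-modulated sinusoid at the mu frequency.

    The modulation envelope spreads the line spectrum over roughly
    ``freq +/- bandwidth/2``.
    """
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    env_freq = rng.uniform(0.2, max(0.3, bandwidth / 2.0))
    env_phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * env_freq * t + env_phase)
    s = envelope * np.sin(2 * np.pi * freq * t + phase)
    return s / np.sqrt(np.mean(s**2))


def _band_noise(rng: np.random.Generator, n: int, fs: float, band=(4.0, 30.0)) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (common background rhythm)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_mi_dataset(config: SynthConfig) -> tuple[MIEEGDataset, ForwardModel]:
    """Generate a labeled two-class dataset and its ground-truth mixing.

    Both mu sources are active in every trial; in class-k trials the class-k
    source's amplitude is scaled by ``sqrt(1 - erd_depth)`` so its power
    drops by the factor ``1 - erd_depth`` while the other class's source
    stays at baseline.  Identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sources = 2 + config.n_common_sources

    # random orthogonal patterns (full rank, identifiable) with heterogeneous
    # per-source projection gains: real sources reach the scalp with unequal
    # strengths, and exactly equal class-source norms would make the
    # channel-averaged mu power identical across classes, hiding the ERD
    # from pooled-power statistics
    gauss = rng.standard_normal((config.n_channels, n_sources))
    q, _ = np.linalg.qr(gauss)
    gains = rng.uniform(0.5, 1.5, size=n_sources)
    mixing = q[:, :n_sources] * gains
    model = ForwardModel(
        mixing=mixing,
        n_class_sources_1=1,
        n_class_sources_2=1,
        n_common_sources=config.n_common_sources,
    )

    n_total = 2 * config.n_trials_per_class
    labels = np.repeat([1, 2], config.n_trials_per_class)
    atten = np.sqrt(1.0 - config.erd_depth)

    trials = np.empty((n_total, config.n_channels, config.n_samples_per_trial))
    for i, label in enumerate(labels):
        sources = np.empty((n_sources, config.n_samples_per_trial))
        for k in range(2):
            s = _mu_source(
                rng,
                config.n_samples_per_trial,
                config.sampling_rate,
                config.mu_freq,
                config.mu_bandwidth,
            )
            if label == k + 1:
                s = s * atten
            sources[k] = s
        for k in range(config.n_common_sources):
            sources[2 + k] = _band_noise(
                rng, config.n_samples_per_trial, config.sampling_rate
            )
        noise = config.noise_sd * rng.standard_normal(
            (config.n_channels, config.n_samples_per_trial)
        )
        trials[i] = mixing @ sources + noise

    dataset = MIEEGDataset(
        trials=trials,
        labels=labels,
        sampling_rate=config.sampling_rate,
        channel_names=[f"CH{c + 1}" for c in range(config.n_channels)],
        provenance=f"synthetic: {config}",
    )
    return dataset, model
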