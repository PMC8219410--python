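"""Synthetic labelled EEG: band-limited sinusoids plus white noise.

Each attention class has a per-band amplitude profile; by default beta and
gamma power increase with the class while theta decreases (the usual
theta/beta-ratio convention), which makes the five classes separable in
band-power space.  Epochs are sums of sinusoids at the dyadic subband
centres (2, 6, 12, 24, 48 Hz) with random phases per channel, plus
Gaussian broadband noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import DEFAULT_CHANNELS, AttentionLevel, Epoch
from .wavelet_mra import EEG_BANDS

__all__ = [
    "BAND_CENTER_HZ",
    "ClassProfile",
    "generate_epoch",
    "generate_dataset",
    "generate_level_stream",
]

#: test-tone frequency inside each dyadic subband, keyed by band name
BAND_CENTER_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 12.0, "beta": 24.0, "gamma": 48.0}


@dataclass(frozen=True)
class ClassProfile:
    """Per-class band amplitudes (microvolts) plus broadband noise level."""

    amplitudes: tuple[tuple[float, ...], ...]  # (5 classes) x (5 bands)
    noise_sd: float = 1.0
    drift: float = 0.0  # optional very-low-frequency trend amplitude

    def __post_init__(self) -> None:
        if len(self.amplitudes) != 5 or any(len(a) != len(EEG_BANDS) for a in self.amplitudes):
            raise ValueError("profile needs 5 classes x 5 band amplitudes")
        if any(a < 0 for row in self.amplitudes for a in row):
            raise ValueError("band amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def default(cls, separation: float = 1.0, noise_sd: float = 1.0) -> "ClassProfile":
        """Separable profile; ``separation=0`` collapses all classes together.

        beta and gamma amplitudes rise strictly with the class, theta falls
        strictly, delta and alpha stay flat.
        """
        if not 0.0 <= separation:
            raise ValueError("separation must be non-negative")
        rows = []
        for c in range(5):
            rows.append((
                4.0,                               # delta
                6.0 - 1.0 * c * separation,        # theta (decreasing)
                5.0,                               # alpha
                2.0 + 1.0 * c * separation,        # beta  (increasing)
                1.0 + 0.6 * c * separation,        # gamma (increasing)
            ))
        if any(a < 0 for row in rows for a in row):
            raise ValueError("separation too large: negative amplitude")
        return cls(amplitudes=tuple(rows), noise_sd=noise_sd)

    def band_amplitude(self, cls_level: int, band: str) -> float:
        return self.amplitudes[cls_level][EEG_BANDS.index(band)]


def generate_epoch(
    cls: AttentionLevel | int,
    profile: ClassProfile | None = None,
    fs: float = 256.0,
    seconds: float = 1.0,
    seed: int = 0,
    channels=DEFAULT_CHANNELS,
) -> Epoch:
    """One labelled multichannel epoch for attention class ``cls``."""
    profile = profile or ClassProfile.default()
    cls = AttentionLevel.from_any(cls)
    rng = np.random.default_rng(seed)
    n = int(round(fs * seconds))
    if n < 2:
        raise ValueError("epoch too short")
    t = np.arange(n) / fs
    data = np.zeros((n, len(channels)))
    for ci in range(len(channels)):
        sig = np.zeros(n)
        for bi, band in enumerate(EEG_BANDS):
            amp = profile.amplitudes[int(cls)][bi]
            phase = rng.uniform(0, 2 * np.pi)
            sig += amp * np.sin(2 * np.pi * BAND_CENTER_HZ[band] * t + phase)
        if profile.drift > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig += profile.drift * np.sin(2 * np.pi * 0.3 * t + phase)
        if profile.noise_sd > 0:
            sig += rng.normal(0.0, profile.noise_sd, size=n)
        data[:, ci] = sig
    return Epoch(channel_names=list(channels), data=data, fs=fs, start_index=0, label=cls)


def generate_dataset(
    n_per_class: int,
    profile: ClassProfile | None = None,
    fs: float = 256.0,
    seconds: float = 1.0,
    seed: int = 0,
    channels=DEFAULT_CHANNELS,
) -> tuple[list[Epoch], list[AttentionLevel]]:
    """Balanced 5-class epoch set, deterministically shuffled."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    profile = profile or ClassProfile.default()
    rng = np.random.default_rng(seed)
    epochs = []
    for cls in range(5):
        for _ in range(n_per_class):
            epoch_seed = int(rng.integers(0, 2**63 - 1))
            epochs.append(generate_epoch(cls, profile, fs, seconds, epoch_seed, channels))
    order = rng.permutation(len(epochs))
    epochs = [epochs[i] for i in order]
    return epochs, [e.label for e in epochs]


def generate_level_stream(
    transition_matrix,
    length: int,
    seed: int = 0,
    start: AttentionLevel | int | None = None,
) -> list[AttentionLevel]:
    """Markov-chain sample of attention levels."""
    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (5, 5):
        raise ValueError("transition matrix must be 5x5")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    if length < 1:
        raise ValueError("stream length must be >= 1")
    rng = np.random.default_rng(seed)
    state = int(rng.integers(0, 5)) if start is None else int(AttentionLevel.from_any(start))
    out = [AttentionLevel(state)]
    for _ in range(length - 1):
        state = int(rng.choice(5, p=P[state]))
        out.append(AttentionLevel(state))
    return out
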