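"""Band-power feature extraction: 4 channels x 5 EEG bands = 20 features.

Each epoch channel is decomposed with the wavelet MRA, denoised, and the
per-band reconstructions (A5 = delta ... D2 = gamma; D1 discarded as noise)
are summarised by their mean squared amplitude.  Features are ordered
channel-major: (TP9, AF7, AF8, TP10) x (delta, theta, alpha, beta, gamma).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .eeg_io import DEFAULT_CHANNELS, AttentionLevel, Epoch
from .wavelet_mra import EEG_BANDS, WaveletConfig, band_map, decompose, denoise, reconstruct_band

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "band_power",
    "extract_features",
    "extract_matrix",
    "feature_names",
]

LOG_EPS = 1e-12


@dataclass
class FeatureVector:
    values: np.ndarray
    feature_names: list[str]
    label: AttentionLevel | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.feature_names):
            raise ValueError("feature values and names misaligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_rows, n_features)
    feature_names: list[str]
    labels: list[AttentionLevel] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names) and self.values.size > 0:
            raise ValueError("feature matrix width does not match names")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("label list length does not match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix carries no labels")
        return np.array([int(l) for l in self.labels])


def feature_names(
    channels: Sequence[str] = DEFAULT_CHANNELS, bands: Sequence[str] = EEG_BANDS
) -> list[str]:
    return [f"{ch}_{band}" for ch in channels for band in bands]


def band_power(band_signal: Sequence[float]) -> float:
    """Mean squared amplitude of a band-limited signal (one power number)."""
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute band power of an empty signal")
    return float(np.mean(x**2))


def extract_features(
    epoch: Epoch,
    cfg: WaveletConfig | None = None,
    log_transform: bool = True,
    denoise_enabled: bool = True,
    relative: bool = False,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> FeatureVector:
    """decompose -> denoise -> reconstruct -> band power, per channel.

    The D1 subband (upper half of the spectrum) is treated as noise and
    excluded; with the default config this leaves the five named EEG bands.
    ``relative`` normalises each channel's powers to sum to one;
    ``log_transform`` applies log10(power + 1e-12) afterwards.
    """
    cfg = cfg or WaveletConfig()
    missing = [ch for ch in channels if ch not in epoch.channel_names]
    if missing:
        raise ValueError(
            f"epoch lacks channel(s) {missing}; has {epoch.channel_names}"
        )
    bm = band_map(cfg)
    band_to_subband = {}
    for band in EEG_BANDS:
        band_to_subband[band] = bm.subband_for(band)
    out = []
    for ch in channels:
        dec = decompose(epoch.channel(ch), cfg)
        if denoise_enabled:
            dec = denoise(dec)
        powers = np.array(
            [band_power(reconstruct_band(dec, band_to_subband[b])) for b in EEG_BANDS]
        )
        if relative:
            total = powers.sum()
            if total > 0:
                powers = powers / total
        if log_transform:
            powers = np.log10(powers + LOG_EPS)
        out.append(powers)
    return FeatureVector(
        values=np.concatenate(out),
        feature_names=feature_names(channels),
        label=epoch.label,
    )


def extract_matrix(
    epochs: Sequence[Epoch],
    cfg: WaveletConfig | None = None,
    log_transform: bool = True,
    denoise_enabled: bool = True,
    relative: bool = False,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> FeatureMatrix:
    """Row i = features of epoch i; labels carried through when present."""
    names = feature_names(channels)
    if not epochs:
        return FeatureMatrix(values=np.empty((0, len(names))), feature_names=names)
    channel_sets = {tuple(e.channel_names) for e in epochs}
    if len(channel_sets) > 1:
        raise ValueError(f"epochs have heterogeneous channel sets: {channel_sets}")
    rows, labels, any_label = [], [], False
    for e in epochs:
        fv = extract_features(
            e, cfg, log_transform=log_transform, denoise_enabled=denoise_enabled,
            relative=relative, channels=channels,
        )
        rows.append(fv.values)
        labels.append(fv.label)
        any_label = any_label or fv.label is not None
    if any_label and any(l is None for l in labels):
        raise ValueError("either all epochs or none must carry labels")
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        labels=labels if any_label else None,
    )
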