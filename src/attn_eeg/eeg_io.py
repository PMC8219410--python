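"""Recording/epoch containers, channel selection, epoching, feature CSV I/O."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._edf import EDFError, read_edf

__all__ = [
    "AttentionLevel",
    "Recording",
    "Epoch",
    "FormatError",
    "DEFAULT_CHANNELS",
    "read_recording",
    "select_channels",
    "epoch_recording",
    "write_feature_matrix",
    "read_feature_matrix",
]

logger = logging.getLogger(__name__)

#: fixed channel order used for the default feature layout
DEFAULT_CHANNELS = ("TP9", "AF7", "AF8", "TP10")


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk layout."""


class AttentionLevel(IntEnum):
    """Five-level ordinal attention scale."""

    LOW = 0
    MEDIUM_LOW = 1
    MEDIUM = 2
    MEDIUM_HIGH = 3
    HIGH = 4

    @classmethod
    def from_any(cls, value) -> "AttentionLevel":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            key = value.strip().upper().replace("-", "_").replace(" ", "_")
            try:
                return cls[key]
            except KeyError:
                raise ValueError(f"unknown attention level {value!r}") from None
        return cls(int(value))


@dataclass
class Recording:
    """Uniformly sampled multichannel EEG (microvolts)."""

    channel_names: list[str]
    data: np.ndarray  # shape (n_samples, n_channels)
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but data has "
                f"{self.data.shape[1]} columns"
            )
        if self.data.shape[0] < 1:
            raise ValueError("Recording must contain at least one sample")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]


@dataclass
class Epoch:
    """A fixed-length window cut from a Recording, optionally labelled."""

    channel_names: list[str]
    data: np.ndarray  # shape (n_samples, n_channels)
    fs: float
    start_index: int = 0
    label: AttentionLevel | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_names):
            raise ValueError("Epoch data shape inconsistent with channel names")
        if self.label is not None:
            self.label = AttentionLevel.from_any(self.label)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]


def read_recording(path: str | Path, format: str | None = None, fs: float = 256.0) -> Recording:
    """Read a recording from CSV (header = channel names) or EDF.

    For CSV the sampling rate comes from ``fs`` (the file carries none); for
    EDF it is taken from the header. ``format`` defaults to the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        try:
            names, data, edf_fs = read_edf(str(path))
        except EDFError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        return Recording(channel_names=names, data=data, fs=edf_fs)
    if format != "csv":
        raise ValueError(f"unknown recording format {format!r}")
    if fs <= 0:
        raise FormatError(f"{path}: configured sampling rate must be positive, got {fs}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed CSV ({exc})") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise FormatError(f"{path}: empty CSV recording")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in channel "
                f"{col!r} at data row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise FormatError(f"{path}: missing value in channel {col!r} at data row {row}")
        frame[col] = converted
    return Recording(channel_names=[str(c) for c in frame.columns],
                     data=frame.to_numpy(dtype=float), fs=fs)


def select_channels(rec: Recording, names: Sequence[str]) -> Recording:
    """Return a Recording with exactly ``names`` in the requested order."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise KeyError(
            f"unknown channel(s) {missing}; available: {rec.channel_names}"
        )
    cols = [rec.channel_names.index(n) for n in names]
    return Recording(channel_names=list(names), data=rec.data[:, cols], fs=rec.fs)


def epoch_recording(
    rec: Recording,
    epoch_seconds: float = 1.0,
    overlap_fraction: float = 0.0,
) -> list[Epoch]:
    """Tile the recording into fixed windows, dropping any trailing partial.

    Windows are half-open ``[start, start + length)`` with stride
    ``length * (1 - overlap_fraction)`` (at least one sample).
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    length = int(round(epoch_seconds * rec.fs))
    if length < 1:
        raise ValueError("epoch shorter than one sample")
    if rec.n_samples < length:
        logger.warning(
            "recording of %d samples shorter than one %d-sample epoch; no epochs",
            rec.n_samples, length,
        )
        return []
    stride = max(1, int(round(length * (1.0 - overlap_fraction))))
    epochs = []
    for start in range(0, rec.n_samples - length + 1, stride):
        epochs.append(
            Epoch(
                channel_names=list(rec.channel_names),
                data=rec.data[start : start + length],
                fs=rec.fs,
                start_index=start,
            )
        )
    return epochs


def _expected_columns(channels: Iterable[str], bands: Iterable[str]) -> list[str]:
    return [f"{ch}_{band}" for ch in channels for band in bands]


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Persist a FeatureMatrix to CSV (full float precision; optional label)."""
    frame = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    if matrix.labels is not None:
        frame["label"] = [int(l) for l in matrix.labels]
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(
    path: str | Path,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    bands: Sequence[str] = ("delta", "theta", "alpha", "beta", "gamma"),
):
    """Read a feature CSV written by :func:`write_feature_matrix`.

    The header must contain every ``CHANNEL_band`` column of the configured
    grid (any order tolerated — columns are realigned), plus an optional
    ``label`` column.
    """
    from .features import FeatureMatrix  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such feature file: {path}")
    frame = pd.read_csv(path)
    expected = _expected_columns(channels, bands)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing feature column(s) {missing}")
    labels = None
    if "label" in frame.columns:
        labels = [AttentionLevel(int(v)) for v in frame["label"]]
    values = frame[expected].to_numpy(dtype=float)
    return FeatureMatrix(values=values, feature_names=expected, labels=labels)
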