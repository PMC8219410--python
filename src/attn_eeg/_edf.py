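"""Minimal EDF/EDF+ reader (continuous recordings, uniform rate signals)."""

from __future__ import annotations

import numpy as np


class EDFError(ValueError):
    pass


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def read_edf(path: str):
    """Parse an EDF file into (channel_names, data[n_samples, n_channels], fs).

    Supports the plain continuous layout: every signal sampled at the same
    rate, 2-byte little-endian integers, physical scaling from the header.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise EDFError("file too short to hold an EDF header")
    try:
        n_records = int(_field(raw, 236, 8))
        record_seconds = float(_field(raw, 244, 8))
        n_signals = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise EDFError(f"malformed EDF header: {exc}") from exc
    if n_signals < 1:
        raise EDFError("EDF file declares no signals")
    header_bytes = 256 + 256 * n_signals
    if len(raw) < header_bytes:
        raise EDFError("truncated EDF signal header")
    sh = raw[256:header_bytes]

    def sig_field(offset: int, width: int, idx: int) -> str:
        base = offset * n_signals
        return sh[base + idx * width : base + (idx + 1) * width].decode(
            "ascii", errors="replace"
        ).strip()

    labels = [sig_field(0, 16, i) for i in range(n_signals)]
    phys_min = [float(sig_field(104, 8, i)) for i in range(n_signals)]
    phys_max = [float(sig_field(112, 8, i)) for i in range(n_signals)]
    dig_min = [float(sig_field(120, 8, i)) for i in range(n_signals)]
    dig_max = [float(sig_field(128, 8, i)) for i in range(n_signals)]
    samples_per_record = [int(sig_field(216, 8, i)) for i in range(n_signals)]

    if len(set(samples_per_record)) != 1:
        raise EDFError("signals with differing sampling rates are not supported")
    spr = samples_per_record[0]
    if record_seconds <= 0:
        raise EDFError("non-positive record duration in EDF header")
    fs = spr / record_seconds

    payload = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * n_signals * spr
    if payload.size < expected:
        raise EDFError("EDF data section shorter than the header declares")
    payload = payload[:expected].reshape(n_records, n_signals, spr).astype(float)

    data = np.empty((n_records * spr, n_signals))
    for i in range(n_signals):
        dig_span = dig_max[i] - dig_min[i]
        if dig_span == 0:
            raise EDFError(f"signal {labels[i]!r} has a zero digital range")
        gain = (phys_max[i] - phys_min[i]) / dig_span
        sig = payload[:, i, :].reshape(-1)
        data[:, i] = (sig - dig_min[i]) * gain + phys_min[i]
    return labels, data, fs
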