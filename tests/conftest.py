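import struct

import numpy as np
import pytest

from attn_eeg import features, synth


@pytest.fixture(scope="session")
def separable_dataset():
    """n=250 balanced 5-class synthetic epochs with the default profile."""
    epochs, labels = synth.generate_dataset(50, seed=7)
    fm = features.extract_matrix(epochs)
    return fm


@pytest.fixture(scope="session")
def small_dataset():
    """n=100 balanced set for the more expensive forest tests."""
    epochs, labels = synth.generate_dataset(20, seed=11)
    return features.extract_matrix(epochs)


@pytest.fixture(scope="session")
def degenerate_dataset():
    """All five classes share one profile: features carry no class signal."""
    profile = synth.ClassProfile.default(separation=0.0)
    epochs, labels = synth.generate_dataset(50, profile=profile, seed=7)
    return features.extract_matrix(epochs)


@pytest.fixture
def edf_factory(tmp_path):
    """Write a minimal single-rate EDF file and return its path."""

    def _pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    def make(channel_names, data, fs, record_seconds=1.0):
        data = np.asarray(data, dtype=float)
        n_sig = len(channel_names)
        spr = int(round(fs * record_seconds))
        n_records = data.shape[0] // spr
        header = b"".join([
            _pad("0", 8), _pad("synthetic", 80), _pad("synthetic", 80),
            _pad("01.01.20", 8), _pad("00.00.00", 8),
            _pad(str(256 + 256 * n_sig), 8), _pad("", 44),
            _pad(str(n_records), 8), _pad(f"{record_seconds:g}", 8),
            _pad(str(n_sig), 4),
        ])
        phys_min, phys_max = -500.0, 500.0
        dig_min, dig_max = -32768, 32767
        sig_header = b"".join([
            b"".join(_pad(n, 16) for n in channel_names),
            b"".join(_pad("", 80) for _ in channel_names),
            b"".join(_pad("uV", 8) for _ in channel_names),
            b"".join(_pad(f"{phys_min:g}", 8) for _ in channel_names),
            b"".join(_pad(f"{phys_max:g}", 8) for _ in channel_names),
            b"".join(_pad(str(dig_min), 8) for _ in channel_names),
            b"".join(_pad(str(dig_max), 8) for _ in channel_names),
            b"".join(_pad("", 80) for _ in channel_names),
            b"".join(_pad(str(spr), 8) for _ in channel_names),
            b"".join(_pad("", 32) for _ in channel_names),
        ])
        gain = (phys_max - phys_min) / (dig_max - dig_min)
        digital = np.round((data - phys_min) / gain + dig_min).astype(np.int16)
        body = b""
        for r in range(n_records):
            for s in range(n_sig):
                seg = digital[r * spr : (r + 1) * spr, s]
                body += struct.pack(f"<{spr}h", *seg)
        path = tmp_path / "rec.edf"
        path.write_bytes(header + sig_header + body)
        return path

    return make
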