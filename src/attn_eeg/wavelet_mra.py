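"""Dyadic wavelet multiresolution analysis with SURE soft-threshold denoising.

Implements an orthonormal discrete wavelet transform (Mallat cascade) with a
compactly supported Daubechies basis, per-subband reconstruction, a mapping
from dyadic subbands to the conventional EEG frequency bands, and adaptive
soft-threshold denoising where the threshold for each detail level minimises
Stein's unbiased risk estimate (the "rigrsure" rule).

Two boundary modes are provided:

``symmetric``
    Each level half-sample-symmetrically extends the signal before filtering.
    Reconstruction trims the extension, so the analysis/synthesis pair is a
    perfect-reconstruction system at every length.
``periodic``
    Circular (periodised) transform; requires an even length at every level
    and is exactly orthonormal (energy preserving).
``zero``
    Zero extension keeping every overlapping coefficient; also exactly
    energy preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WaveletConfig",
    "SubbandDecomposition",
    "BandMap",
    "decompose",
    "reconstruct",
    "reconstruct_band",
    "band_map",
    "sure_threshold",
    "soft_threshold",
    "denoise",
    "denoise_signal",
    "min_signal_length",
]

# Orthonormal scaling (lowpass) filters.  db4 = Daubechies, 4 vanishing
# moments, 8 taps.  haar kept as the trivial extensibility hook.
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "db4": np.array(
        [
            -0.010597401785069032,
            0.032883011666885206,
            0.030841381835560763,
            -0.18703481171909309,
            -0.027983769416859854,
            0.6308807679298589,
            0.7148465705529157,
            0.23037781330889648,
        ]
    ),
    "haar": np.array([0.7071067811865476, 0.7071067811865476]),
}

_BAND_NAMES_256_L5 = {
    "D1": "noise",
    "D2": "gamma",
    "D3": "beta",
    "D4": "alpha",
    "D5": "theta",
    "A5": "delta",
}

#: canonical low->high frequency ordering of the named EEG bands
EEG_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


def _qmf(lo: np.ndarray) -> np.ndarray:
    """Quadrature-mirror highpass filter of an orthonormal scaling filter."""
    taps = len(lo)
    return np.array([(-1.0) ** k * lo[taps - 1 - k] for k in range(taps)])


def _filters(basis_name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        lo = _SCALING_FILTERS[basis_name]
    except KeyError:
        known = ", ".join(sorted(_SCALING_FILTERS))
        raise ValueError(f"unknown wavelet basis {basis_name!r}; known: {known}")
    return lo, _qmf(lo)


@dataclass(frozen=True)
class WaveletConfig:
    """Parameters of the multiresolution analysis."""

    basis_name: str = "db4"
    levels: int = 5
    fs: float = 256.0
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.boundary_mode not in ("symmetric", "periodic", "zero"):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")
        _filters(self.basis_name)  # validate basis name eagerly

    @property
    def filter_length(self) -> int:
        return len(_SCALING_FILTERS[self.basis_name])


@dataclass
class SubbandDecomposition:
    """L detail coefficient sets (level 1 = finest) plus one approximation."""

    detail_coeffs: list[np.ndarray]
    approx_coeffs: np.ndarray
    config: WaveletConfig
    original_length: int
    # length of the approximation *input* at each level, needed to invert
    # the per-level extension exactly
    level_lengths: list[int] = field(default_factory=list)

    @property
    def levels(self) -> int:
        return len(self.detail_coeffs)

    def subband_ids(self) -> list[str]:
        l = self.levels
        return [f"D{j}" for j in range(1, l + 1)] + [f"A{l}"]

    def copy(self) -> "SubbandDecomposition":
        return SubbandDecomposition(
            detail_coeffs=[c.copy() for c in self.detail_coeffs],
            approx_coeffs=self.approx_coeffs.copy(),
            config=self.config,
            original_length=self.original_length,
            level_lengths=list(self.level_lengths),
        )


@dataclass(frozen=True)
class BandMap:
    """Subband id -> (f_lo, f_hi, band name); edges are dyadic in fs."""

    entries: dict[str, tuple[float, float, str | None]]

    def subband_for(self, band_name: str) -> str:
        for sid, (_, _, name) in self.entries.items():
            if name == band_name:
                return sid
        raise KeyError(f"no subband named {band_name!r}")

    def edges(self, subband_id: str) -> tuple[float, float]:
        f_lo, f_hi, _ = self.entries[subband_id]
        return f_lo, f_hi


def min_signal_length(cfg: WaveletConfig) -> int:
    """Smallest signal length admitting ``cfg.levels`` decomposition levels."""
    # each level must see at least one full filter support after halving
    return cfg.filter_length * 2 ** (cfg.levels - 1)


# ---------------------------------------------------------------------------
# single-level analysis / synthesis


def _sym_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-sample symmetric extension by ``pad`` samples on each side."""
    if pad == 0:
        return x
    n = len(x)
    if pad > n:  # reflect repeatedly for very short signals
        reps = int(np.ceil(pad / n))
        tiles = []
        flip = True
        for _ in range(reps):
            tiles.append(x[::-1] if flip else x)
            flip = not flip
        left = np.concatenate(tiles[::-1])[-pad:]
        tiles = []
        flip = True
        for _ in range(reps):
            tiles.append(x[::-1] if flip else x)
            flip = not flip
        right = np.concatenate(tiles)[:pad]
        return np.concatenate([left, x, right])
    return np.concatenate([x[pad - 1 :: -1], x, x[: n - pad - 1 : -1]])


def _analysis_zero(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Inner products with every overlapping even shift, zero extension."""
    taps = len(lo)
    start = (taps - 1) % 2
    ca = np.convolve(x, lo[::-1])[start::2]
    cd = np.convolve(x, hi[::-1])[start::2]
    return ca, cd


def _synthesis_zero(ca, cd, lo, hi, n: int) -> np.ndarray:
    taps = len(lo)
    start = (taps - 1) % 2
    shift0 = start - (taps - 1)
    ua = np.zeros(2 * len(ca) - 1)
    ua[::2] = ca
    ud = np.zeros(2 * len(cd) - 1)
    ud[::2] = cd
    rec = np.convolve(ua, lo) + np.convolve(ud, hi)
    return rec[-shift0 : -shift0 + n]


def _analysis_interior(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Inner products with the even shifts whose support lies inside x.

    Used after symmetric extension: every kept window sees only real
    (extended) data, so e.g. a constant signal yields exactly zero details.
    """
    ca = np.convolve(x, lo[::-1], mode="valid")[::2]
    cd = np.convolve(x, hi[::-1], mode="valid")[::2]
    return ca, cd


def _synthesis_interior(ca, cd, lo, hi, ne: int) -> np.ndarray:
    """Adjoint of :func:`_analysis_interior` over the extended support.

    Exact on the interior after trimming the extension margin: the dropped
    boundary windows only touch the outer ``taps - 1`` extension samples.
    """
    ua = np.zeros(2 * len(ca) - 1)
    ua[::2] = ca
    ud = np.zeros(2 * len(cd) - 1)
    ud[::2] = cd
    rec = np.convolve(ua, lo) + np.convolve(ud, hi)
    out = np.zeros(ne)
    m = min(ne, len(rec))
    out[:m] = rec[:m]
    return out


def _analysis_periodic(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    n = len(x)
    if n % 2:
        raise ValueError("periodic boundary mode requires an even length at every level")
    taps = len(lo)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(taps)[None, :]) % n
    windows = x[idx]
    return windows @ lo, windows @ hi

def _synthesis_periodic(ca, cd, lo, hi) -> np.ndarray:
    half = len(ca)
    n = 2 * half
    taps = len(lo)
    x = np.zeros(n)
    pos = (2 * np.arange(half)[:, None] + np.arange(taps)[None, :]) % n
    np.add.at(x, pos, ca[:, None] * lo[None, :] + cd[:, None] * hi[None, :])
    return x


def _dwt_single(x: np.ndarray, cfg: WaveletConfig):
    lo, hi = _filters(cfg.basis_name)
    if cfg.boundary_mode == "periodic":
        return _analysis_periodic(x, lo, hi)
    if cfg.boundary_mode == "symmetric":
        pad = len(lo) - 1
        return _analysis_interior(_sym_extend(x, pad), lo, hi)
    return _analysis_zero(x, lo, hi)


def _idwt_single(ca, cd, cfg: WaveletConfig, n: int) -> np.ndarray:
    lo, hi = _filters(cfg.basis_name)
    if cfg.boundary_mode == "periodic":
        return _synthesis_periodic(ca, cd, lo, hi)[:n]
    if cfg.boundary_mode == "symmetric":
        pad = len(lo) - 1
        xe = _synthesis_interior(ca, cd, lo, hi, n + 2 * pad)
        return xe[pad : pad + n]
    return _synthesis_zero(ca, cd, lo, hi, n)


# ---------------------------------------------------------------------------
# public operations


def decompose(signal: Sequence[float], cfg: WaveletConfig | None = None) -> SubbandDecomposition:
    """Run an ``cfg.levels``-level multiresolution decomposition.

    Returns L detail coefficient sets (xD1 finest ... xDL coarsest) plus the
    level-L approximation xA_L.  Deterministic; raises if the signal is too
    short to support the requested number of levels.
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("decompose expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    need = min_signal_length(cfg)
    if len(x) < need:
        raise ValueError(
            f"signal of length {len(x)} too short for {cfg.levels} levels "
            f"with {cfg.basis_name}; need at least {need} samples"
        )
    details: list[np.ndarray] = []
    lengths: list[int] = []
    approx = x
    for _ in range(cfg.levels):
        lengths.append(len(approx))
        ca, cd = _dwt_single(approx, cfg)
        details.append(cd)
        approx = ca
    return SubbandDecomposition(
        detail_coeffs=details,
        approx_coeffs=approx,
        config=cfg,
        original_length=len(x),
        level_lengths=lengths,
    )


def reconstruct(dec: SubbandDecomposition) -> np.ndarray:
    """Invert the full decomposition; exact for untouched coefficients."""
    cfg = dec.config
    approx = dec.approx_coeffs
    for j in range(dec.levels, 0, -1):
        n = dec.level_lengths[j - 1]
        approx = _idwt_single(approx, dec.detail_coeffs[j - 1], cfg, n)
    return approx


def reconstruct_band(dec: SubbandDecomposition, subband_id: str) -> np.ndarray:
    """Inverse transform with every subband except ``subband_id`` zeroed."""
    valid = dec.subband_ids()
    if subband_id not in valid:
        raise ValueError(f"unknown subband {subband_id!r}; expected one of {valid}")
    iso = dec.copy()
    if subband_id.startswith("D"):
        keep = int(subband_id[1:])
        iso.approx_coeffs = np.zeros_like(iso.approx_coeffs)
        for j in range(1, iso.levels + 1):
            if j != keep:
                iso.detail_coeffs[j - 1] = np.zeros_like(iso.detail_coeffs[j - 1])
    else:
        for j in range(1, iso.levels + 1):
            iso.detail_coeffs[j - 1] = np.zeros_like(iso.detail_coeffs[j - 1])
    return reconstruct(iso)


def band_map(cfg: WaveletConfig | None = None) -> BandMap:
    """Dyadic subband -> frequency-interval map.

    Detail subband Dj covers (fs/2^(j+1), fs/2^j]; the approximation A_L
    covers (0, fs/2^(L+1)].  The conventional EEG names (noise, gamma, beta,
    alpha, theta, delta) are attached for fs=256 Hz with 5 levels; any other
    configuration yields unnamed dyadic edges.
    """
    cfg = cfg or WaveletConfig()
    named = cfg.fs == 256 and cfg.levels == 5
    entries: dict[str, tuple[float, float, str | None]] = {}
    for j in range(1, cfg.levels + 1):
        sid = f"D{j}"
        f_lo, f_hi = cfg.fs / 2 ** (j + 1), cfg.fs / 2**j
        entries[sid] = (f_lo, f_hi, _BAND_NAMES_256_L5[sid] if named else None)
    sid = f"A{cfg.levels}"
    entries[sid] = (
        0.0,
        cfg.fs / 2 ** (cfg.levels + 1),
        _BAND_NAMES_256_L5["A5"] if named else None,
    )
    return BandMap(entries=entries)


# ---------------------------------------------------------------------------
# denoising


def soft_threshold(coeffs: Sequence[float], t: float) -> np.ndarray:
    """Shrink toward zero: c -> sign(c) * max(|c| - t, 0)."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    c = np.asarray(coeffs, dtype=float)
    return np.sign(c) * np.maximum(np.abs(c) - t, 0.0)


def sure_threshold(coeffs: Sequence[float], noise_scale: float = 1.0) -> float:
    """Threshold minimising Stein's unbiased risk estimate (rigrsure).

    Coefficients are normalised by ``noise_scale``; candidates are the sorted
    absolute normalised coefficients, ties broken toward the smaller
    threshold.  The returned threshold is on the normalised scale, in
    [0, max|c|/noise_scale].
    """
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("cannot compute a SURE threshold of an empty coefficient set")
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    z2 = np.sort((c / noise_scale) ** 2)
    n = z2.size
    cumsum = np.cumsum(z2)
    # candidate t_k = sqrt(z2[k]); risk(t) = n - 2*#{|z|<=t} + sum min(z^2,t^2)
    ks = np.arange(1, n + 1)
    risks = n - 2.0 * ks + cumsum + z2 * (n - ks)
    best = int(np.argmin(risks))  # argmin takes first minimum = smallest t
    return float(np.sqrt(z2[best]))


def estimate_sigma(dec: SubbandDecomposition) -> float:
    """MAD estimate of the noise scale from the finest detail coefficients."""
    d1 = dec.detail_coeffs[0]
    return float(np.median(np.abs(d1)) / 0.6745)


def denoise(dec: SubbandDecomposition, sigma_rule: str = "mad_d1") -> SubbandDecomposition:
    """SURE-soft-threshold every detail level; approximation untouched.

    The noise scale sigma is estimated once from the finest details (MAD
    rule); each level's threshold is chosen by :func:`sure_threshold` on the
    sigma-normalised coefficients of that level.
    """
    if sigma_rule != "mad_d1":
        raise ValueError(f"unknown sigma rule {sigma_rule!r}")
    out = dec.copy()
    sigma = estimate_sigma(dec)
    # effectively noise-free signals: nothing to threshold.  (The rigrsure
    # candidate grid contains no zero, so a vanishing sigma would otherwise
    # still shrink every level by its smallest coefficient.)
    all_coeffs = np.concatenate([*dec.detail_coeffs, dec.approx_coeffs])
    scale = float(np.sqrt(np.mean(all_coeffs**2)))
    if sigma <= 1e-3 * scale:
        return out
    for j, cd in enumerate(out.detail_coeffs):
        t = sure_threshold(cd, noise_scale=sigma)
        out.detail_coeffs[j] = soft_threshold(cd, t * sigma)
    return out


def denoise_signal(signal: Sequence[float], cfg: WaveletConfig | None = None) -> np.ndarray:
    """decompose -> denoise -> reconstruct convenience wrapper."""
    cfg = cfg or WaveletConfig()
    return reconstruct(denoise(decompose(signal, cfg)))
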