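"""Wavelet denoising: db7/level-4 decomposition with universal-threshold
garrote shrinkage on the D2 detail band.

The additive noise model is y = x + k with k white Gaussian noise.  The
noise scale sigma is estimated robustly from the thresholded band itself
(median absolute deviation about the median, divided by the Gaussian
consistency constant 0.6745), and the universal (Donoho-Johnstone)
threshold is lambda = sigma * sqrt(2 ln N) with N the signal length.
Non-negative garrote shrinkage -- c -> c - lambda^2/c above the threshold,
0 below -- is intermediate between hard and soft thresholding: continuous
like soft, but with less bias on large coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

#: Gaussian consistency constant: median(|Z|) for Z ~ N(0,1).
MAD_GAUSSIAN = 0.6745


@dataclass
class WaveletDecomposition:
    """Multilevel DWT coefficients of one 1-D signal.

    ``details`` is ordered finest-first: ``details[0]`` is D1, the highest
    frequency band; ``details[level-1]`` is the coarsest detail.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    wavelet_name: str
    level: int
    padding_mode: str
    original_length: int

    def __post_init__(self) -> None:
        if self.level < 1 or len(self.details) != self.level:
            raise ValueError("details must hold exactly `level` bands")

    def band(self, name: str) -> np.ndarray:
        """Return a band by name: 'A' for the approximation, 'D1'..'DL'."""
        if name == "A":
            return self.approx
        if name.startswith("D"):
            idx = int(name[1:]) - 1
            if 0 <= idx < self.level:
                return self.details[idx]
        raise KeyError(f"no band {name!r} in a level-{self.level} decomposition")


@dataclass
class ThresholdSpec:
    """A resolved shrinkage threshold: lambda = sigma * sqrt(2 ln n)."""

    lam: float
    sigma: float
    n: int
    rule: str = "universal"
    shrinkage: str = "garrote"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class WdConfig:
    """Configuration of the wavelet-denoising stage."""

    wavelet: str = "db7"
    level: int = 4
    threshold_band: str = "D2"
    rule: str = "universal"
    shrinkage: str = "garrote"
    padding_mode: str = "symmetric"


def decompose(
    signal: np.ndarray,
    wavelet_name: str = "db7",
    level: int = 4,
    padding_mode: str = "symmetric",
) -> WaveletDecomposition:
    """Multilevel discrete wavelet transform of a 1-D signal."""
    x = np.asarray(signal, dtype=float).ravel()
    w = pywt.Wavelet(wavelet_name)
    if len(x) < w.dec_len:
        raise ValueError(
            f"signal length {len(x)} shorter than the {wavelet_name} filter "
            f"({w.dec_len} taps)"
        )
    if level > pywt.dwt_max_level(len(x), w.dec_len):
        raise ValueError(
            f"signal of length {len(x)} too short for a level-{level} "
            f"{wavelet_name} decomposition"
        )
    coeffs = pywt.wavedec(x, w, mode=padding_mode, level=level)
    # pywt orders [A_L, D_L, ..., D_1]; store details finest-first (D1..DL)
    return WaveletDecomposition(
        approx=coeffs[0],
        details=list(coeffs[1:])[::-1],
        wavelet_name=wavelet_name,
        level=level,
        padding_mode=padding_mode,
        original_length=len(x),
    )


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse transform, trimmed to the original signal length."""
    coeffs = [dec.approx] + list(dec.details[::-1])
    y = pywt.waverec(coeffs, dec.wavelet_name, mode=dec.padding_mode)
    return y[: dec.original_length]


def universal_threshold(
    coeffs: np.ndarray, n: int, shrinkage: str = "garrote"
) -> ThresholdSpec:
    """Universal threshold lambda = sigma*sqrt(2 ln n) from one band.

    sigma is the median absolute deviation of the coefficients about their
    median, divided by 0.6745; ``n`` is the *signal* length, not the
    coefficient count.
    """
    c = np.asarray(coeffs, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("cannot estimate a threshold from an empty band")
    if n < 2:
        raise ValueError("universal threshold needs n >= 2")
    sigma = float(np.median(np.abs(c - np.median(c))) / MAD_GAUSSIAN)
    lam = sigma * np.sqrt(2.0 * np.log(n))
    return ThresholdSpec(lam=float(lam), sigma=sigma, n=int(n), shrinkage=shrinkage)


def shrink_garrote(coeffs: np.ndarray, lam: float) -> np.ndarray:
    """Non-negative garrote: 0 below lambda, c - lambda^2/c above.

    Odd in c, continuous at |c| = lambda, and always a contraction
    (|out| <= |c|).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    c = np.asarray(coeffs, dtype=float)
    keep = np.abs(c) > lam
    safe = np.where(keep, c, 1.0)
    return np.where(keep, c - lam**2 / safe, 0.0)


def shrink_soft(coeffs: np.ndarray, lam: float) -> np.ndarray:
    """Soft thresholding: sign(c) * max(|c| - lambda, 0)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    c = np.asarray(coeffs, dtype=float)
    return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)


def shrink_hard(coeffs: np.ndarray, lam: float) -> np.ndarray:
    """Hard thresholding: zero below lambda, identity above."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    c = np.asarray(coeffs, dtype=float)
    return np.where(np.abs(c) > lam, c, 0.0)


_SHRINKERS = {"garrote": shrink_garrote, "soft": shrink_soft, "hard": shrink_hard}


def wd_denoise(signal: np.ndarray, cfg: WdConfig | None = None) -> np.ndarray:
    """Wavelet-denoise one signal: decompose, shrink the configured detail
    band with its own universal threshold, reconstruct.

    Only the configured band (default D2) is modified; all other bands pass
    through untouched.  Output length equals input length.
    """
    cfg = cfg or WdConfig()
    if cfg.rule != "universal":
        raise ValueError(f"unknown threshold rule {cfg.rule!r}")
    try:
        shrinker = _SHRINKERS[cfg.shrinkage]
    except KeyError:
        raise ValueError(f"unknown shrinkage {cfg.shrinkage!r}") from None
    x = np.asarray(signal, dtype=float).ravel()
    dec = decompose(x, cfg.wavelet, cfg.level, cfg.padding_mode)
    band_idx = int(cfg.threshold_band[1:]) - 1
    if not 0 <= band_idx < cfg.level:
        raise ValueError(
            f"band {cfg.threshold_band!r} not present at level {cfg.level}"
        )
    spec = universal_threshold(dec.details[band_idx], n=len(x), shrinkage=cfg.shrinkage)
    dec.details[band_idx] = shrinker(dec.details[band_idx], spec.lam)
    return reconstruct(dec)
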