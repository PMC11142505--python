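"""Empirical Mode Decomposition by sifting, and noise-assisted Ensemble EMD.

EMD splits a signal into intrinsic mode functions (IMFs): oscillatory
components whose extrema and zero-crossing counts differ by at most one and
whose local mean envelope is near zero.  Sifting repeatedly subtracts the
mean of the upper and lower cubic-spline extremal envelopes until the
candidate satisfies a Cauchy-type convergence criterion *and* the IMF
counting property; the procedure then recurses on the remainder until it is
monotone (too few extrema) or the IMF budget is exhausted.  The additive
identity  signal = sum(IMFs) + residual  holds exactly by construction.

EEMD runs EMD on an ensemble of noise-perturbed copies of the signal
(white Gaussian noise, std = noise_scale * std(signal)) and averages IMFs
by ordinal position, which suppresses mode mixing at the cost of a small
residual ensemble-noise error of order noise_scale/sqrt(T).

Envelope end effects are mitigated by mirroring the two edge extrema about
each signal boundary before fitting the splines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


class TooFewExtrema(ValueError):
    """Raised when a signal is monotone/trend-like: fewer than two maxima
    or two minima, so extremal envelopes are undefined and sifting stops."""


@dataclass
class EEMDConfig:
    """Knobs of the (ensemble) decomposition.

    ``ensemble_size`` (T) and ``noise_scale`` follow the EEMD literature's
    canonical defaults (100 and 0.2).  ``noise_scale=0`` with T=1 reduces
    EEMD to plain EMD.  ``max_imfs=None`` decomposes until the residual is
    monotone.
    """

    ensemble_size: int = 100
    noise_scale: float = 0.2
    max_imfs: int | None = None
    sd_threshold: float = 0.2
    max_sifts: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1 (or None)")


@dataclass
class IMFSet:
    """Ordered IMFs (highest-frequency first) plus the residual trend."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in [*self.imfs, self.residual]:
            if len(a) != self.source_length:
                raise ValueError("all IMFs and the residual must share the "
                                 "source signal length")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def sum_imfs(self, upto: int | None = None) -> np.ndarray:
        """Sum of the first ``upto`` IMFs (all of them when None)."""
        sel = self.imfs[:upto] if upto is not None else self.imfs
        if not sel:
            return np.zeros(self.source_length)
        return np.sum(sel, axis=0)

    def reconstruct(self) -> np.ndarray:
        return self.sum_imfs() + self.residual


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus count once, at their
    trailing edge."""
    d = np.diff(x)
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # carry the last non-zero slope sign across flat segments
    idx = np.where(nz, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0)
    ds = np.diff(filled)
    maxima = np.nonzero(ds < 0)[0] + 1
    minima = np.nonzero(ds > 0)[0] + 1
    return maxima, minima


def count_extrema(x: np.ndarray) -> int:
    mx, mn = _extrema_indices(np.asarray(x, dtype=float))
    return len(mx) + len(mn)


def count_zero_crossings(x: np.ndarray) -> int:
    """Sign changes of the signal, ignoring exact zeros."""
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def is_imf(x: np.ndarray) -> bool:
    """The IMF counting property: |#extrema - #zero-crossings| <= 1."""
    return abs(count_extrema(x) - count_zero_crossings(x)) <= 1


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through extrema, with the two edge extrema mirrored
    about each boundary to tame end effects."""
    left_i = -idx[1::-1]  # mirror (idx0, idx1) about t=0, ascending order
    left_v = val[1::-1]
    last = n - 1
    right_i = 2 * last - idx[-1:-3:-1]
    right_v = val[-1:-3:-1]
    xs = np.concatenate([left_i, idx, right_i])
    ys = np.concatenate([left_v, val, right_v])
    keep = np.concatenate([[True], np.diff(xs) > 0])
    xs, ys = xs[keep], ys[keep]
    return CubicSpline(xs, ys)(np.arange(n))


def mean_envelope(signal: np.ndarray) -> np.ndarray:
    """Mean of the upper (maxima) and lower (minima) cubic-spline envelopes.

    Raises :class:`TooFewExtrema` when the signal has fewer than two maxima
    or two minima -- the caller's signal that sifting has hit a monotone
    trend.
    """
    x = np.asarray(signal, dtype=float).ravel()
    maxima, minima = _extrema_indices(x)
    if len(maxima) < 2 or len(minima) < 2:
        raise TooFewExtrema(
            f"need >=2 maxima and >=2 minima, found {len(maxima)}/{len(minima)}"
        )
    upper = _mirrored_spline(maxima, x[maxima], len(x))
    lower = _mirrored_spline(minima, x[minima], len(x))
    return 0.5 * (upper + lower)


def _sift(residual: np.ndarray, cfg: EEMDConfig) -> np.ndarray | None:
    """Extract one IMF from ``residual``, or None when it is a trend."""
    try:
        h = residual - mean_envelope(residual)
    except TooFewExtrema:
        return None
    for _ in range(cfg.max_sifts - 1):
        denom = float(np.sum(h**2))
        if denom == 0.0:
            break
        try:
            h_new = h - mean_envelope(h)
        except TooFewExtrema:
            break
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < cfg.sd_threshold and is_imf(h):
            break
    return h


def emd(signal: np.ndarray, cfg: EEMDConfig | None = None) -> IMFSet:
    """Plain EMD of a 1-D signal (``cfg.noise_scale``/``ensemble_size``
    are ignored here; only the sifting controls apply).

    The residual carries whatever sifting could not decompose, so
    ``sum(imfs) + residual == signal`` exactly.
    """
    cfg = cfg or EEMDConfig()
    cfg.validate()
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 16:
        raise ValueError("signal too short for EMD (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    limit = cfg.max_imfs if cfg.max_imfs is not None else np.inf
    while len(imfs) < limit:
        imf = _sift(residual, cfg)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(imfs=imfs, residual=residual, source_length=len(x))


def eemd(signal: np.ndarray, cfg: EEMDConfig | None = None) -> IMFSet:
    """Ensemble EMD: average the EMDs of T noise-perturbed copies.

    Member IMFs are aligned by ordinal position; members that produce fewer
    IMFs contribute zeros to the missing positions.  The averaged residual
    is the mean of member residuals, so the reconstruction differs from the
    clean signal only by the ensemble-mean of the added noise
    (O(noise_scale/sqrt(T))).  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or EEMDConfig()
    cfg.validate()
    x = np.asarray(signal, dtype=float).ravel()
    if cfg.noise_scale == 0.0 and cfg.ensemble_size == 1:
        out = emd(x, cfg)
        out.meta = {"ensemble_size": 1, "noise_scale": 0.0, "seed": cfg.seed}
        return out
    sig_std = float(np.std(x))
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.ensemble_size)
    members: list[IMFSet] = []
    for child in children:
        rng = np.random.default_rng(child)
        noisy = x + rng.standard_normal(x.size) * (cfg.noise_scale * sig_std)
        members.append(emd(noisy, cfg))
    n_imfs = max(m.n_imfs for m in members)
    imfs = []
    for q in range(n_imfs):
        stack = [
            m.imfs[q] if q < m.n_imfs else np.zeros(x.size) for m in members
        ]
        imfs.append(np.mean(stack, axis=0))
    residual = np.mean([m.residual for m in members], axis=0)
    return IMFSet(
        imfs=imfs,
        residual=residual,
        source_length=x.size,
        meta={
            "ensemble_size": cfg.ensemble_size,
            "noise_scale": cfg.noise_scale,
            "seed": cfg.seed,
        },
    )
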