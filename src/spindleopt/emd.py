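"""Empirical mode decomposition and related instantaneous-frequency tools.

The sifting procedure decomposes a signal into intrinsic mode functions
(IMFs): oscillatory components obtained by repeatedly subtracting the mean of
cubic-spline envelopes through the local maxima and minima. The decomposition
is exact by construction — the IMFs plus the residual always sum back to the
input.

Numerical choices (the originating literature leaves them open):

* stopping rule per IMF: normalized squared difference between successive
  sifts < 0.2, or 10 sift iterations, whichever comes first;
* boundary handling: mirror extension of the two outermost extrema at each
  end before spline fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .io import Recording

logger = logging.getLogger(__name__)

_SD_STOP = 0.2
_MAX_SIFT = 10


@dataclass(frozen=True)
class ImfSet:
    """Result of a sifting run: IMFs plus the final residual."""

    imfs: tuple[np.ndarray, ...]
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through (idx, val) evaluated on 0..n-1, with the two
    outermost knots mirrored past each boundary to tame end swings."""
    if idx.size >= 2:
        left_i = 2 * idx[0] - idx[1:3][::-1]
        left_v = val[1:3][::-1]
        right_i = 2 * idx[-1] - idx[-3:-1][::-1]
        right_v = val[-3:-1][::-1]
        idx = np.concatenate([left_i, idx, right_i])
        val = np.concatenate([left_v, val, right_v])
        order = np.argsort(idx)
        idx, val = idx[order], val[order]
        idx, uniq = np.unique(idx, return_index=True)
        val = val[uniq]
    cs = CubicSpline(idx, val)
    return cs(np.arange(n))


def _mean_envelope(x: np.ndarray,
                   extrema_filter=None) -> np.ndarray | None:
    """Mean of the upper/lower spline envelopes, or None if the signal has
    too few extrema to define them."""
    maxima, _ = find_peaks(x)
    minima, _ = find_peaks(-x)
    if extrema_filter is not None:
        maxima, minima = (extrema_filter(maxima, minima, "max"),
                          extrema_filter(maxima, minima, "min"))
    if maxima.size < 2 or minima.size < 2:
        return None
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    return (upper + lower) / 2.0


def _sift_one(x: np.ndarray, extrema_filter=None) -> np.ndarray | None:
    """Extract one IMF from *x*, or None if *x* carries no oscillation."""
    h = x
    for _ in range(_MAX_SIFT):
        m = _mean_envelope(h, extrema_filter)
        if m is None:
            return None if h is x else h
        h_new = h - m
        denom = float(np.sum(h ** 2))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < _SD_STOP:
            break
    return h


def emd_sift(sig: Recording | np.ndarray, k: int,
             rate: float | None = None) -> ImfSet:
    """First *k* IMFs of a signal by standard sifting.

    A monotone (extremum-free) signal yields zero IMFs with the input as
    residual. The identity ``sum(imfs) + residual == input`` holds to
    floating-point accuracy for every call.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = sig.samples if isinstance(sig, Recording) else np.asarray(sig, float)
    if x.size < 8:
        raise ValueError("signal too short for sifting (need >= 8 samples)")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(k):
        imf = _sift_one(residual)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return ImfSet(tuple(imfs), residual)


def rolling_ball_highpass(sig: Recording, f_cut: float) -> Recording:
    """Extract the high-frequency (> *f_cut*) oscillatory component.

    Frequency-selective sifting: only extrema whose spacing to a neighboring
    extremum is shorter than ``1 / (2 * f_cut)`` — i.e. extrema produced by
    oscillations faster than *f_cut* — anchor the envelopes. The extracted
    component plus the remainder equals the input exactly; a signal with no
    fast extrema returns all zeros.
    """
    if not (0 < f_cut < sig.rate / 2):
        raise ValueError(f"f_cut {f_cut} outside (0, Nyquist)")
    max_gap = sig.rate / (2.0 * f_cut)  # samples

    def fast_only(maxima: np.ndarray, minima: np.ndarray,
                  kind: str) -> np.ndarray:
        own = maxima if kind == "max" else minima
        if own.size == 0:
            return own
        allx = np.sort(np.concatenate([maxima, minima]))
        pos = np.searchsorted(allx, own)
        prev_gap = np.where(pos > 0, own - allx[np.maximum(pos - 1, 0)],
                            np.inf)
        nxt = np.minimum(pos + 1, allx.size - 1)
        next_gap = np.where(pos < allx.size - 1, allx[nxt] - own, np.inf)
        return own[np.minimum(prev_gap, next_gap) < max_gap]

    component = _sift_one(sig.samples, extrema_filter=fast_only)
    if component is None:
        component = np.zeros_like(sig.samples)
    return Recording(component, sig.rate, sig.channel)


def zero_crossing_times(x: np.ndarray, rate: float) -> np.ndarray:
    """Times (s) where the signal crosses zero, linearly interpolated."""
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    # treat exact zeros as crossings at the sample itself
    idx = np.flatnonzero((s[:-1] * s[1:]) < 0)
    frac = x[idx] / (x[idx] - x[idx + 1])
    times = (idx + frac) / rate
    zeros = np.flatnonzero(x == 0) / rate
    return np.unique(np.concatenate([times, zeros]))


def zero_crossing_frequency(imf: np.ndarray, rate: float,
                            n_crossings: int = 1) -> np.ndarray:
    """Per-sample instantaneous frequency from zero-crossing intervals.

    For each sample, the window spanning the nearest *n_crossings* consecutive
    zero-crossing intervals gives ``f = n_crossings / (2 * window duration)``
    — each interval is half an oscillation period. Samples before the first /
    after the last crossing take the nearest defined value. Signals with too
    few crossings yield all zeros (with a warning).
    """
    if n_crossings % 2 != 1 or n_crossings < 1:
        raise ValueError("n_crossings must be a positive odd count")
    x = np.asarray(imf, dtype=float)
    c = zero_crossing_times(x, rate)
    if c.size < n_crossings + 1:
        warnings.warn(
            f"signal has {c.size} zero crossings < {n_crossings + 1}; "
            "frequency undefined, returning zeros", stacklevel=2)
        return np.zeros(x.size)
    n_int = c.size - 1
    # window start for the window centered on interval j, clipped to range
    j = np.arange(n_int)
    start = np.clip(j - n_crossings // 2, 0, n_int - n_crossings)
    f_per_interval = n_crossings / (2.0 * (c[start + n_crossings] - c[start]))
    t = np.arange(x.size) / rate
    interval = np.clip(np.searchsorted(c, t, side="right") - 1, 0, n_int - 1)
    return f_per_interval[interval]
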