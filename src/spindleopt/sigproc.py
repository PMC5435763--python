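"""Band-limited filtering, RMS grids and envelopes shared by the detectors."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import Recording

SIGMA_BAND = (11.0, 16.0)  # Hz, the canonical spindle band


def bandpass_sigma(rec: Recording, lo: float = SIGMA_BAND[0],
                   hi: float = SIGMA_BAND[1]) -> Recording:
    """Zero-phase FIR band-pass of a recording.

    A Hamming-window FIR filter with ~1 Hz transition width (>50 dB stopband)
    applied forward-backward, so the output is band-limited with no phase
    distortion and the same length as the input.
    """
    nyq = rec.rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist={nyq})")
    transition = 1.0  # Hz
    numtaps = int(np.ceil(3.3 * rec.rate / transition)) | 1
    # keep the filter shorter than the signal so filtfilt stays well-posed
    max_taps = max(3, (rec.n_samples - 2) // 3 | 1)
    numtaps = min(numtaps, max_taps)
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=rec.rate)
    padlen = min(3 * numtaps, rec.n_samples - 1)
    y = sps.filtfilt(taps, [1.0], rec.samples, padlen=padlen)
    return Recording(y, rec.rate, rec.channel)


def moving_rms(sig: Recording, resolution: float, window: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """RMS of a signal on a regular time grid.

    One value per *resolution* step; each value is the RMS over the centered
    *window* (truncated at the edges). Returns ``(times, rms)`` where
    ``times[j]`` is the left edge ``j * resolution`` of grid cell *j*.
    """
    if resolution <= 0 or window <= 0:
        raise ValueError("resolution and window must be positive")
    half = window * sig.rate / 2.0
    if 2 * half < 2:
        raise ValueError("window must span at least 2 samples")
    n = sig.n_samples
    n_out = int(np.floor(n / (resolution * sig.rate) + 1e-9))
    n_out = max(n_out, 1)
    centers = (np.arange(n_out) + 0.5) * resolution * sig.rate
    lo = np.clip(np.round(centers - half).astype(int), 0, n)
    hi = np.clip(np.round(centers + half).astype(int), 0, n)
    csum = np.concatenate([[0.0], np.cumsum(sig.samples ** 2)])
    counts = np.maximum(hi - lo, 1)
    rms = np.sqrt((csum[hi] - csum[lo]) / counts)
    return np.arange(n_out) * resolution, rms


def peak_envelope(x: np.ndarray, rate: float) -> np.ndarray:
    """Envelope through the local maxima of a (rectified) signal.

    Linear interpolation through strict local maxima; flat before the first
    and after the last maximum. A signal with fewer than two local maxima
    returns its own absolute value.
    """
    x = np.asarray(x, dtype=float)
    peaks, _ = sps.find_peaks(x)
    if peaks.size < 2:
        return np.abs(x)
    return np.interp(np.arange(x.size), peaks, x[peaks])


def spline_envelope(x: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the maxima of ``|x|``.

    Used as the instantaneous-amplitude estimate of an oscillatory component.
    Ends are handled by pinning the envelope to ``|x|`` at the boundaries.
    """
    ax = np.abs(np.asarray(x, dtype=float))
    peaks, _ = sps.find_peaks(ax)
    if peaks.size < 2:
        return ax
    knots = np.r_[0, peaks, ax.size - 1]
    vals = ax[knots]
    # dedupe boundary knots that coincide with a peak
    knots, idx = np.unique(knots, return_index=True)
    cs = CubicSpline(knots, vals[idx])
    env = cs(np.arange(ax.size))
    return np.maximum(env, 0.0)


def threshold_runs(values: np.ndarray, threshold: float, dt: float,
                   above: bool = True) -> list[tuple[float, float]]:
    """Maximal runs of supra-threshold values on a regular grid.

    Returns (onset, duration) pairs in seconds, where grid cell *j* covers
    ``[j * dt, (j + 1) * dt)``. Comparison is strict (``>``).
    """
    m = values > threshold if above else values < threshold
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return [(s * dt, (e - s) * dt) for s, e in zip(starts, ends)]
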