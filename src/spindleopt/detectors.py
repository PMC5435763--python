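"""The six simplex spindle detectors and the sequential double-reading hybrids.

Each detector maps a single-channel EEG recording (plus, for the Fourier
family, a hypnogram) and a real parameter vector to a list of spindle events.
The parameter vectors, their meanings and their box bounds follow the
published Pareto-optimization formulation:

======== ==== ==========================================================
detector dim  principle
======== ==== ==========================================================
d1        4   sigma band-pass, peak envelope, dual amplitude thresholds
d2        5   sigma band-pass, moving RMS vs. N2 standard deviation
d3        3   sigma band-pass, moving RMS vs. NREM percentile threshold
d4       15   Morlet CWT top-10-scale probability estimate (stage-free)
d5       12   EMD: 3 IMFs, fuzzy amplitude x zero-crossing frequency
d6       12   rolling-ball high-pass component, fuzzy logic as d5
d7       17   double reading, d6 screens then d2 reviews
d8       17   double reading, d2 screens then d6 reviews
d9       27   double reading, d4 screens then d6 reviews
======== ==== ==========================================================

Every detector is split into a *preprocess* step (signal transforms that do
not depend on the parameter vector — computed once per recording) and a
*detect* step (thresholding and event logic — cheap, evaluated thousands of
times during optimization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

import numpy as np

from .cwt import estimate_from_top_frequencies, top_scale_frequencies
from .emd import emd_sift, rolling_ball_highpass, zero_crossing_frequency
from .io import NREM_DEEP, EventList, Recording, SampleMask, StageSeries, \
    mask_to_events
from .sigproc import bandpass_sigma, moving_rms, peak_envelope, \
    spline_envelope, threshold_runs


class NormalizationError(ValueError):
    """Raised when a recording has no NREM samples to normalize against."""


# ---------------------------------------------------------------------------
# parameter vectors and bounds

_BOUNDS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "d1": ((0.1, 0.1, 0.3, 0.3), (20, 30, 1, 3)),
    "d2": ((0.05, 0.05, 0.1, 0.3, 0.3), (0.5, 0.5, 10, 1, 3)),
    "d3": ((0.1, 0.3, 0.3), (99, 1, 3)),
    "d4": ((8, 14, 0.05, 0.1, 0.01, 0.05, 0.3, 0.05, 0.1, 0.3,
            0.05, 0.05, 0.1, 0.3, 0.3),
           (12, 18, 0.25, 0.8, 0.1, 0.25, 0.9, 0.25, 0.5, 0.8,
            0.25, 0.5, 0.5, 1, 3)),
    "d5": ((1, 5, 10, 1, 0.1, 8, 1, 0.1, 0.01, 0.05, 0.3, 0.3),
           (10, 40, 120, 50, 4, 13.5, 8, 4, 0.99, 0.5, 1, 3)),
}
_BOUNDS["d6"] = _BOUNDS["d5"]
_HYBRID_PARTS = {"d7": ("d6", "d2"), "d8": ("d2", "d6"), "d9": ("d4", "d6")}

_NAMES: dict[str, tuple[str, ...]] = {
    "d1": ("lower_ratio", "upper_ratio", "min_dur_s", "max_dur_s"),
    "d2": ("rms_resolution_s", "rms_window_s", "threshold_ratio",
           "min_dur_s", "max_dur_s"),
    "d3": ("rms_percentile", "min_dur_s", "max_dur_s"),
    "d4": ("freq_lo_hz", "freq_hi_hz", "smooth_s", "estimate_threshold",
           "min_initial_s", "merge_gap_s", "strong_mean_threshold",
           "pair_dur_a_s", "pair_dur_b_s", "weak_mean_threshold",
           "strong_dur_a_s", "strong_dur_b_s", "final_merge_gap_s",
           "min_dur_s", "max_merge_dur_s"),
    "d5": ("amp_rise_uv", "amp_onset_uv", "amp_plateau_uv", "amp_fall_uv",
           "freq_rise_hz", "freq_onset_hz", "freq_plateau_hz", "freq_fall_hz",
           "estimate_threshold", "merge_gap_s", "min_dur_s", "max_dur_s"),
}
_NAMES["d6"] = _NAMES["d5"]

DETECTOR_IDS = ("d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9")


def default_bounds(det_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Published lower/upper parameter bounds for a detector id."""
    if det_id in _BOUNDS:
        lo, hi = _BOUNDS[det_id]
        return np.array(lo, float), np.array(hi, float)
    if det_id in _HYBRID_PARTS:
        a, b = _HYBRID_PARTS[det_id]
        la, ha = default_bounds(a)
        lb, hb = default_bounds(b)
        return np.concatenate([la, lb]), np.concatenate([ha, hb])
    raise ValueError(f"unknown detector id {det_id!r}")


def parameter_names(det_id: str) -> tuple[str, ...]:
    if det_id in _NAMES:
        return _NAMES[det_id]
    if det_id in _HYBRID_PARTS:
        a, b = _HYBRID_PARTS[det_id]
        return tuple(f"{a}.{n}" for n in parameter_names(a)) + \
            tuple(f"{b}.{n}" for n in parameter_names(b))
    raise ValueError(f"unknown detector id {det_id!r}")


@dataclass(frozen=True)
class DetectorSpec:
    """A detector id plus a concrete operating-parameter vector with bounds."""

    id: str
    x: np.ndarray
    lower: np.ndarray = None  # type: ignore[assignment]
    upper: np.ndarray = None  # type: ignore[assignment]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.id not in DETECTOR_IDS:
            raise ValueError(f"unknown detector id {self.id!r}")
        lo, hi = default_bounds(self.id)
        lower = lo if self.lower is None else np.asarray(self.lower, float)
        upper = hi if self.upper is None else np.asarray(self.upper, float)
        x = np.asarray(self.x, float)
        names = self.names or parameter_names(self.id)
        if not (x.size == lower.size == upper.size == len(names)):
            raise ValueError(
                f"{self.id}: expected {lower.size} parameters, got {x.size}")
        if np.any(x < lower - 1e-12) or np.any(x > upper + 1e-12):
            bad = [f"{n}={v:g} not in [{a:g}, {b:g}]"
                   for n, v, a, b in zip(names, x, lower, upper)
                   if not (a - 1e-12 <= v <= b + 1e-12)]
            raise ValueError(f"{self.id}: parameters out of bounds: {bad}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "names", tuple(names))

    @classmethod
    def midpoint(cls, det_id: str) -> "DetectorSpec":
        lo, hi = default_bounds(det_id)
        return cls(det_id, (lo + hi) / 2.0)

    def to_dict(self) -> dict:
        return {"id": self.id,
                "parameters": {n: float(v)
                               for n, v in zip(self.names, self.x)},
                "lower": [float(v) for v in self.lower],
                "upper": [float(v) for v in self.upper]}

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorSpec":
        names = parameter_names(d["id"])
        x = [d["parameters"][n] for n in names]
        return cls(d["id"], np.array(x),
                   np.array(d["lower"]) if "lower" in d else None,
                   np.array(d["upper"]) if "upper" in d else None)


# ---------------------------------------------------------------------------
# normalization statistics

@dataclass(frozen=True)
class NormalizationStats:
    """Amplitude statistics of the sigma-filtered signal in deep NREM sleep.

    ``A1``/``A2`` are the peak and average rectified amplitude over NREM
    2/3/4, ``sigma_n2`` the standard deviation over N2 only, and
    ``rms_values`` the fixed-grid RMS series over NREM 2/3/4 used for
    percentile thresholds.
    """

    A1: float
    A2: float
    sigma_n2: float
    rms_values: np.ndarray

    def __post_init__(self) -> None:
        if not (self.A1 >= self.A2 >= 0):
            raise ValueError("requires A1 >= A2 >= 0")
        if self.sigma_n2 < 0:
            raise ValueError("sigma_n2 must be >= 0")


#: fixed RMS grid used by d3 (resolution, window) in seconds
D3_RMS_GRID = (0.1, 0.25)


def normalization_stats(rec: Recording, stages: StageSeries,
                        filtered: Recording | None = None
                        ) -> NormalizationStats:
    """Compute per-recording normalization statistics (once per recording)."""
    filt = filtered if filtered is not None else bandpass_sigma(rec)
    m234 = stages.mask(rec.rate, rec.n_samples, NREM_DEEP)
    if not m234.any():
        raise NormalizationError("recording has no NREM 2/3/4 samples")
    rect = np.abs(filt.samples[m234])
    a1, a2 = float(rect.max()), float(rect.mean())
    m2 = stages.mask(rec.rate, rec.n_samples, ("N2",))
    sigma_n2 = float(filt.samples[m2].std()) if m2.any() else 0.0
    res, win = D3_RMS_GRID
    times, rms = moving_rms(filt, res, win)
    centers = times + res / 2.0
    idx = np.clip((centers * rec.rate).astype(int), 0, rec.n_samples - 1)
    return NormalizationStats(a1, a2, sigma_n2, rms[m234[idx]])


# ---------------------------------------------------------------------------
# event-list helpers

def duration_filter(events: EventList, lo: float, hi: float) -> EventList:
    return EventList(tuple((o, d) for o, d in events if lo <= d <= hi))


def merge_gaps(events: EventList, gap: float,
               max_merged: float = np.inf) -> EventList:
    """Merge consecutive events separated by less than *gap* seconds, but
    only while the merged event stays no longer than *max_merged*."""
    if len(events) < 2:
        return events
    out = [list(events[0])]
    for o, d in events[1:]:
        prev_end = out[-1][0] + out[-1][1]
        merged_dur = o + d - out[-1][0]
        if o - prev_end < gap and merged_dur <= max_merged:
            out[-1][1] = max(out[-1][1], merged_dur)
        else:
            out.append([o, d])
    return EventList(tuple((o, d) for o, d in out))


def trapezoid_membership(v: np.ndarray | float, p_a: float, p_b: float,
                         p_c: float, p_d: float) -> np.ndarray | float:
    """Trapezoidal fuzzy membership with breakpoints
    ``(p_b - p_a, p_b, p_b + p_c, p_b + p_c + p_d)``.

    Zero up to the first breakpoint, linear rise over *p_a*, plateau of 1
    over *p_c*, linear fall over *p_d*, zero after. Zero-width edges resolve
    to steps (an all-zero-width trapezoid is the indicator of ``v == p_b``).
    """
    if p_a < 0 or p_c < 0 or p_d < 0:
        raise ValueError("widths must be non-negative")
    a, b, c, d = p_b - p_a, p_b, p_b + p_c, p_b + p_c + p_d
    scalar = np.isscalar(v) or np.ndim(v) == 0
    v = np.atleast_1d(np.asarray(v, dtype=float))
    out = np.zeros_like(v)
    out[(v >= b) & (v <= c)] = 1.0
    if p_a > 0:
        rising = (v > a) & (v < b)
        out[rising] = (v[rising] - a) / (b - a)
    if p_d > 0:
        falling = (v > c) & (v < d)
        out[falling] = (d - v[falling]) / (d - c)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# detector classes

class SimplexDetector:
    """Base class: preprocess once per recording, detect per parameter set."""

    id: str = ""
    needs_stages: bool = False

    @property
    def n_params(self) -> int:
        return default_bounds(self.id)[0].size

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        DetectorSpec(self.id, x)  # bound validation
        return x

    def preprocess(self, rec: Recording, stages: StageSeries | None = None,
                   stats: NormalizationStats | None = None) -> dict[str, Any]:
        raise NotImplementedError

    def candidates(self, feats: dict[str, Any], x: np.ndarray) -> EventList:
        """Detected events *before* the final duration gate."""
        raise NotImplementedError

    def duration_gate(self, x: np.ndarray) -> tuple[float, float]:
        raise NotImplementedError

    def detect(self, feats: dict[str, Any], x: np.ndarray) -> EventList:
        x = self._check(x)
        return duration_filter(self.candidates(feats, x),
                               *self.duration_gate(x))

    def run(self, rec: Recording, stages: StageSeries | None,
            x: np.ndarray) -> EventList:
        """Full pipeline on one recording.

        A missing hypnogram treats the whole recording as N2. When a
        hypnogram is present, events entirely outside NREM 2/3/4 epochs are
        discarded.
        """
        gate_stages = stages
        if stages is None:
            stages = StageSeries.constant("N2", rec.duration)
        feats = self.preprocess(rec, stages)
        events = self.detect(feats, np.asarray(x, float))
        if gate_stages is not None:
            events = stage_gate(events, gate_stages, rec)
        return events


def stage_gate(events: EventList, stages: StageSeries,
                rec: Recording) -> EventList:
    m = stages.mask(rec.rate, rec.n_samples, NREM_DEEP)
    kept = []
    for o, d in events:
        i0 = max(0, int(o * rec.rate))
        i1 = min(rec.n_samples, int(np.ceil((o + d) * rec.rate)))
        if i1 > i0 and m[i0:i1].any():
            kept.append((o, d))
    return EventList(tuple(kept))


class DetectorD1(SimplexDetector):
    """Band-pass + peak-envelope detector with dual amplitude thresholds.

    Candidates are envelope regions above the lower threshold ``p1 * A1``
    (A1: NREM peak amplitude) that contain at least one sample above the
    upper threshold ``p2 * A2`` (A2: NREM mean amplitude).
    """

    id = "d1"
    needs_stages = True

    def preprocess(self, rec, stages=None, stats=None):
        if stages is None:
            stages = StageSeries.constant("N2", rec.duration)
        filt = bandpass_sigma(rec)
        if stats is None:
            stats = normalization_stats(rec, stages, filtered=filt)
        env = peak_envelope(np.abs(filt.samples), rec.rate)
        return {"envelope": env, "stats": stats, "rate": rec.rate}

    def candidates(self, feats, x):
        env, stats, rate = feats["envelope"], feats["stats"], feats["rate"]
        lower_thr = x[0] * stats.A1
        upper_thr = x[1] * stats.A2
        mask = SampleMask(env > lower_thr, rate)
        events = []
        for o, d in mask_to_events(mask):
            i0, i1 = int(round(o * rate)), int(round((o + d) * rate))
            if np.any(env[i0:i1] > upper_thr):
                events.append((o, d))
        return EventList(tuple(events))

    def duration_gate(self, x):
        return x[2], x[3]


class DetectorD2(SimplexDetector):
    """Band-pass + moving-RMS detector thresholded by the N2 deviation.

    RMS on a grid of resolution ``p1`` with window ``p2``; runs above
    ``p3 * sigma_N2`` become candidates.
    """

    id = "d2"
    needs_stages = True

    def preprocess(self, rec, stages=None, stats=None):
        if stages is None:
            stages = StageSeries.constant("N2", rec.duration)
        filt = bandpass_sigma(rec)
        if stats is None:
            stats = normalization_stats(rec, stages, filtered=filt)
        if stats.sigma_n2 == 0.0:
            raise NormalizationError("recording has no N2 samples")
        return {"filtered": filt, "stats": stats}

    def candidates(self, feats, x):
        filt, stats = feats["filtered"], feats["stats"]
        _, rms = moving_rms(filt, x[0], x[1])
        runs = threshold_runs(rms, x[2] * stats.sigma_n2, x[0])
        return EventList(tuple(runs))

    def duration_gate(self, x):
        return x[3], x[4]


class DetectorD3(SimplexDetector):
    """Band-pass + fixed-grid RMS detector with a percentile threshold.

    RMS resolution/window fixed at 0.1/0.25 s so the grid is preprocessed
    once; the threshold is the ``p1``-th percentile (in percent) of the RMS
    values over NREM 2/3/4.
    """

    id = "d3"
    needs_stages = True

    def preprocess(self, rec, stages=None, stats=None):
        if stages is None:
            stages = StageSeries.constant("N2", rec.duration)
        filt = bandpass_sigma(rec)
        if stats is None:
            stats = normalization_stats(rec, stages, filtered=filt)
        _, rms = moving_rms(filt, *D3_RMS_GRID)
        return {"rms": rms, "stats": stats}

    def candidates(self, feats, x):
        thr = float(np.percentile(feats["stats"].rms_values, x[0]))
        runs = threshold_runs(feats["rms"], thr, D3_RMS_GRID[0])
        return EventList(tuple(runs))

    def duration_gate(self, x):
        return x[1], x[2]


class DetectorD4(SimplexDetector):
    """CWT top-10-scale probability detector (needs no sleep stages).

    The per-sample probability estimate (fraction of the 10 strongest Morlet
    scales inside the adjustable band [p1, p2] Hz) is smoothed, thresholded,
    and passed through the merge/grouping cascade controlled by p5–p15.
    """

    id = "d4"
    needs_stages = False

    def preprocess(self, rec, stages=None, stats=None):
        return {"top_freqs": top_scale_frequencies(rec), "rate": rec.rate}

    def candidates(self, feats, x):
        rate = feats["rate"]
        est = estimate_from_top_frequencies(feats["top_freqs"], x[0], x[1])
        w = max(1, int(round(x[2] * rate)))
        kernel = np.ones(w) / w
        smoothed = np.convolve(est, kernel, mode="same")
        runs = threshold_runs(smoothed, x[3], 1.0 / rate)
        events = EventList(tuple((o, d) for o, d in runs if d > x[4]))
        events = merge_gaps(events, x[5])
        events = _group_adjacent(
            events, smoothed, rate, mean_thr=x[9],
            cond=lambda a, b: (a >= x[7] and b >= x[8]) or
                              (a >= x[8] and b >= x[7]))
        events = _group_adjacent(
            events, smoothed, rate, mean_thr=x[6],
            cond=lambda a, b: a > x[10] or b > x[11])
        return merge_gaps(events, x[12], max_merged=x[14])

    def duration_gate(self, x):
        # only a lower duration criterion; the upper value caps merging
        return x[13], np.inf


def _group_adjacent(events: EventList, est: np.ndarray, rate: float,
                    mean_thr: float,
                    cond: Callable[[float, float], bool]) -> EventList:
    """Left-to-right pass merging adjacent candidates whose combined span has
    a mean estimate above *mean_thr* and whose durations satisfy *cond*."""
    if len(events) < 2:
        return events
    out = [list(events[0])]
    for o, d in events[1:]:
        po, pd = out[-1]
        span0, span1 = po, o + d
        i0, i1 = int(span0 * rate), min(int(np.ceil(span1 * rate)), est.size)
        if cond(pd, d) and i1 > i0 and est[i0:i1].mean() >= mean_thr:
            out[-1] = [po, span1 - po]
        else:
            out.append([o, d])
    return EventList(tuple((o, d) for o, d in out))


class DetectorD5(SimplexDetector):
    """EMD fuzzy-logic detector.

    For each of the first 3 IMFs, a trapezoidal amplitude membership (p1–p4,
    µV, on the spline envelope of |IMF|) is multiplied with a trapezoidal
    frequency membership (p5–p8, Hz, on the zero-crossing frequency); the
    per-sample maximum over IMFs is thresholded by p9, merged by gap p10 and
    duration-gated by [p11, p12].
    """

    id = "d5"
    needs_stages = False
    _n_imfs = 3

    def preprocess(self, rec, stages=None, stats=None):
        imfset = emd_sift(rec, self._n_imfs)
        amps, freqs = [], []
        for imf in imfset.imfs:
            amps.append(spline_envelope(imf))
            freqs.append(zero_crossing_frequency(imf, rec.rate, 1))
        return {"amps": amps, "freqs": freqs, "rate": rec.rate,
                "n": rec.n_samples}

    def _estimate(self, feats, x):
        est = np.zeros(feats["n"])
        for amp, freq in zip(feats["amps"], feats["freqs"]):
            m = trapezoid_membership(amp, x[0], x[1], x[2], x[3]) * \
                trapezoid_membership(freq, x[4], x[5], x[6], x[7])
            est = np.maximum(est, m)
        return est

    def candidates(self, feats, x):
        est = self._estimate(feats, x)
        mask = SampleMask(est > x[8], feats["rate"])
        return merge_gaps(mask_to_events(mask), x[9])

    def duration_gate(self, x):
        return x[10], x[11]


class DetectorD6(DetectorD5):
    """Rolling-ball fuzzy-logic detector.

    A single high-frequency component (> 10 Hz) supplies one amplitude
    envelope and five zero-crossing frequency estimates (windows of 1, 3, 5,
    7, 9 crossings, for smoothing); the estimate is the amplitude membership
    times the best of the five frequency memberships. Thresholding, merging
    and duration checks are identical to d5.
    """

    id = "d6"
    f_cut = 10.0  # Hz
    _windows = (1, 3, 5, 7, 9)

    def preprocess(self, rec, stages=None, stats=None):
        comp = rolling_ball_highpass(rec, self.f_cut)
        amp = spline_envelope(comp.samples)
        freqs = [zero_crossing_frequency(comp.samples, rec.rate, w)
                 for w in self._windows]
        return {"amps": [amp], "freqs": freqs, "rate": rec.rate,
                "n": rec.n_samples}

    def _estimate(self, feats, x):
        amp_m = trapezoid_membership(feats["amps"][0], x[0], x[1], x[2], x[3])
        freq_m = np.zeros(feats["n"])
        for freq in feats["freqs"]:
            freq_m = np.maximum(
                freq_m, trapezoid_membership(freq, x[4], x[5], x[6], x[7]))
        return amp_m * freq_m


class HybridDetector:
    """Sequential double-reading detector.

    The first detector screens the whole recording; each candidate window is
    padded by *pad* seconds on both ends, overlapping windows are merged, and
    the second detector reviews each padded segment independently (with
    normalization statistics still taken from the full recording). The second
    reader's detections are clipped to the unpadded candidate windows and the
    surviving pieces re-checked against the second's duration gate.
    """

    needs_stages = True

    def __init__(self, first: SimplexDetector, second: SimplexDetector,
                 det_id: str | None = None, pad: float = 2.5) -> None:
        self.first = first
        self.second = second
        self.pad = pad
        self.id = det_id or next(
            (k for k, v in _HYBRID_PARTS.items()
             if v == (first.id, second.id)), f"{first.id}+{second.id}")

    @property
    def n_params(self) -> int:
        return self.first.n_params + self.second.n_params

    def split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, float)
        n1 = self.first.n_params
        return x[:n1], x[n1:]

    def run(self, rec: Recording, stages: StageSeries | None,
            x: np.ndarray) -> EventList:
        x1, x2 = self.split(x)
        candidates = self.first.run(rec, stages, x1)
        if len(candidates) == 0:
            return EventList()
        full_stages = stages if stages is not None else \
            StageSeries.constant("N2", rec.duration)
        # second's normalization comes from the full recording
        stats = None
        if self.second.needs_stages:
            stats = normalization_stats(rec, full_stages)
        cand_windows = candidates.intervals()
        reviewed: list[tuple[float, float]] = []
        for seg0, seg1 in candidates.dilate(self.pad).merge().intervals():
            seg1 = min(seg1, rec.duration)
            segment = rec.slice(seg0, seg1)
            seg_stages = full_stages.slice(seg0, seg1)
            feats = self.second.preprocess(segment, seg_stages, stats=stats)
            dets = self.second.candidates(feats, x2).shift(seg0)
            for s, e in dets.intervals():
                for c0, c1 in cand_windows:
                    s2, e2 = max(s, c0), min(e, c1)
                    if e2 > s2:
                        reviewed.append((s2, e2 - s2))
        lo, hi = self.second.duration_gate(x2)
        return duration_filter(EventList(tuple(sorted(reviewed))), lo, hi)


_REGISTRY: dict[str, Callable[[], SimplexDetector | HybridDetector]] = {
    "d1": DetectorD1, "d2": DetectorD2, "d3": DetectorD3,
    "d4": DetectorD4, "d5": DetectorD5, "d6": DetectorD6,
}


def get_detector(det_id: str) -> SimplexDetector | HybridDetector:
    """Instantiate a detector by id (d1–d9)."""
    if det_id in _REGISTRY:
        return _REGISTRY[det_id]()
    if det_id in _HYBRID_PARTS:
        a, b = _HYBRID_PARTS[det_id]
        return HybridDetector(_REGISTRY[a](), _REGISTRY[b](), det_id)
    raise ValueError(f"unknown detector id {det_id!r}")
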