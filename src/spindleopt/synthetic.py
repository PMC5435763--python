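"""Synthetic polysomnography with planted spindles and simulated scorers.

The generator emulates the statistical shape of NREM sleep EEG needed to
exercise every detector: a 1/f-type background, sigma-band (11–16 Hz) bursts
with waxing-waning (Hann) envelopes and durations of at least 0.5 s, biphasic
low-frequency K-complex-like confounders, an alternating N2/N3 hypnogram, and
two scorer models of differing sensitivity — one annotating true durations
and one assigning fixed 1-s durations. Everything is a deterministic
function of the seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import EventList, Recording, StageSeries, write_annotations, \
    write_edf_signal, write_hypnogram
from .sigproc import SIGMA_BAND, bandpass_sigma

#: (amplitude sensitivity threshold µV, duration style)
ScorerModel = tuple[float, str]

DURATION_STYLES = ("true_duration", "fixed_1s")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic recording."""

    duration: float = 600.0          # s
    rate: float = 100.0              # Hz
    density: float = 3.0             # spindles per minute
    freq_range: tuple[float, float] = SIGMA_BAND        # Hz
    dur_range: tuple[float, float] = (0.5, 2.0)         # s
    amp_range: tuple[float, float] = (40.0, 60.0)       # µV peak
    noise_exponent: float = 1.0      # spectral slope of the 1/f background
    background_std: float = 12.0     # µV, broadband
    kcomplex_rate: float = 1.0       # events per minute
    kcomplex_amp: float = 100.0      # µV
    scorers: tuple[ScorerModel, ...] = ((45.0, "true_duration"),
                                        (0.0, "fixed_1s"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dur_range[0] < 0.5:
            raise ValueError("spindles are at least 0.5 s long")
        lo, hi = self.freq_range
        if not (0 < lo < hi < self.rate / 2):
            raise ValueError("freq_range must lie within (0, rate/2)")
        for _, style in self.scorers:
            if style not in DURATION_STYLES:
                raise ValueError(f"unknown duration style {style!r}")


@dataclass(frozen=True)
class TrueEvent:
    """A planted spindle with its generation metadata."""

    onset: float
    duration: float
    frequency: float   # Hz
    amplitude: float   # µV peak


@dataclass(frozen=True)
class SimulatedPSG:
    """One synthetic recording with its hypnogram and ground truth."""

    recording: Recording
    stages: StageSeries
    truth: tuple[TrueEvent, ...]

    @property
    def events(self) -> EventList:
        return EventList(tuple((e.onset, e.duration) for e in self.truth))


def _pink_noise(n: int, rate: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    return np.fft.irfft(spec * shaping, n=n)


def _poisson_onsets(cfg: SimulationConfig, durations_of: callable,
                    rng: np.random.Generator,
                    margin: float = 0.25) -> list[tuple[float, float]]:
    """Poisson-count onset/duration pairs with overlap forbidden.

    The event count is drawn from the Poisson law of the configured density;
    each onset proposal that would overlap an already placed event (within
    *margin* seconds) is rejected and redrawn, so thinning forbids overlap
    without biasing the planted count. Densities so high that more than half
    of all proposals are rejected raise an error.
    """
    n_events = int(rng.poisson(cfg.density * cfg.duration / 60.0))
    events: list[tuple[float, float]] = []
    proposals = rejected = 0
    for _ in range(n_events):
        dur = durations_of()
        placed = False
        for _ in range(200):
            proposals += 1
            t = float(rng.uniform(0.0, max(cfg.duration - dur, 0.0)))
            clash = any(min(o + d, t + dur) + margin > max(o, t)
                        for o, d in events)
            if not clash:
                events.append((t, dur))
                placed = True
                break
            rejected += 1
        if not placed or (proposals > 20 and rejected / proposals > 0.5):
            raise ValueError(
                f"spindle density {cfg.density}/min too high: "
                f"{rejected}/{proposals} proposals rejected by overlap "
                "thinning")
    return sorted(events)


def simulate_psg(cfg: SimulationConfig) -> SimulatedPSG:
    """Generate one synthetic polysomnography recording.

    Background: 1/f**noise_exponent noise scaled to *background_std* µV.
    Spindles: Poisson onsets (rate = *density*, thinned to forbid overlap),
    sinusoids with uniform frequency/duration/peak amplitude and a Hann
    (waxing-waning) envelope. K-complex-like transients: biphasic
    low-frequency waves at *kcomplex_rate*, kept clear of the spindles.
    Stages: alternating N2/N3 in 30-s epochs.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.rate))
    x = _pink_noise(n, cfg.rate, cfg.noise_exponent, rng)
    std = x.std()
    if std > 0:
        x *= cfg.background_std / std
    t_axis = np.arange(n) / cfg.rate

    spindle_iv = _poisson_onsets(
        cfg, lambda: float(rng.uniform(*cfg.dur_range)), rng)
    truth = []
    for onset, dur in spindle_iv:
        freq = float(rng.uniform(*cfg.freq_range))
        amp = float(rng.uniform(*cfg.amp_range))
        phase = float(rng.uniform(0, 2 * np.pi))
        i0, i1 = int(round(onset * cfg.rate)), int(round((onset + dur) *
                                                         cfg.rate))
        tt = t_axis[i0:i1] - onset
        envelope = np.sin(np.pi * tt / dur) ** 2  # Hann window
        x[i0:i1] += amp * envelope * np.sin(2 * np.pi * freq * tt + phase)
        truth.append(TrueEvent(onset, dur, freq, amp))

    # K-complex confounders: biphasic ~1 s transients away from spindles
    n_kc = rng.poisson(cfg.kcomplex_rate * cfg.duration / 60.0)
    kc_dur = 1.0
    spindles = EventList(tuple(spindle_iv)).dilate(0.5)
    placed = 0
    for _ in range(10 * n_kc):
        if placed >= n_kc:
            break
        onset = float(rng.uniform(0, max(cfg.duration - kc_dur, 0)))
        clash = any(min(o + d, onset + kc_dur) > max(o, onset)
                    for o, d in spindles)
        if clash:
            continue
        i0, i1 = int(round(onset * cfg.rate)), int(round((onset + kc_dur) *
                                                         cfg.rate))
        tt = t_axis[i0:i1] - onset
        shape = np.sin(2 * np.pi * tt / kc_dur) * np.sin(np.pi * tt /
                                                         kc_dur) ** 2
        x[i0:i1] += -cfg.kcomplex_amp * shape
        placed += 1

    rec = Recording(x, cfg.rate, "C3-A1")
    n_epochs = max(1, int(np.ceil(cfg.duration / 30.0)))
    stages = StageSeries(30.0, tuple("N2" if i % 2 == 0 else "N3"
                                     for i in range(n_epochs)))
    return SimulatedPSG(rec, stages, tuple(truth))


def apply_scorer_model(truth: tuple[TrueEvent, ...], model: ScorerModel,
                       seed: int = 0) -> EventList:
    """Annotations a simulated scorer would produce for the planted truth.

    Events below the amplitude threshold are not seen; events near the
    threshold are missed with a logistic probability (scale 2 µV). The
    ``fixed_1s`` duration style replaces every duration by 1.0 s centered on
    the event midpoint, mimicking scorers who mark occurrences only.
    """
    threshold, style = model
    if style not in DURATION_STYLES:
        raise ValueError(f"unknown duration style {style!r}")
    rng = np.random.default_rng(seed)
    out = []
    width = 2.0  # µV, softness of the sensitivity threshold
    for ev in truth:
        if threshold > 0:
            p_seen = 1.0 / (1.0 + np.exp(-(ev.amplitude - threshold) / width))
            if rng.random() >= p_seen:
                continue
        if style == "fixed_1s":
            mid = ev.onset + ev.duration / 2.0
            out.append((max(0.0, mid - 0.5), 1.0))
        else:
            out.append((ev.onset, ev.duration))
    return EventList(tuple(sorted(out)))


def sigma_band_snr(psg: SimulatedPSG) -> np.ndarray:
    """Per-event ratio of in-event sigma-band RMS to background sigma RMS."""
    rec = psg.recording
    filt = bandpass_sigma(rec).samples
    mask = np.zeros(rec.n_samples, dtype=bool)
    for ev in psg.truth:
        i0 = int(round(ev.onset * rec.rate))
        i1 = int(round((ev.onset + ev.duration) * rec.rate))
        mask[i0:i1] = True
    background = filt[~mask]
    bg_rms = np.sqrt(np.mean(background ** 2)) if background.size else 1.0
    ratios = []
    for ev in psg.truth:
        i0 = int(round(ev.onset * rec.rate))
        i1 = int(round((ev.onset + ev.duration) * rec.rate))
        ratios.append(np.sqrt(np.mean(filt[i0:i1] ** 2)) / bg_rms)
    return np.array(ratios)


def write_dataset(directory: str | Path, psg: SimulatedPSG,
                  name: str = "subject") -> dict[str, Path]:
    """Write a simulated recording in the formats the readers accept.

    Produces ``<name>.edf`` (signal), ``<name>_hypnogram.txt`` and one
    annotation file per scorer-independent truth (``<name>_truth.txt``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": directory / f"{name}.edf",
        "hypnogram": directory / f"{name}_hypnogram.txt",
        "truth": directory / f"{name}_truth.txt",
    }
    write_edf_signal(paths["edf"], psg.recording)
    write_hypnogram(paths["hypnogram"], psg.stages)
    write_annotations(paths["truth"], psg.events)
    return paths
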