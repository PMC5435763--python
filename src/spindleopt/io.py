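"""Domain types and file formats for single-channel sleep EEG.

All internal times are seconds. Intervals are half-open ``[onset, onset +
duration)``; sample ``i`` of a recording covers time ``i / rate``. Conversions
between event lists and boolean sample masks happen only at the mask boundary,
so recordings at different native rates (50/100/200/256 Hz) mix freely.

Formats:

* EDF (16-bit, plain header) for signals — read via :mod:`mne`, written by a
  minimal built-in writer;
* annotations — plain text, one ``onset<whitespace>duration`` pair per line,
  ``#`` comments;
* hypnograms — plain text, header line ``epoch_length <seconds>`` followed by
  one stage label per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STAGES = ("W", "N1", "N2", "N3", "N4", "REM", "UNKNOWN")
#: Stages used for amplitude normalization (NREM 2/3/4).
NREM_DEEP = ("N2", "N3", "N4")


class FormatError(ValueError):
    """Malformed input file."""


class ChannelNotFoundError(KeyError):
    """Requested channel label absent from an EDF file."""


@dataclass(frozen=True)
class Recording:
    """Uniformly sampled single-channel EEG trace in microvolts."""

    samples: np.ndarray
    rate: float
    channel: str = "EEG"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def slice(self, t0: float, t1: float) -> "Recording":
        """Sub-recording covering ``[t0, t1)`` (clipped to the record)."""
        i0 = max(0, int(np.ceil(t0 * self.rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil(t1 * self.rate - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{t0}, {t1})")
        return Recording(self.samples[i0:i1], self.rate, self.channel)


@dataclass(frozen=True)
class StageSeries:
    """Per-epoch sleep stages aligned to a recording."""

    epoch_length: float
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        stages = tuple(self.stages)
        for s in stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage label {s!r}")
        object.__setattr__(self, "stages", stages)

    @classmethod
    def constant(cls, stage: str, duration: float,
                 epoch_length: float = 30.0) -> "StageSeries":
        n = max(1, int(np.ceil(duration / epoch_length)))
        return cls(epoch_length, (stage,) * n)

    def stage_at(self, t: float) -> str:
        i = int(t // self.epoch_length)
        i = min(max(i, 0), len(self.stages) - 1)
        return self.stages[i]

    def mask(self, rate: float, n_samples: int,
             include: Sequence[str]) -> np.ndarray:
        """Boolean sample mask of the samples whose epoch stage is in *include*."""
        idx = (np.arange(n_samples) / rate // self.epoch_length).astype(int)
        idx = np.clip(idx, 0, len(self.stages) - 1)
        table = np.array([s in include for s in self.stages])
        return table[idx]

    def slice(self, t0: float, t1: float) -> "StageSeries":
        """Stage series for a signal segment ``[t0, t1)``: the stage at each
        epoch-grid point of the segment, read from the parent series."""
        n = max(1, int(np.ceil((t1 - t0) / self.epoch_length)))
        labels = tuple(self.stage_at(t0 + k * self.epoch_length) for k in range(n))
        return StageSeries(self.epoch_length, labels)


@dataclass(frozen=True)
class EventList:
    """Ordered list of (onset, duration) intervals in seconds."""

    events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        evs = tuple((float(o), float(d)) for o, d in self.events)
        for o, d in evs:
            if d <= 0:
                raise ValueError(f"event duration must be positive, got {d}")
        if any(evs[i][0] > evs[i + 1][0] for i in range(len(evs) - 1)):
            evs = tuple(sorted(evs))
        object.__setattr__(self, "events", evs)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([o for o, _ in self.events])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.events])

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [start, end) times."""
        if not self.events:
            return np.empty((0, 2))
        a = np.array(self.events)
        return np.column_stack([a[:, 0], a[:, 0] + a[:, 1]])

    def merge(self) -> "EventList":
        """Union of the intervals: overlapping/touching events coalesced."""
        if not self.events:
            return self
        out: list[list[float]] = []
        for s, e in self.intervals():
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return EventList(tuple((s, e - s) for s, e in out))

    def dilate(self, pad: float) -> "EventList":
        """Pad every event by *pad* seconds on both ends (clipped at 0)."""
        return EventList(tuple((max(0.0, o - pad), d + pad + min(pad, o))
                               for o, d in self.events))

    def shift(self, dt: float) -> "EventList":
        return EventList(tuple((o + dt, d) for o, d in self.events))

    def clip(self, t0: float, t1: float) -> "EventList":
        """Intersect every event with [t0, t1); drop emptied events."""
        kept = []
        for s, e in self.intervals():
            s2, e2 = max(s, t0), min(e, t1)
            if e2 > s2:
                kept.append((s2, e2 - s2))
        return EventList(tuple(kept))


@dataclass(frozen=True)
class SampleMask:
    """Boolean sequence aligned to a recording's sample grid."""

    mask: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.rate <= 0:
            raise ValueError("rate must be positive")


# ---------------------------------------------------------------------------
# event <-> mask conversions

def events_to_mask(events: EventList, rate: float, n_samples: int) -> SampleMask:
    """Rasterize events onto a sample grid.

    Sample ``i`` is true iff ``i / rate`` lies in some half-open event interval.
    Events extending beyond the grid are clipped with a logged warning.
    """
    if rate <= 0 or n_samples < 1:
        raise ValueError("rate must be positive and n_samples >= 1")
    mask = np.zeros(n_samples, dtype=bool)
    end_time = n_samples / rate
    for onset, dur in events:
        if onset + dur > end_time + 1e-9:
            logger.warning("event (%.3f, %.3f) extends beyond recording end "
                           "%.3f s; clipped", onset, dur, end_time)
        i0 = int(np.ceil(onset * rate - 1e-9))
        i1 = int(np.ceil((onset + dur) * rate - 1e-9))
        mask[max(i0, 0):min(i1, n_samples)] = True
    return SampleMask(mask, rate)


def mask_to_events(mask: SampleMask) -> EventList:
    """Regroup a sample mask into events, one per maximal run of true samples.

    No minimum-duration filter is applied: arbitrarily short runs survive.
    """
    m = mask.mask
    if not m.any():
        return EventList()
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return EventList(tuple((s / mask.rate, (e - s) / mask.rate)
                           for s, e in zip(starts, ends)))


# ---------------------------------------------------------------------------
# EDF

def read_edf_signal(path: str | Path, channel: str) -> Recording:
    """Read one channel of an EDF file as a :class:`Recording` in µV.

    No resampling is performed; the file's native rate is kept.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises bare ValueError on bad headers
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {raw.ch_names}")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> µV
    return Recording(data, float(raw.info["sfreq"]), channel)


def write_edf_signal(path: str | Path,
                     rec: Recording | Sequence[Recording],
                     physical_max: float | None = None) -> None:
    """Write one or more equal-rate channels as a minimal 16-bit EDF file.

    The record duration is 1 s, so traces are zero-padded up to a whole
    number of seconds. Amplitudes are quantized to 16 bits over the symmetric
    physical range ``±physical_max`` (default: smallest power of ten covering
    the data).
    """
    recs = [rec] if isinstance(rec, Recording) else list(rec)
    rate = recs[0].rate
    if any(r.rate != rate for r in recs):
        raise ValueError("all channels must share one sampling rate")
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1-s record
    n_rec = int(np.ceil(max(r.n_samples for r in recs) / spr))
    if physical_max is None:
        peak = max(float(np.abs(r.samples).max()) for r in recs)
        physical_max = 10.0 ** np.ceil(np.log10(max(peak, 1.0)))
    pmin, pmax = -physical_max, physical_max
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.zeros((len(recs), n_rec * spr), dtype="<i2")
    for ci, r in enumerate(recs):
        padded = np.zeros(n_rec * spr)
        padded[: r.n_samples] = r.samples
        digital[ci] = np.clip(np.round((padded - pmin) * gain + dmin),
                              dmin, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    ns = len(recs)
    header = b"".join([
        f("0", 8),                      # version
        f("X X X X", 80),               # patient id
        f("Startdate X X X X", 80),     # recording id
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 + 256 * ns), 8),
        f("", 44),
        f(str(n_rec), 8), f("1", 8), f(str(ns), 4),
        # per-signal fields, each field repeated for every signal
        *[f(r.channel, 16) for r in recs],
        *[f("", 80)] * ns,
        *[f("uV", 8)] * ns,
        *[f(f"{pmin:g}", 8)] * ns,
        *[f(f"{pmax:g}", 8)] * ns,
        *[f(str(dmin), 8)] * ns,
        *[f(str(dmax), 8)] * ns,
        *[f("", 80)] * ns,
        *[f(str(spr), 8)] * ns,
        *[f("", 32)] * ns,
    ])
    assert len(header) == 256 + 256 * ns
    with open(path, "wb") as fh:
        fh.write(header)
        # data records: per record, all samples of ch1, then ch2, ...
        for ri in range(n_rec):
            for ci in range(ns):
                fh.write(digital[ci, ri * spr:(ri + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# plain-text annotations and hypnograms

def read_annotations(path: str | Path,
                     dialect: str = "dreams_text") -> EventList:
    """Parse a plain-text annotation file into an :class:`EventList`.

    Both supported dialects (``dreams_text``, ``generic_tsv``) hold one
    ``onset<whitespace>duration`` pair per non-comment line, in seconds.
    """
    if dialect not in ("dreams_text", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            parts = stripped.replace("\t", " ").split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'onset duration', got {line!r}")
            try:
                onset, dur = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if dur <= 0:
                raise FormatError(
                    f"{path}:{lineno}: non-positive duration {dur}")
            events.append((onset, dur))
    return EventList(tuple(events))


def write_annotations(path: str | Path, events: EventList) -> None:
    with open(path, "w") as fh:
        fh.write("# onset_s duration_s\n")
        for onset, dur in events:
            fh.write(f"{onset:.6g} {dur:.6g}\n")


def read_hypnogram(path: str | Path) -> StageSeries:
    """Read a hypnogram: ``epoch_length <s>`` header then one stage per line."""
    with open(path) as fh:
        lines = [ln.split("#", 1)[0].strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines or not lines[0].lower().startswith("epoch_length"):
        raise FormatError(f"{path}: missing 'epoch_length' header line")
    try:
        epoch_length = float(lines[0].split()[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: bad epoch_length header") from exc
    return StageSeries(epoch_length, tuple(lines[1:]))


def write_hypnogram(path: str | Path, stages: StageSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"epoch_length {stages.epoch_length:g}\n")
        for s in stages.stages:
            fh.write(s + "\n")
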