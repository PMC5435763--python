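"""Shared fixtures: planted-burst recordings and synthetic PSG subjects."""

import numpy as np
import pytest

from spindleopt import (EventList, Recording, SimulationConfig, StageSeries,
                        Subject, simulate_psg)


def make_burst_recording(seed=0, rate=200.0, duration=60.0,
                         bursts=((30.0, 1.0, 40.0),), freq=13.0,
                         background_std=6.0):
    """Pink-noise background with Hann-windowed sigma bursts planted at known
    times. Returns (Recording, StageSeries all-N2, gold EventList)."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** -0.5
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    if background_std > 0:
        x *= background_std / x.std()
    else:
        x[:] = 0.0
    t = np.arange(n) / rate
    for onset, dur, amp in bursts:
        i0, i1 = int(onset * rate), int((onset + dur) * rate)
        tt = t[i0:i1] - onset
        x[i0:i1] += amp * np.sin(np.pi * tt / dur) ** 2 * \
            np.sin(2 * np.pi * freq * tt)
    rec = Recording(x, rate)
    stages = StageSeries.constant("N2", duration)
    gold = EventList(tuple((o, d) for o, d, _ in bursts))
    return rec, stages, gold


@pytest.fixture(scope="session")
def burst_fixture():
    """Single high-SNR 13 Hz burst of 1 s planted at t=30 s."""
    return make_burst_recording()


@pytest.fixture(scope="session")
def noise_fixture():
    """Pure pink-noise recording (no bursts), all-N2 stages."""
    rec, stages, _ = make_burst_recording(seed=7, bursts=())
    return rec, stages


@pytest.fixture(scope="session")
def smoke_psg():
    """5-minute synthetic PSG at the default study conditions."""
    return simulate_psg(SimulationConfig(duration=300.0, seed=42))


def make_subjects(n, seed0, duration=600.0):
    """Synthetic subjects at the default study conditions."""
    out = []
    for i in range(n):
        psg = simulate_psg(SimulationConfig(duration=duration, seed=seed0 + i))
        out.append(Subject(psg.recording, psg.stages, psg.events, f"s{i}"))
    return out
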