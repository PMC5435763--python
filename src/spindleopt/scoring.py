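"""Event-based scoring: overlap-rate matching, precision/recall/F-beta,
and gold-standard fusion across scorers.

A detection confirms a true spindle only when their intersection-over-union
(overlap rate) strictly exceeds a threshold, 0.2 by default. Matching is
one-to-one and greedy by descending overlap rate, so every gold event and
every detection is used at most once — which is what the count identities
``TP + FN = |gold|`` and ``TP + FP = |detections|`` behind precision and
recall implicitly assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EventList, SampleMask, events_to_mask, mask_to_events

#: default overlap-rate threshold for a true positive (strict >)
DEFAULT_R_OV = 0.2

#: virtual sample grid used when fusing annotation lists with no recording
VIRTUAL_RATE = 256.0


@dataclass(frozen=True)
class MatchResult:
    """TP/FN/FP counts plus the matched (gold, detection) index pairs."""

    tp: int
    fn: int
    fp: int
    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")
        if self.pairs and len(self.pairs) != self.tp:
            raise ValueError("pairs must list exactly tp matches")

    def __add__(self, other: "MatchResult") -> "MatchResult":
        # pooled counts; index pairs are meaningless across recordings
        return MatchResult(self.tp + other.tp, self.fn + other.fn,
                           self.fp + other.fp, ())


def overlap_rate(ss: tuple[float, float], d: tuple[float, float]) -> float:
    """Intersection-over-union of two (onset, duration) intervals."""
    if ss[1] <= 0 or d[1] <= 0:
        raise ValueError("intervals must have positive duration")
    s0, s1 = ss[0], ss[0] + ss[1]
    d0, d1 = d[0], d[0] + d[1]
    inter = max(0.0, min(s1, d1) - max(s0, d0))
    union = (s1 - s0) + (d1 - d0) - inter
    return inter / union


def match_events(gold: EventList, det: EventList,
                 r_ov: float = DEFAULT_R_OV) -> MatchResult:
    """One-to-one greedy matching of detections to gold events.

    Candidate pairs with overlap rate strictly above *r_ov* are taken in
    order of descending overlap rate (ties by earlier gold onset, then
    earlier detection onset); each event participates in at most one match.
    """
    cands: list[tuple[float, float, float, int, int]] = []
    for i, g in enumerate(gold):
        for j, d in enumerate(det):
            if d[0] >= g[0] + g[1]:
                # detections are onset-sorted: no later one can overlap g
                break
            r = overlap_rate(g, d)
            if r > r_ov:
                cands.append((-r, g[0], d[0], i, j))
    cands.sort()
    used_g: set[int] = set()
    used_d: set[int] = set()
    pairs = []
    for _, _, _, i, j in cands:
        if i not in used_g and j not in used_d:
            used_g.add(i)
            used_d.add(j)
            pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp, len(gold) - tp, len(det) - tp, tuple(pairs))


def prf_metrics(m: MatchResult, beta: float = 1.0
                ) -> tuple[float, float, float]:
    """Precision, recall and the F-beta score of a match result.

    Zero-denominator conventions: ``P = 0`` when there are no detections,
    ``R = 0`` when there are no gold events, and ``F = 0`` when both P and R
    vanish — so the empty detector and the empty gold standard are
    well-defined extremes.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    f = fbeta(p, r, beta)
    return p, r, f


def fbeta(p: float, r: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean of precision and recall."""
    if p == 0.0 and r == 0.0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * p * r / (r + b2 * p)


def fuse_by_sample(a: EventList, b: EventList, rate: float | None = None,
                   n_samples: int | None = None,
                   mode: str = "union") -> EventList:
    """By-sample union/intersection of two event lists.

    The two lists are rasterized on a shared sample grid, combined with
    boolean OR/AND, and regrouped into events with no duration filtering.
    Without an explicit grid a 256 Hz virtual grid spanning the events is
    used.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union|intersection, got {mode!r}")
    if rate is None:
        rate = VIRTUAL_RATE
    if n_samples is None:
        end = max([o + d for o, d in a] + [o + d for o, d in b], default=1.0)
        n_samples = int(np.ceil(end * rate)) + 1
    ma = events_to_mask(a, rate, n_samples).mask
    mb = events_to_mask(b, rate, n_samples).mask
    fused = (ma | mb) if mode == "union" else (ma & mb)
    return mask_to_events(SampleMask(fused, rate))


def dreams_combine_scorers(a: EventList, b: EventList,
                           mode: str = "union") -> EventList:
    """Two-scorer agreement sets with expert-1 priority on overlaps.

    This is the partial/total-agreement rule used for annotation pairs where
    the second scorer assigns fixed durations: whenever events of the two
    scorers overlap at all, expert 1's interval is kept for its better
    duration assessment. Union mode additionally keeps expert-2 events that
    overlap nothing of expert 1; intersection mode keeps only expert-1 events
    confirmed by expert 2.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union|intersection, got {mode!r}")

    def overlaps(u: tuple[float, float], v: tuple[float, float]) -> bool:
        return min(u[0] + u[1], v[0] + v[1]) > max(u[0], v[0])

    if mode == "intersection":
        kept = [e1 for e1 in a if any(overlaps(e1, e2) for e2 in b)]
        return EventList(tuple(kept))
    extra = [e2 for e2 in b if not any(overlaps(e2, e1) for e1 in a)]
    return EventList(tuple(list(a) + extra))
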