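"""Training/validation protocols: subsampling, hold-out, k-fold, and
Monte-Carlo confidence intervals for the F1-score.

The optimizer never trains on whole-night recordings directly. A detector-
specific *subsample* — the neighborhoods of all gold spindles plus the false
positives a collector parameter set produces, dilated and merged, randomly
drawn up to a target total length — stands in for the full training data.
Selection of the final operating point, however, is always judged on the
complete training recordings, and held-out test data is evaluated exactly
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detectors import HybridDetector, NormalizationStats, \
    SimplexDetector, normalization_stats, stage_gate
from .io import EventList, Recording, StageSeries
from .moea import MOEAConfig, ObjectivePoint, ParetoFront, spea2_optimize
from .scoring import DEFAULT_R_OV, MatchResult, match_events, prf_metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subject:
    """One recording with its hypnogram and gold-standard annotations."""

    recording: Recording
    stages: StageSeries | None
    gold: EventList
    name: str = ""
    #: normalization statistics inherited from a parent full recording
    #: (set on subsample segments so thresholds stay those of the whole night)
    stats: NormalizationStats | None = None


@dataclass(frozen=True)
class SubsampleSpec:
    """Settings of the subsample builder."""

    dilation: float = 2.5          # s, padding around collected events
    target_total: float = 3600.0   # s of subsample signal to draw
    collector_beta: float = 2.0    # F-score weight used to pick the collector
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilation < 0:
            raise ValueError("dilation must be >= 0")
        if self.target_total <= 0:
            raise ValueError("target_total must be positive")


@dataclass
class SplitResult:
    """Metrics of one evaluation split (train, test, or one fold)."""

    name: str
    match: MatchResult
    precision: float
    recall: float
    f1: float
    selected_x: np.ndarray | None = None


@dataclass
class ValidationReport:
    """Per-split results plus micro-averaged pooled totals."""

    splits: list[SplitResult]
    pooled: MatchResult
    pooled_precision: float
    pooled_recall: float
    pooled_f1: float
    fronts: list[ParetoFront] = field(default_factory=list)
    ci: tuple[float, float] | None = None
    audit: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cached detection

class CachedDetector:
    """Preprocesses every subject once; detection per parameter set is cheap.

    For hybrid detectors (whose second-stage input depends on the parameter
    vector) detection falls back to the full pipeline.
    """

    def __init__(self, detector: SimplexDetector | HybridDetector,
                 subjects: Sequence[Subject]) -> None:
        self.detector = detector
        self.subjects = list(subjects)
        self._feats: list[dict] | None = None
        if isinstance(detector, SimplexDetector):
            self._feats = []
            for s in self.subjects:
                stages = s.stages or StageSeries.constant(
                    "N2", s.recording.duration)
                self._feats.append(
                    detector.preprocess(s.recording, stages, stats=s.stats))

    def detect_all(self, x: np.ndarray) -> list[EventList]:
        out = []
        for i, s in enumerate(self.subjects):
            if self._feats is not None:
                events = self.detector.detect(self._feats[i], x)
                if s.stages is not None:
                    events = stage_gate(events, s.stages, s.recording)
            else:
                events = self.detector.run(s.recording, s.stages, x)
            out.append(events)
        return out

    def objective(self, x: np.ndarray,
                  r_ov: float = DEFAULT_R_OV) -> ObjectivePoint:
        fn = fp = 0
        for events, s in zip(self.detect_all(x), self.subjects):
            m = match_events(s.gold, events, r_ov)
            fn += m.fn
            fp += m.fp
        return ObjectivePoint(fn, fp)

    def match_pooled(self, x: np.ndarray,
                     r_ov: float = DEFAULT_R_OV) -> MatchResult:
        total = MatchResult(0, 0, 0)
        for events, s in zip(self.detect_all(x), self.subjects):
            total = total + match_events(s.gold, events, r_ov)
        return total

    @property
    def n_gold(self) -> int:
        return sum(len(s.gold) for s in self.subjects)


# ---------------------------------------------------------------------------
# subsample builder

def build_subsample(subjects: Sequence[Subject],
                    detector: SimplexDetector | HybridDetector,
                    collector_params: np.ndarray,
                    spec: SubsampleSpec,
                    r_ov: float = DEFAULT_R_OV) -> list[Subject]:
    """Detector-dependent training subsample.

    Runs the detector with the *collector* parameters, takes its false
    positives plus all gold events, dilates each by ``spec.dilation`` on both
    ends, merges overlaps into a pool of segments, and draws segments at
    random (seeded, without replacement) until their total length reaches
    ``spec.target_total``. Each returned segment is an independent
    :class:`Subject` with clipped gold annotations and stage labels.
    """
    pool: list[tuple[int, float, float]] = []
    parent_stats: list[NormalizationStats | None] = []
    for si, s in enumerate(subjects):
        parent_stats.append(
            normalization_stats(s.recording, s.stages)
            if s.stages is not None else None)
        detections = detector.run(s.recording, s.stages,
                                  np.asarray(collector_params, float))
        m = match_events(s.gold, detections, r_ov)
        matched_det = {j for _, j in m.pairs}
        fps = EventList(tuple(detections[j] for j in range(len(detections))
                              if j not in matched_det))
        seeds = EventList(tuple(list(fps) + list(s.gold)))
        segments = seeds.dilate(spec.dilation).merge()
        for t0, t1 in segments.intervals():
            pool.append((si, t0, min(t1, s.recording.duration)))

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(pool))
    total_available = sum(t1 - t0 for _, t0, t1 in pool)
    chosen: list[tuple[int, float, float]] = []
    drawn = 0.0
    for idx in order:
        if drawn >= spec.target_total:
            break
        chosen.append(pool[idx])
        drawn += pool[idx][2] - pool[idx][1]
    if total_available < spec.target_total:
        logger.warning("subsample pool (%.0f s) shorter than target %.0f s; "
                       "using the whole pool", total_available,
                       spec.target_total)

    out = []
    for si, t0, t1 in chosen:
        s = subjects[si]
        stages = s.stages.slice(t0, t1) if s.stages is not None else None
        out.append(Subject(
            recording=s.recording.slice(t0, t1),
            stages=stages,
            gold=s.gold.clip(t0, t1).shift(-t0),
            name=f"{s.name}[{t0:.1f}-{t1:.1f}]",
            stats=parent_stats[si]))
    return out


def select_collector(reference: Sequence[Subject],
                     detector: SimplexDetector | HybridDetector,
                     cfg: MOEAConfig, spec: SubsampleSpec,
                     r_ov: float = DEFAULT_R_OV) -> np.ndarray:
    """Collector parameters for the subsample builder.

    The collector should be recall-heavy so its false positives populate the
    subsample with the hard negative neighborhoods: a preliminary SPEA2 pass
    on the reference recordings, from whose front the maximal
    F_beta (beta = ``spec.collector_beta``, i.e. recall-weighted) member is
    taken.
    """
    from .moea import front_metrics
    cache = CachedDetector(detector, reference)
    pre_cfg = MOEAConfig(pop_size=min(cfg.pop_size, 40),
                         max_gen=min(cfg.max_gen, 30),
                         seed=cfg.seed + 101, crossover=cfg.crossover,
                         mutation=cfg.mutation)
    front = spea2_optimize(lambda x: cache.objective(x, r_ov),
                           _detector_bounds(detector), pre_cfg)
    metrics = front_metrics(front, cache.n_gold, beta=spec.collector_beta)
    return metrics.best.x


# ---------------------------------------------------------------------------
# validation drivers

def _select_max_f1(front: ParetoFront, train_cache: CachedDetector,
                   r_ov: float) -> tuple[np.ndarray, MatchResult]:
    """Max-F1 front member judged on the complete training recordings."""
    best_x, best_match, best_key = None, None, None
    for member in front:
        m = train_cache.match_pooled(member.x, r_ov)
        _, _, f1 = prf_metrics(m)
        key = (f1, -m.fp)
        if best_key is None or key > best_key:
            best_x, best_match, best_key = member.x, m, key
    assert best_x is not None
    return best_x, best_match


def run_holdout(train: Sequence[Subject], test: Sequence[Subject],
                detector: SimplexDetector | HybridDetector,
                cfg: MOEAConfig, spec: SubsampleSpec,
                collector_params: np.ndarray | None = None,
                r_ov: float = DEFAULT_R_OV) -> ValidationReport:
    """Hold-out validation: optimize on a training subsample, select the
    max-F1 operating point on the complete training recordings, and evaluate
    it exactly once on the held-out test group."""
    if not train or not test:
        raise ValueError("train and test groups must be non-empty")
    if collector_params is None:
        collector_params = select_collector(train, detector, cfg, spec, r_ov)
    segments = build_subsample(train, detector, collector_params, spec, r_ov)
    sub_cache = CachedDetector(detector, segments)
    front = spea2_optimize(lambda x: sub_cache.objective(x, r_ov),
                           _detector_bounds(detector), cfg)
    train_cache = CachedDetector(detector, train)
    best_x, train_match = _select_max_f1(front, train_cache, r_ov)

    test_cache = CachedDetector(detector, test)
    test_match = test_cache.match_pooled(best_x, r_ov)
    test_evaluations = 1  # by construction: a single detection pass on test

    splits = []
    for name, match in (("train", train_match), ("test", test_match)):
        p, r, f1 = prf_metrics(match)
        splits.append(SplitResult(name, match, p, r, f1, best_x))
    pooled = test_match
    p, r, f1 = prf_metrics(pooled)
    return ValidationReport(
        splits=splits, pooled=pooled, pooled_precision=p, pooled_recall=r,
        pooled_f1=f1, fronts=[front],
        audit={"test_detection_passes": test_evaluations,
               "front_size": len(front),
               "n_subsample_segments": len(segments)})


def run_kfold(subjects: Sequence[Subject],
              detector: SimplexDetector | HybridDetector,
              cfg: MOEAConfig, spec: SubsampleSpec, k: int = 3,
              seed: int = 0,
              collector_params: np.ndarray | None = None,
              r_ov: float = DEFAULT_R_OV) -> ValidationReport:
    """K-fold cross-validation with subject-level partitioning.

    Subjects are randomly split into *k* near-equal groups; each group serves
    exactly once as validation data while the remaining groups are used for
    subsample training. The pooled result micro-averages the per-fold counts.
    """
    subjects = list(subjects)
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = [sorted(f.tolist()) for f in np.array_split(order, k)]

    splits = []
    fronts = []
    pooled = MatchResult(0, 0, 0)
    for fi, val_idx in enumerate(folds):
        val = [subjects[i] for i in val_idx]
        tr = [subjects[i] for i in range(len(subjects)) if i not in val_idx]
        fold_cfg = MOEAConfig(
            pop_size=cfg.pop_size, max_gen=cfg.max_gen,
            archive_size=cfg.archive_size, seed=cfg.seed + fi,
            crossover=cfg.crossover, mutation=cfg.mutation)
        rep = run_holdout(tr, val, detector, fold_cfg, spec,
                          collector_params, r_ov)
        test_split = next(s for s in rep.splits if s.name == "test")
        pooled = pooled + test_split.match
        splits.append(SplitResult(f"fold{fi}", test_split.match,
                                  test_split.precision, test_split.recall,
                                  test_split.f1, test_split.selected_x))
        fronts.extend(rep.fronts)
    p, r, f1 = prf_metrics(pooled)
    return ValidationReport(
        splits=splits, pooled=pooled, pooled_precision=p, pooled_recall=r,
        pooled_f1=f1, fronts=fronts,
        audit={"fold_sizes": [len(f) for f in folds],
               "fold_subjects": [[subjects[i].name for i in f]
                                 for f in folds]})


def _detector_bounds(detector) -> tuple[np.ndarray, np.ndarray]:
    from .detectors import default_bounds
    return default_bounds(detector.id)


# ---------------------------------------------------------------------------
# Monte-Carlo confidence interval

def f1_confidence_interval(tp: int, fn: int, fp: int, draws: int = 10_000,
                           level: float = 0.95,
                           seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo confidence interval for F1 from Beta-distributed P and R.

    With a uniform prior, precision ~ Beta(tp+1, fp+1) and recall ~
    Beta(tp+1, fn+1); *draws* independent (P, R) pairs give an empirical F1
    distribution whose central *level* quantile band is returned.
    """
    if tp + fp <= 0 or tp + fn <= 0:
        raise ValueError("need tp+fp > 0 and tp+fn > 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.beta(tp + 1, fp + 1, size=draws)
    r = rng.beta(tp + 1, fn + 1, size=draws)
    f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(f1, alpha)),
            float(np.quantile(f1, 1.0 - alpha)))


def counts_from_rates(precision: float, recall: float,
                      n_gold: int) -> tuple[int, int, int]:
    """Reconstruct (tp, fn, fp) from printed precision/recall and gold size.

    ``TP = round(R * n_gold)``; ``FP = round(TP / P) - TP``. Useful for
    re-deriving confidence intervals from published three-decimal tables.
    """
    tp = int(round(recall * n_gold))
    fn = n_gold - tp
    fp = int(round(tp / precision)) - tp
    return tp, fn, fp
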