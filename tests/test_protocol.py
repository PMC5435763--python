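"""Subsample builder, hold-out / k-fold drivers and Monte-Carlo CIs."""

import numpy as np
import pytest
from scipy import stats as sps

from spindleopt import (CachedDetector, EventList, MOEAConfig, Recording,
                        SampleMask, Subject, SubsampleSpec,
                        build_subsample, counts_from_rates,
                        f1_confidence_interval, get_detector, mask_to_events,
                        prf_metrics, run_holdout, run_kfold, spea2_optimize)
from spindleopt.detectors import SimplexDetector

from conftest import make_subjects


class MarkerDetector(SimplexDetector):
    """Detects rectangular amplitude markers; parameters are ignored.

    Gives protocol tests a fast, exact detector: planting markers equal to
    the gold events makes detector output and gold coincide by construction.
    """

    id = "d3"  # borrow a small parameter space for the optimizer
    needs_stages = False

    def preprocess(self, rec, stages=None, stats=None):
        return {"mask": rec.samples > 0.5, "rate": rec.rate}

    def candidates(self, feats, x):
        return mask_to_events(SampleMask(feats["mask"], feats["rate"]))

    def duration_gate(self, x):
        return 0.0, np.inf

    def detect(self, feats, x):
        return self.candidates(feats, x)

    def run(self, rec, stages, x):
        return self.detect(self.preprocess(rec), x)


def marker_subject(events, duration=60.0, rate=10.0, name="m",
                   marked=None) -> Subject:
    """Subject whose recording carries 1.0-amplitude markers.

    *marked* (default: the gold events) controls where markers are placed,
    so detector false positives can be planted deliberately.
    """
    x = np.zeros(int(duration * rate))
    for onset, dur in (marked if marked is not None else events):
        x[int(onset * rate):int((onset + dur) * rate)] = 1.0
    return Subject(Recording(x, rate), None, EventList(tuple(events)), name)


class TestBuildSubsample:
    def test_dilation_merges_fp_and_gold_neighborhoods(self):
        # marker (detection) at 10 s is a false positive; gold at 12 s is
        # missed; dilation by 2.5 s merges [7.5,13.5] and [9.5,15.5]
        subj = marker_subject([(12.0, 1.0)], marked=[(10.0, 1.0)])
        spec = SubsampleSpec(dilation=2.5, target_total=100.0, seed=0)
        segs = build_subsample([subj], MarkerDetector(), np.zeros(3), spec)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.recording.duration == pytest.approx(8.0)
        assert seg.gold.events == ((4.5, 1.0),)

    def test_stopping_rule(self):
        events = [(float(o), 0.5) for o in range(5, 295, 10)]
        subj = marker_subject(events, duration=300.0)
        spec = SubsampleSpec(dilation=1.0, target_total=20.0, seed=1)
        segs = build_subsample([subj], MarkerDetector(), np.zeros(3), spec)
        total = sum(s.recording.duration for s in segs)
        longest = max(s.recording.duration for s in segs)
        assert 20.0 <= total < 20.0 + longest

    def test_deterministic_in_seed(self):
        events = [(float(o), 0.5) for o in range(5, 295, 10)]
        subj = marker_subject(events, duration=300.0)
        spec = SubsampleSpec(dilation=1.0, target_total=20.0, seed=7)
        a = build_subsample([subj], MarkerDetector(), np.zeros(3), spec)
        b = build_subsample([subj], MarkerDetector(), np.zeros(3), spec)
        assert [s.name for s in a] == [s.name for s in b]

    def test_short_pool_returns_everything_with_warning(self, caplog):
        subj = marker_subject([(5.0, 1.0)])
        spec = SubsampleSpec(target_total=500.0, seed=0)
        import logging
        with caplog.at_level(logging.WARNING, logger="spindleopt.protocol"):
            segs = build_subsample([subj], MarkerDetector(), np.zeros(3),
                                   spec)
        assert len(segs) == 1
        assert any("shorter than target" in r.message
                   for r in caplog.records)


class CountingMarkerDetector(MarkerDetector):
    """Counts detection passes per recording object (protocol audit)."""

    def __init__(self):
        self.detect_counts: dict[int, int] = {}
        self._rec_of_feats: dict[int, int] = {}

    def preprocess(self, rec, stages=None, stats=None):
        feats = super().preprocess(rec, stages, stats)
        self._rec_of_feats[id(feats["mask"])] = id(rec)
        return feats

    def detect(self, feats, x):
        key = self._rec_of_feats[id(feats["mask"])]
        self.detect_counts[key] = self.detect_counts.get(key, 0) + 1
        return super().detect(feats, x)

    def run(self, rec, stages, x):
        self.detect_counts[id(rec)] = self.detect_counts.get(id(rec), 0) + 1
        return super().run(rec, stages, x)


SMALL_CFG = MOEAConfig(pop_size=8, max_gen=3, seed=0)
SMALL_SPEC = SubsampleSpec(dilation=1.0, target_total=30.0, seed=0)


def marker_group(n, seed, duration=60.0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        onsets = np.sort(rng.uniform(2, duration - 4, 4))
        onsets = onsets[np.r_[True, np.diff(onsets) > 2.0]]
        events = [(float(o), 1.0) for o in onsets]
        out.append(marker_subject(events, duration=duration, name=f"m{i}"))
    return out


class TestRunHoldout:
    def test_perfect_detector_scores_one_on_test(self):
        train, test = marker_group(3, 0), marker_group(3, 1)
        rep = run_holdout(train, test, MarkerDetector(), SMALL_CFG,
                          SMALL_SPEC, collector_params=np.zeros(3))
        test_split = next(s for s in rep.splits if s.name == "test")
        assert test_split.f1 == 1.0

    def test_test_data_touched_exactly_once(self):
        train, test = marker_group(3, 2), marker_group(2, 3)
        det = CountingMarkerDetector()
        rep = run_holdout(train, test, det, SMALL_CFG, SMALL_SPEC,
                          collector_params=np.zeros(3))
        assert rep.audit["test_detection_passes"] == 1
        for s in test:
            assert det.detect_counts.get(id(s.recording), 0) == 1

    def test_selected_vector_comes_from_front(self):
        train, test = marker_group(3, 4), marker_group(2, 5)
        rep = run_holdout(train, test, MarkerDetector(), SMALL_CFG,
                          SMALL_SPEC, collector_params=np.zeros(3))
        front_xs = [tuple(m.x) for m in rep.fronts[0]]
        sel = next(s for s in rep.splits if s.name == "train").selected_x
        assert tuple(sel) in front_xs

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            run_holdout([], marker_group(1, 0), MarkerDetector(),
                        SMALL_CFG, SMALL_SPEC, collector_params=np.zeros(3))


class TestRunKfold:
    def test_partition_covers_every_subject_once(self):
        subjects = marker_group(19, 10)
        rep = run_kfold(subjects, MarkerDetector(), SMALL_CFG, SMALL_SPEC,
                        k=3, seed=1, collector_params=np.zeros(3))
        assert sorted(rep.audit["fold_sizes"], reverse=True) == [7, 6, 6]
        seen = [n for fold in rep.audit["fold_subjects"] for n in fold]
        assert sorted(seen) == sorted(s.name for s in subjects)

    def test_pooled_counts_are_fold_sums(self):
        subjects = marker_group(6, 20)
        rep = run_kfold(subjects, MarkerDetector(), SMALL_CFG, SMALL_SPEC,
                        k=3, seed=2, collector_params=np.zeros(3))
        assert rep.pooled.tp == sum(s.match.tp for s in rep.splits)
        assert rep.pooled.fn == sum(s.match.fn for s in rep.splits)
        assert rep.pooled.fp == sum(s.match.fp for s in rep.splits)


class TestSubsampleApproximation:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_subsample_front_close_to_full_data_front(self, seed):
        """Training on the subsample loses little of the full-data max F1."""
        from spindleopt.protocol import select_collector
        train = make_subjects(2, 200 + 10 * seed, duration=600.0)
        det = get_detector("d2")
        cfg = MOEAConfig(pop_size=40, max_gen=40, seed=seed)
        spec = SubsampleSpec(target_total=600.0, seed=seed)
        collector = select_collector(train, det, cfg, spec)
        segments = build_subsample(train, det, collector, spec)
        sub_cache = CachedDetector(det, segments)
        train_cache = CachedDetector(det, train)
        from spindleopt.detectors import default_bounds
        sub_front = spea2_optimize(sub_cache.objective,
                                   default_bounds("d2"), cfg)
        full_front = spea2_optimize(train_cache.objective,
                                    default_bounds("d2"), cfg)

        def max_f1_on_train(front):
            return max(prf_metrics(train_cache.match_pooled(m.x))[2]
                       for m in front)

        assert max_f1_on_train(sub_front) >= \
            max_f1_on_train(full_front) - 0.05


class TestConfidenceInterval:
    def test_counts_reconstruction_from_printed_rates(self):
        assert counts_from_rates(0.697, 0.783, 5165) == (4044, 1121, 1758)

    def test_concentration_limit(self):
        lo, hi = f1_confidence_interval(10_000_000, 1, 1, seed=0)
        assert hi - lo < 1e-3

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            f1_confidence_interval(0, 0, 5)

    def test_quantiles_monotone_in_level(self):
        lo90, hi90 = f1_confidence_interval(40, 11, 17, level=0.90, seed=3)
        lo99, hi99 = f1_confidence_interval(40, 11, 17, level=0.99, seed=3)
        assert lo99 <= lo90 and hi90 <= hi99

    def test_doubling_draws_is_stable(self):
        tp, fn, fp = 4044, 1121, 1758
        a = f1_confidence_interval(tp, fn, fp, draws=10_000, seed=5)
        b = f1_confidence_interval(tp, fn, fp, draws=20_000, seed=6)
        assert abs(a[0] - b[0]) < 0.002 and abs(a[1] - b[1]) < 0.002

    def test_matches_quadrature_oracle_at_tiny_counts(self):
        """MC quantiles agree with numeric integration of the F1 law."""
        tp = fn = fp = 1
        # deterministic quadrature over the product Beta(2,2) x Beta(2,2)
        u = (np.arange(400) + 0.5) / 400
        w = sps.beta.pdf(u, 2, 2)
        w /= w.sum()
        P, R = np.meshgrid(u, u)
        W = np.outer(w, w).ravel()
        F = (2 * P * R / (P + R)).ravel()
        order = np.argsort(F)
        cum = np.cumsum(W[order])
        q_lo = F[order][np.searchsorted(cum, 0.025)]
        q_hi = F[order][np.searchsorted(cum, 0.975)]
        lo, hi = f1_confidence_interval(tp, fn, fp, draws=40_000, seed=7)
        assert abs(lo - q_lo) < 0.01 and abs(hi - q_hi) < 0.01
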