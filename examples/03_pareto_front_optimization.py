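"""Optimize a detector's operating parameters on the (FN, FP) Pareto front.

SPEA2 minimizes the two competing objectives — missed spindles (FN) and
false detections (FP) — over the RMS detector's 5-dimensional parameter box.
The resulting front is the complete trade-off curve; precision/recall and
the F1-curve are derived from it, and the maximal-F1 member is the natural
single operating point.
"""

import numpy as np

from spindleopt import (CachedDetector, MOEAConfig, SimulationConfig,
                        Subject, front_metrics, get_detector, simulate_psg,
                        spea2_optimize)
from spindleopt.detectors import default_bounds

# weaker spindles (8-25 uV) than the default conditions, so that no single
# parameter set is perfect and the front shows a real FN/FP trade-off
psg = simulate_psg(SimulationConfig(duration=600.0, seed=11,
                                    amp_range=(8.0, 25.0)))
subject = Subject(psg.recording, psg.stages, psg.events, "sim")

detector = get_detector("d2")
cache = CachedDetector(detector, [subject])  # preprocess once, detect often
cfg = MOEAConfig(pop_size=24, max_gen=20, seed=0)
front = spea2_optimize(cache.objective, default_bounds("d2"), cfg)

metrics = front_metrics(front, n_gold=cache.n_gold)
print(f"gold spindles: {cache.n_gold}; front size: {len(front)}")
for member, f1 in zip(front, metrics.f1_points):
    print(f"  FN={member.obj.fn:2d} FP={member.obj.fp:2d}  F1={f1:.3f}")
print(f"max-F1 operating point: F1={metrics.best_f1:.3f} at "
      f"x={np.round(metrics.best.x, 3)}")

# Each front member is a different FN/FP compromise; no member can improve
# one objective without worsening the other.
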