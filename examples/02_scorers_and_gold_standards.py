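"""Two simulated scorers and the gold standards built from them.

A sensitive scorer that marks true durations and a less precise scorer that
assigns every spindle a fixed 1-s duration annotate the same recording.
Their by-sample intersection (total agreement) and union (partial agreement)
form alternative gold standards, and detector rankings depend on which one
is used — the reason scoring should be gold-standard adaptive.
"""

from spindleopt import (SimulationConfig, apply_scorer_model, fuse_by_sample,
                        simulate_psg)

psg = simulate_psg(SimulationConfig(duration=600.0, seed=7))
scorer1 = apply_scorer_model(psg.truth, (45.0, "true_duration"), seed=1)
scorer2 = apply_scorer_model(psg.truth, (35.0, "fixed_1s"), seed=2)

inter = fuse_by_sample(scorer1, scorer2, mode="intersection")
union = fuse_by_sample(scorer1, scorer2, mode="union")

print(f"planted truth : {len(psg.truth):3d} spindles")
print(f"scorer 1      : {len(scorer1):3d} (threshold 45 uV, true durations)")
print(f"scorer 2      : {len(scorer2):3d} (threshold 35 uV, fixed 1 s)")
print(f"intersection  : {len(inter):3d} (events both scorers agree on)")
print(f"union         : {len(union):3d} (events either scorer marked)")

# The intersection is the strictest gold standard (fewest events), the union
# the most permissive; individual scorers lie in between.
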