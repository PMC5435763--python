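# spindleopt

Sleep-spindle detectors evaluated and tuned on Pareto fronts.

Sleep spindles are brief (≥ 0.5 s) bursts of 11–16 Hz ("sigma band") EEG
activity with a waxing-and-waning envelope, a defining feature of NREM stage
2 sleep and a biomarker of interest in aging, memory and neurological
disease. Automatic spindle detectors abound, but their reported performance
is notoriously inconsistent: expert gold standards disagree with each other,
and most comparisons evaluate each detector at a single, arbitrary operating
point. `spindleopt` is a library for people who study or build spindle
detectors and want evaluation that is *gold-standard adaptive*: instead of
one operating point, every detector is characterized by the full trade-off
curve between its two competing error types.

## The approach

A detector with operating parameters **x** produces, against a chosen gold
standard, a count of missed spindles FN(**x**) and false detections
FP(**x**). A detection D confirms a true spindle SS only when their overlap
rate (intersection over union)

```
R_ov = |SS ∩ D| / |SS ∪ D| > 0.2
```

exceeds 0.2, with one-to-one matching. Performance is the two-objective
minimization **F**(**x**) = (FN(**x**), FP(**x**)); its optimal solutions
form a Pareto front, from which precision P = TP/(TP+FP), recall
R = TP/(TP+FN) and

```
F_beta = (1 + beta^2) P R / (R + beta^2 P)
```

curves are derived uniquely. The front is found with SPEA2, a strength-
Pareto evolutionary algorithm with an external archive and nearest-neighbor
density estimation.

The package implements:

* **nine detectors** — band-pass + dual amplitude thresholds (d1), band-pass
  + moving RMS against the N2 standard deviation (d2) or an NREM percentile
  (d3), a Morlet-CWT top-10-scale probability estimate (d4), fuzzy-logic
  detectors on EMD intrinsic mode functions (d5) and on a rolling-ball
  high-frequency component (d6), and three sequential "double reading"
  hybrids (d7 = d6→d2, d8 = d2→d6, d9 = d4→d6) in which the second detector
  reviews only the first's candidates;
* **event-based scoring** — overlap-rate matching, P/R/F-beta, by-sample
  union/intersection gold-standard fusion, and expert-priority agreement
  sets for annotation pairs with fixed-duration scorers;
* **SPEA2 optimization** of each detector's published parameter box;
* **validation protocols** — a subsample builder (gold neighborhoods plus
  collector false positives, dilated 2.5 s and merged), hold-out with a
  single test evaluation, subject-level k-fold cross-validation, and
  Monte-Carlo F1 confidence intervals from Beta-distributed precision and
  recall;
* a **synthetic polysomnography generator** (1/f background, Hann-enveloped
  sigma bursts, K-complex-like confounders, two scorer models) so the whole
  pipeline runs and is tested without any recording downloads.

## Worked example

Optimizing the RMS detector (d2) on one synthetic recording with weak
spindles (`examples/03_pareto_front_optimization.py`):

```
gold spindles: 23; front size: 3
  FN= 0 FP= 4  F1=0.850
  FN= 1 FP= 2  F1=0.936
  FN= 6 FP= 0  F1=0.920
max-F1 operating point: F1=0.936 at x=[0.412 0.293 1.153 0.8   2.061]
```

Each front member is a different compromise — find everything but accept 4
false alarms, or miss 6 spindles and report none. No member can improve one
objective without worsening the other; the maximal-F1 member (here FN=1,
FP=2: RMS resolution 0.41 s, window 0.29 s, threshold 1.15 × σ_N2, duration
gate [0.8, 2.06] s) is the natural single operating point.

Uncertainty of a published operating point
(`examples/05_f1_confidence_interval.py`):

```
reconstructed counts: TP=4044 FN=1121 FP=1758
point estimate      : F1 = 0.738
95% CI              : [0.729, 0.745]
```

With precision ~ Beta(TP+1, FP+1) and recall ~ Beta(TP+1, FN+1), 10,000
Monte-Carlo draws give the central 95% band of the F1 distribution — a
held-out score below the band indicates genuine overfitting rather than
sampling noise.

The other `examples/` scripts cover simulation + detection, scorer models
and gold-standard fusion, and hold-out validation end to end. A thin CLI
(`spindleopt simulate|detect|score|optimize|cv|ci`) wraps the same
functions for shell use.

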