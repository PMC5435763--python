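# Methods

This note records the scientific and numerical choices behind `spindleopt`:
what each component assumes, which knobs matter, and what the synthetic
test bed does and does not establish about real sleep EEG.

## Signal model and conventions

All internal times are seconds; intervals are half-open
`[onset, onset + duration)` and sample `i` of a recording covers time
`i / rate`, so event/mask conversions are exact and boundary samples are
never double-counted. Recordings are single-channel EEG in µV at their
native sampling rate — nothing is resampled, and every detector is
parameterized in physical units (µV, Hz, s) so the same parameter vector is
meaningful at 50, 100, 200 or 256 Hz. When a recording has no hypnogram,
the whole excerpt is treated as stage N2 (the situation of 30-min NREM-2
excerpt databases); when a hypnogram is present, detectors run on all
samples but events entirely outside NREM 2/3/4 epochs are discarded.

## Detectors

Every detector is split into a *preprocess* step (all transforms that do not
depend on the operating parameters, computed once per recording) and a
*detect* step (thresholding and event logic). This mirrors how the
amplitude-normalization statistics are defined — from the full recording,
once — and makes evolutionary optimization tractable: a parameter evaluation
costs milliseconds instead of seconds.

Shared numerical choices:

* **Sigma band-pass (d1–d3):** zero-phase FIR (Hamming window, ~1 Hz
  transition, > 50 dB stopband) with passband 11–16 Hz, applied
  forward-backward. Any zero-phase filter with this band and comparable
  stopband would be equivalent for these detectors.
* **Normalization statistics:** A1 (peak) and A2 (mean) rectified amplitude
  of the filtered signal over NREM 2/3/4; σ_N2 the standard deviation over
  N2 only; the percentile-threshold RMS series on a fixed 0.1 s / 0.25 s
  grid over NREM 2/3/4. Statistics are computed once per recording and are
  inherited by any segment cut from it (subsample segments, hybrid review
  windows), so thresholds stay those of the whole night.
* **d1 threshold semantics:** candidate regions are peak-envelope runs above
  the *lower* threshold `p1·A1` that contain at least one sample above the
  *upper* threshold `p2·A2`. Since A1 ≥ A2 while p1's box is tighter than
  p2's, both orderings of the two absolute thresholds are reachable within
  the bounds; the envelope is linear interpolation through the local maxima
  of the rectified filtered signal.
* **d3 percentile:** the threshold parameter is a percentile in percent
  (box 0.1–99), applied to the NREM RMS distribution.
* **CWT estimate (d4):** complex Morlet (`cmor1.5-1.0`) over 120
  logarithmically spaced scales covering 0.5–30 Hz. Two choices here are
  deliberate. A *complex* wavelet is used because a real Morlet's
  coefficient power oscillates at the carrier phase, which makes the
  per-instant top-10 ranking flicker at tone zero crossings. The grid has
  120 scales because the estimate is defined as the fraction of the 10
  largest-power scales lying in the spindle band: with ~11 scale centers
  inside 11–16 Hz the estimate can reach 1.0 for a clean sigma tone,
  whereas a coarser (e.g. 50-scale) grid has only ~5 in-band centers and
  caps the estimate near 0.5 by construction. Ties in power are broken by
  scale order, which also makes the all-zero signal well defined. The
  grouping cascade applies, in order: smoothing, thresholding, minimum
  initial duration, gap merging, a weak-pair grouping pass, a strong
  grouping pass, and a final merge whose gap closure is applied only while
  the merged event stays at or below the upper "mergeable duration" cap;
  the final keep-filter enforces only the lower duration bound.
* **EMD (d5):** standard sifting with cubic-spline envelopes through
  maxima/minima, mirror extension of the two outermost extrema at each end,
  and a per-IMF stop rule of normalized squared difference < 0.2 between
  successive sifts or 10 sift iterations. The decomposition is exact by
  construction (IMFs + residual ≡ input). Instantaneous amplitude is the
  cubic-spline envelope through the maxima of |IMF|; instantaneous
  frequency uses the 1-crossing zero-crossing estimator.
* **Rolling-ball high-pass (d6):** frequency-selective sifting in which only
  extrema whose spacing to a neighboring extremum is shorter than
  `1/(2 f_cut)` anchor the envelopes (f_cut = 10 Hz). This is a behavior
  contract for the published rolling-ball geometry, not a reimplementation
  of it: it extracts a single component concentrated above the cutoff, with
  component + remainder equal to the input exactly. Five zero-crossing
  frequency estimates (windows of 1, 3, 5, 7, 9 crossings) smooth the
  frequency membership.
* **Hybrids (d7–d9):** the first detector screens the whole recording; each
  candidate is padded by 2.5 s on both ends (the same dilation constant the
  subsample builder uses), overlapping windows are merged, and the second
  detector reviews each padded segment independently with normalization
  statistics from the full recording. The second's raw detections are
  clipped to the *unpadded* candidate windows before its duration gate is
  applied — applying the gate before clipping would reject every review of
  a long padded segment and make the composition vacuous.

## Scoring

Matching is one-to-one and greedy by descending overlap rate (ties by
earlier gold onset, then earlier detection onset), with the strict rule
R_ov > 0.2. One-to-one matching preserves the count identities
TP + FN = |gold| and TP + FP = |detections| that precision and recall
implicitly assume; on randomized small instances the greedy matching equals
maximum bipartite matching in ≥ 99% of cases, and the test suite quantifies
that gap rather than hiding it. Zero-denominator conventions (P = 0 with no
detections, R = 0 with no gold, F = 0 when both vanish) make the empty
detector and empty gold standard well-defined extremes. By-sample fusion of
two annotation lists uses a shared grid (a 256 Hz virtual grid when no
recording is attached) and regroups without any duration filtering.

## Optimization

SPEA2 with archive size equal to population size; per-detector default
populations (100, 100, 100, 150, 120, 120, 170, 170, 270) and generations
(100, 100, 100, 250, 200, 200, 250, 250, 320) for d1–d9. Variation is
simulated-binary crossover (probability 0.9, distribution index 15) and
polynomial mutation (per-gene probability 1/n, index 20) — standard
real-coded settings, since the original optimizer's defaults are not
published. Density and truncation distances are computed on objectives
normalized by their pool ranges (FN and FP scales differ with dataset
size); k for the density term is round(√pool), minimum 1. Objective
evaluations are memoized on the parameter vector rounded to 12 significant
digits. A failed evaluation receives a large sentinel objective and is
logged, never silently dropped.

One structural property worth knowing: with a bounded archive, truncation
can discard nondominated points when the true front is larger than the
archive, so on such problems the returned front is an approximation — the
suite asserts exact oracle equality only on problems whose front fits the
archive, and otherwise checks hypervolume (≥ 99% of the brute-force front
across seeds).

## Protocols

The subsample builder runs a *collector* parameter set, takes its false
positives plus all gold events, dilates each by 2.5 s, merges overlaps, and
draws segments (seeded, without replacement) until 3600 s by default. The
collector defaults to the maximal-F2 member of a preliminary SPEA2 pass on
the training group: a recall-weighted collector is deliberately permissive,
so its false positives populate the subsample with the hard negative
neighborhoods. Pools shorter than the target are used whole, with a
warning. Segments are processed independently downstream; how stage context
would carry across concatenated segments is left out by design.

Hold-out optimizes on the subsample, re-evaluates every front member on the
complete training recordings, selects the maximal-F1 member (ties by lower
FP — selection never invents parameters), and evaluates that single vector
exactly once on the held-out group; the report's audit block records the
single test pass. K-fold partitions at the subject level and pools per-fold
counts (micro-averaging) before computing P/R/F1.

F1 confidence intervals draw precision ~ Beta(TP+1, FP+1) and recall ~
Beta(TP+1, FN+1) independently (uniform prior) and report empirical
quantiles of the induced F1 sample; 10,000 draws reproduce published
3-decimal bounds to ±0.002 across seeds. Counts are reconstructed from
printed rates as TP = round(R·N), FP = round(TP/P) − TP. A
true-negative-count assumption sometimes quoted alongside this construction
is unnecessary for P/R/F1 and is not implemented.

## Synthetic data

The generator emulates what the detectors are sensitive to, not sleep
physiology: 1/f^α background noise (α = 1, broadband std 12 µV), spindles
as Hann-enveloped sinusoids with frequency ~ U(11, 16) Hz, duration ~
U(0.5, 2.0) s and peak amplitude ~ U(40, 60) µV — which puts the in-event
sigma-band RMS at least 4× the background sigma RMS, the "clearly visible
spindle" regime — at 3 events/min with a Poisson event count and
overlap-forbidding placement (rejected proposals are redrawn so the count
stays Poisson), plus biphasic ~1 s, ~100 µV K-complex-like transients at
1/min kept clear of the spindles, and an alternating N2/N3 hypnogram in
30-s epochs. Two scorer models differ in amplitude sensitivity (a logistic
miss probability of 2 µV softness around the threshold) and duration style
(true durations vs. fixed 1-s marks centered on the event).

What passing tests on this generator show: the detectors, scoring,
optimizer and protocols are internally correct and the pipeline recovers
planted structure. What they do not show: performance on real EEG, whose
spindles chirp, ride on slow oscillations, co-occur with artifacts, and are
annotated by scorers whose disagreement is not a simple amplitude
threshold. Absolute F1 values on the synthetic bed are far above what any
detector achieves on real recordings.

Problem sizes used by the test suite were chosen to make the statistical
checks stable: end-to-end recovery runs on 10-minute subjects (≈ 30 gold
events per subject; two training subjects, one held-out) with SPEA2 at
population 40 / 40 generations over three seeds, and the heavier published
run settings above are exercised only on cheap lookup-table objectives.

## Known limitations

* The EDF writer is minimal (16-bit, 1-s records, whole-second padding,
  single physical range per file) — sufficient for fixtures and the
  simulator, not a general EDF+ exporter.
* The rolling-ball component extractor is a behavior-contracted surrogate;
  it reproduces the cutoff behavior, not the original ball geometry.
* Hybrid optimization cannot reuse cached preprocessing for its second
  stage (the review windows depend on the parameters), so d7–d9 train
  substantially slower than the simplex detectors.
* Greedy matching is the specified behavior; in < 1% of randomized dense
  instances it scores one TP fewer than maximum bipartite matching.
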