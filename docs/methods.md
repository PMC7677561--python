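# Methods

## Model and assumptions

The package analyzes timestamped detection-event streams from a
continuously sampling in vivo flow cytometer.  Its central modelling
assumption is the *equivalent blood sample*: because the instrument
interrogates a fixed volumetric blood flow, the event count in a scan
interval of length `w` seconds is treated as the count that a drawn
blood sample of volume `w/60 × sampling_rate` would have contained, with
no dilution or mixing correction.  Volumes in μl are canonical; the
%-of-PBV labels (1/5/10/20% for 24 s / 2 min / 4 min / 8 min at the
defaults) are display-only and never enter a computation, so the results
are insensitive to the exact PBV.

Default constants: blood sampling rate 50 μl/min, peripheral blood
volume 2.0 ml (adult mouse, ~25 g).  Both are `ScanConfig` fields and
can be changed per analysis.

The null model throughout is the homogeneous Poisson process: cells well
mixed in blood, mean number steady on the scan timescale.  Departures
are modelled as piecewise-constant-rate processes (change-point and
Markov-modulated streams) and as scan-level rate multipliers (24-h
sessions).

## Synthetic stream generators

All generators realize piecewise-constant-rate point processes by
exponential inter-arrival sampling; the memoryless property makes
restarting the clock at every rate change exact, so no thinning is
needed.  Randomness flows through `numpy.random.Generator`; batteries
spawn one child seed per stream from a master seed
(`SeedSequence.spawn`) in a fixed order, so any replicate is
reproducible in isolation and identical specs (including seed)
reproduce output bit-for-bit.

The default battery emulates the simulated study designs this kind of
experiment uses:

* 54 homogeneous 35-min streams with rates log-spaced across
  0.6–19.6 events/min — the envelope of the abundant-CTC cohort.  The
  exact per-stream rates of such designs are typically not published;
  the log-spaced grid reproduces the stated envelope with even coverage
  per decade.
* 54 change-point streams: rate `r` for the first 17.5 min, `2r` for the
  second 17.5 min (same rate grid).  Pooled window counts are then a
  50/50 mixture of Poissons with means μ₁ = rw, μ₂ = 2rw, whose
  variance-to-mean ratio is `1 + (μ₂−μ₁)²/(2(μ₁+μ₂))` — the closed form
  the tests check against brute-force pmf mixing.
* 54 merged streams: the union of independent streams at `r` and `2r`.
  By the superposition theorem this is Poisson at `3r`; the battery
  exists to show superposition does *not* create overdispersion.
* 14 diurnal sessions: four 50-min scans at 6-h spacing, each
  homogeneous at `base_rate × multiplier`.  The multiplier law is a
  modelling choice (real within-day kinetics are unknown): log-uniform
  on (0.1, 10) by default, which makes session max/min mean-rate ratios
  span roughly 3–100 across a 14-session battery — order-of-magnitude
  within-day variability with occasional extremes, without committing to
  a circadian phase.  Session base rates reuse the 0.6–19.6 grid.
* A two-state Markov-modulated ("high/low shedding") generator with
  exponential dwell times, stationary initial state, long-run rate equal
  to the dwell-weighted average.  It is provided as the mechanistic
  counterpart of the change-point stream; no likelihood fitting of such
  models is attempted.

What the generators do *not* emulate: detection efficiency and optical
noise (streams are true event times, not fluorescence peaks), cell
clusters, within-scan rate drift other than a single jump, correlations
between scans of a session beyond the shared multiplier, and operator
repositioning variability.  Passing tests therefore demonstrate the
statistical machinery on known point-process structures, not fidelity to
any particular animal dataset.

## Interval counting

Windows are half-open `[t, t+w)` with starts `t = 0, s, 2s, …` while
`t + w ≤ duration`; the trailing partial window is discarded (a
fixed-size blood sample is all or nothing) and an event exactly at
`t + w` belongs to the next window, which makes the non-overlapping
conservation invariant exact.  Sliding mode defaults to a 1-s stride —
effectively "all possible intervals"; results are insensitive to finer
strides because the counts change only at event times.  Counting is two
`searchsorted` calls; an O(n·m) recount is kept in the tests as the
oracle.

Cohort inclusion mirrors the two standard definitions: `any_detection`
(≥ 1 event in the scan) and `min_rate` (scan mean strictly above
0.5 events/min).

## DFSM and Poisson references

`DFSM_i = |C_i − λ|/λ × 100` with λ the scan mean per window; it is
undefined (error) for λ ≤ 0.  Threshold fractions use an inclusive
comparison with a 1e-9 absolute guard against float noise at exact
rational boundaries.  The Poisson reference fraction sums the pmf over
the integers within the band `|k − λ| ≤ λ·t/100` (enumeration, via the
Poisson CDF); a Monte-Carlo cross-check at λ ∈ {1, 5, 20} is part of the
suite.  25% and 50% thresholds are the defaults because errors of that
size straddle the integer count differences used in prognostic cutoffs.

## Variance-to-mean analysis and the overlap correction

Each scan contributes one (mean, variance) point per window size; the
zero-intercept least-squares slope `Σmᵢvᵢ/Σmᵢ²` across scans is the
dispersion summary (1 = Poisson).

The plain n−1 sample variance of *overlapping* window counts is biased
low, and materially so when the window is a sizeable fraction of the
scan: neighbouring counts share events, and for a stationary stream with
stride `s`, lag-`d` correlation is `max(0, 1 − ds/w)`, giving

    E[S²] = σ² · (n/(n−1)) · (1 − g/n),
    g = 1 + 2 Σ_{d≥1} (1 − d/n) · max(0, 1 − ds/w).

For 8-min windows in a 35-min scan this factor is ≈ 0.70 — left
uncorrected it drags variance-mean slopes of genuinely Poisson data to
~0.7.  `variance_mean_point` therefore divides the sliding-window sample
variance by this factor by default ("auto": applied in sliding mode
only; raw values remain available).  The factor → 1 as `w/duration → 0`,
recovering the standard result that the sliding variance converges to
the non-overlapping variance on long streams — itself a tested property.

Even unbiased, a single scan's variance estimate at the largest window
rests on only ~4.4 window-lengths of data, so a single 54-stream
battery's slope carries sampling noise of roughly ±0.05 (24 s) to ±0.11
(8 min), concentrated by the m²-weighting in the few highest-rate
streams.  Where a test asserts the *design's* slope (equidispersion
recovery within [0.9, 1.1]), it therefore averages the slope over 20
replicated batteries, which brings the standard error to ~0.025;
per-battery conditions are untouched.  Directional assertions
(change-point slope > 1) do not need replication — the expected slope
there is far from 1 (e.g. ≈ 2 at 24-s windows, growing with window
size).

## Ratio metrics and group comparison

Within-day variability is summarized as max/min of the four scan mean
rates per session; within-scan variability as the max/min of the
first-15-min and last-15-min rates of a ≥ 35-min scan (5-min guard gap).
A zero minimum yields a flagged infinite ratio rather than a silent one;
an optional floor substitution is available, and the pipeline excludes
non-finite ratios from the KS comparison while counting them.  The
two-sample KS test is SciPy's, with the asymptotic p-value — what
standard tools report at these group sizes (6–54).

## Sampling strategies

A strategy draws `n` samples of window `w` with pairwise separation
≥ 6 h.  Separation is measured at scan granularity (different scans:
difference of scan clock starts; same scan: offset difference), matching
the intent of "samples at least 6 h apart" on sessions whose scans are
6 h apart — one sample per scan.  The estimate is the mean of per-sample
counts (all samples of a strategy share one window, so no rescaling is
needed); the reference is the session's pooled events over pooled
scanned time, expressed per window of the strategy's size.  Accuracy is
the fraction of draws with DFSM ≤ 25%.

Exhaustive enumeration over an offset grid (default stride = one window)
is the deterministic default; for multi-sample strategies over fine
grids the draw space explodes combinatorially, so a seeded random mode
(`n_draws` draws) is provided and used by the pipeline's standard grid
(1%, 2%, two 1%, 4%, four 1%, 20%, 80%, four 20% of the PBV).  Single
large samples must fit inside one scan (an 80%-PBV draw is 32 min of a
50-min scan); straddling scans is not allowed.

## Numerical and interface choices

* Sample variances use the n−1 divisor throughout.
* Window-start grids are built from integer multiples of the stride with
  a 1e-9 guard, never by accumulating floats.
* Event-series files are CSV (`scan_id,time_s`) plus a JSON sidecar
  (duration, label, metadata); timestamps are written at 17 significant
  digits and parsed with pandas' round-trip float precision, so the pair
  round-trips losslessly.
* Duplicate timestamps are legal (two cells within one clock tick) but
  logged; timestamps outside `[0, duration)` are rejected with the
  offending value named.
* The analysis summary JSON carries a `schema_version`; the report
  renderer is a pure function of the summary, so regeneration is
  byte-identical.

## Problem sizes

The shipped analyses and tests run on the default battery sizes (3 × 54
streams of 35 min, 14 sessions of 4 × 50 min), 20-battery replication
for the equidispersion check, 100–300 replicates for Monte-Carlo
oracles, and 100-draw strategy evaluations — a few minutes end to end on
one CPU.

## Known limitations

* The DFSM reference λ is the realized scan mean, not the true rate;
  at very low rates (λ → 0) the statistic is undefined and such scans
  are excluded by the inclusion rules.
* The overlap correction assumes stationarity within the scan; for
  change-point streams the corrected sliding variance is only
  approximately calibrated (the overdispersion conclusions there are
  directional and large, and the mixture-variance oracle uses
  non-overlapping windows).
* KS p-values are asymptotic; at the smallest group sizes they are
  approximate, as with standard tools.
* Strategy accuracy compares estimates with the session's own pooled
  mean, so it measures sampling error, not biological ground truth.
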