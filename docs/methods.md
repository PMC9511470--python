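# Methods

## Signal model and preprocessing

The package operates on uniformly sampled SaO2 series (percent, 1 Hz or
0.1 Hz).  Preprocessing runs clip → filter → resample:

1. **Dropout removal.** Readings below a physiological floor (default
   75%), non-finite or non-positive readings are treated as sensor
   dropouts and linearly interpolated between the nearest valid
   neighbours.  Invalid runs touching a record boundary are filled by
   nearest-valid constant extension — extrapolating a trend into a gap at
   the boundary would invent structure the recurrence stage could pick
   up.  The operation is idempotent and records which samples were
   filled.
2. **Low-pass filtering.** A 4th-order Butterworth with 0.25 Hz cutoff,
   applied forward–backward (zero phase).  Only the cutoff is a
   physiologically meaningful parameter (desaturation dynamics live well
   below 0.25 Hz); the family/order is a design choice — Butterworth for
   a maximally flat passband, zero-phase application so event timestamps
   are not shifted by filter delay.
3. **Resampling.** Optional decimation by non-overlapping block
   averaging (default 10 s → 0.1 Hz).  A trailing partial block is
   dropped rather than averaged: deterministic output length, and no
   final sample with different noise variance.  Filtering precedes
   decimation, so it doubles as an anti-alias stage.

## Recurrence analysis

Recurrence is evaluated on the raw scalar samples — no phase-space
embedding (dimension 1, no delay), matching the definition applied to
x(t_i) directly.  The distance is the absolute difference, Θ(0) = 1
(a pair at exactly the threshold counts as recurrent), and a Theiler
band of 1 excludes only the line of identity, which would otherwise add
an artificial length-N line to every histogram.

`det_curve` evaluates DET on a grid of 100 thresholds spanning 0 to the
segment's maximum pairwise distance, with a spacing floor of 0.01
percentage points (finer grids would sample measurement noise).  The
implementation avoids building N×N matrices per threshold: for every
diagonal offset the distance profile |x_{i+k} − x_i| is computed once,
and a sliding max followed by a sliding min (a morphological closing of
width l_min) yields, per cell, the smallest ε at which that cell joins a
fully recurrent run of length ≥ l_min.  Sorting those two profiles turns
the whole DET curve into a pair of binary searches per threshold.  The
literal route (recurrence matrix → diagonal histogram → determinism) is
also provided and the test suite asserts the two agree everywhere; a
third, independent per-diagonal run enumeration serves as the oracle.

ε_opt is the grid point maximising the finite-difference derivative of
DET (central differences in the interior, one-sided at the ends), ties
resolved toward the smallest ε, no curve smoothing by default.  Windows
with a flat DET curve (constant signal) or an empty histogram are
flagged degenerate and excluded from downstream distributions instead of
being assigned a value.

l_min spans roughly 10 s of signal: 10 samples at 1 Hz, 2 at 0.1 Hz
(`l_min_for_fs`).  ε_opt is reported in raw SaO2 percentage points; the
reference class boundaries 0.33 / 0.73 are in those units and should be
re-derived (Jenks) for other geometries, sampling rates or l_min.

## Rolling windows

Windows are [start, start + W) on the sample grid, starting at 0, S,
2S, …; the final window is anchored to end exactly at the record end,
deduplicated when N − W already lies on the step lattice.  Every sample
is therefore covered whenever S ≤ W.  5-min/1-min geometry is used for
segment distributions and classification, 10-min/1-min for comparison
against the desaturation density.

## Desaturation metrics

The baseline is the mean of the first 3 minutes, held fixed.  A
desaturation is a maximal run strictly below (baseline − N) percentage
points (N = 3 by default) lasting between 10 and 60 s inclusive,
timestamped at its first sample; runs outside the duration band are
discarded, and a sample exactly at the threshold terminates a run
("falls below" is strict).  ODI divides the event count by hours of
sleep (or record).  ODD at time t counts events timestamped in
(t − 600 s, t], evaluated on the rolling-window end grid so the two
series align point for point.  At 0.1 Hz the 10-s minimum duration is a
single sample — the detector has very little to work with at low rates,
which is exactly the fragility the recurrence biomarker sidesteps.

## Classing and screening

Jenks natural breaks (exact O(k n²) dynamic programming over the sorted
values; a break is the midpoint between adjacent class extremes)
partitions a corpus of ε_opt values into the no / maybe / with IHHOP
regions.  Severity labels come from the ODD: the 10-min count × 6 is an
hourly rate cut at 5 / 15 / 30 events/h (healthy / mild / moderate /
severe; boundary rates go to the higher class — the ×6 conversion is an
interpretation that makes the hourly cut-offs applicable to 10-min
counts).  Three nested binarisation schemes (>Mild, >Moderate, >Severe)
produce with/without-SAS labels.

The screening harness z-scores the feature (per-segment ε_opt) on the
training split only, fits AdaBoost, LDA and a random forest with library
defaults, and evaluates ROC/AUC on a held-out 30% stratified split.
Segments — not patients — are the classification unit, so segments of
one recording may appear in both splits.  The operating point maximises
the Euclidean distance from (FPR = 1, TPR = 0); sensitivity,
specificity, PPV and NPV are reported there.  All stochastic steps are
seeded and bit-reproducible.

## Synthetic data

The generator emulates intradialytic oximetry: a per-record baseline
drawn from Normal(94.3, 2.1)%, a slow two-sinusoid drift (±0.5%, ~30-min
scale), white measurement noise (sd 0.3%), and episodes of repetitive
sawtooth desaturation trains — per-cycle depth uniform in 3–10
percentage points, per-cycle period uniform in 30–90 s, slow fall (75%
of the cycle) and fast recovery.  A smooth AR(1) relative amplitude
modulation (sd 0.25, correlation time 8 s) makes the trains irregular:
obstructed-breathing desaturations are not clean ramps, and a purely
periodic train would be a deterministic signal — the regime the
recurrence biomarker maps to *small* ε_opt, the opposite of the
intermittent phenotype being emulated.  Isolated rectangular
desaturations are also available.  Depth and baseline are independent,
so episodes that never cross 90% are generatable.  All randomness flows
from one master seed through SeedSequence spawning.

What the generator does **not** model: motion/perfusion artifacts,
device quantisation, heart-rate coupling, genuine sleep architecture,
and any physiological gas-exchange dynamics.  Passing tests show the
method behaves as designed on signals with these statistics; they are
not clinical validation.

## Problem sizes and numerical choices

The screening study runs on 1200 five-minute 1-Hz segments (half with
episodes) and the correlation study on ten 3-hour sessions with 3–5
episodes of 10–20 min each — corpus sizes chosen to mirror the scale of
an event-level screening study (a few dozen multi-hour recordings cut
into five-minute segments) while keeping a full run around a minute.  Episode placement leaves the first 10 minutes clean so the
3-min baseline is well defined, mirroring recordings where patients fall
asleep after treatment onset.  "Episode-containing periods" for the
correlation are windows within one window-length (600 s) of an injected
episode — the synthetic surrogate of restricting to reported-sleep
periods, which include quiet stretches between events.

## Known limitations

- Windows straddling an episode boundary take their ε_opt from the
  dominant clean regime (the sharpest DET rise is at the clean-noise
  scale), while the ODD counts the partial events; this deflates the
  ε_opt–ODD correlation relative to sessions with long homogeneous
  sleep, and is the main reason the synthetic correlation sits near,
  rather than above, 0.7.
- ε_opt values scale with the signal units; the 0.33 / 0.73 reference
  boundaries do not transfer to normalised or rescaled segments.
- The exact Jenks DP is quadratic in n; at n ≈ 10⁴ it takes seconds and
  beyond that a sampling of the corpus is advisable.
- DET of a constant segment is 1 only up to the corner diagonals shorter
  than l_min (e.g. 378/380 for N = 20, l_min = 2); such segments are
  flagged degenerate rather than interpreted.
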