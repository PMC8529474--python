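# Methods

## The estimation problem

A wrist accelerometer sampled at a fixed rate (the package supports any
fixed rate with an integer number of samples per minute; 10 Hz is used
throughout the tests, and 20/30 Hz devices are typical) records linear
acceleration on three axes, always superimposed on the Earth's gravity
projection. Sleep appears as an extended episode of strongly reduced
fluctuation; non-wear appears as a nearly flat trace. The pipeline's job
is to locate, for each analysis day, the single longest continuous
low-activity episode of at least 100 minutes (the major Sleep Episode),
plus the surrounding bedrest interval, after removing non-wear minutes.
Days run from 6 PM to 6 PM so that the night sits mid-window; minute slot
`k` covers the half-open clock minute starting at 18:00 + `k` (half-open
intervals avoid double counting at boundaries).

## Stage-by-stage model and parameter choices

**Minute presence.** A minute slot is *present* when ≥ 80% of its
expected samples exist (`present_fraction`). This tolerates clock jitter
at recording edges and watch changes without inventing data; the exact
sub-minute behaviour at watch changes is a convention of this package.

**Non-wear.** Per-axis within-minute population SDs are smoothed by a
150-minute forward-and-backward moving window and the RMS of the three
smoothed values is compared *strictly below* a fixed 0.0185 g threshold
("below" is read as strict; the boundary value stays on-wrist). Two
choices here were genuinely open:

- *SD vs variance units.* The threshold is of SD magnitude for a device
  reporting in g, so the RMS is applied to the smoothed SDs by default;
  `nonwear_square=True` squares them (true variances) first.
- *Combining the two one-sided means.* The default for detection is the
  **minimum** of the backward and forward 150-minute means: a minute is
  non-wear when *either* its past or its future window is flat. The
  arithmetic-mean combination (available as `nonwear_combine="mean"`, and
  the default of the standalone `fb_moving_average` smoother) requires
  both windows to lie mostly inside the flat segment, so no minute of a
  segment shorter than ~2 windows (~300 min) can ever be flagged and each
  edge loses up to ~45–110 minutes at realistic wake SDs; the minimum
  variant detects segments down to roughly the window length at the cost
  of flagging a modest margin (~20–50 min) of quiet minutes adjacent to a
  flat segment — a conservative trade for sleep estimation, since
  over-flagging near non-wear removes ambiguous minutes rather than
  inventing sleep.

**Activity scoring.** Each present, on-wrist minute's power is the area
under its Welch power density spectrum: Hann window, 50% overlap,
per-segment mean removal, segment length `min(256, n/2)` samples — capped
at half the minute so at least three half-overlapping segments exist at
any rate (256 at the study rates). The zero-frequency bin is excluded
from the trapezoidal integral, which removes the constant gravity
component without any explicit calibration; for band-limited signals the
result approximates the within-minute variance (a pure sine of amplitude
A yields A²/2; white noise yields σ²; a constant minute yields exactly
0). Axis powers combine as `sqrt((Px²+Py²+Pz²)/3)`. Only the *relative*
position of a minute in the participant's own power distribution matters
downstream, so Welch settings affect precision, not scale.

**Thresholds and classes.** The 15-minute centered moving mean of the
combined power is pooled over all valid minutes of the whole study, and
the within-individual 10/25/50/75th empirical percentiles (linear
interpolation) cut it into five bands A0 (< p10) .. A4 (≥ p75). Bands are
left-closed at the lower edge — an unstated boundary fixed for
determinism. Both thresholding and classification use the same smoothed
series by default, which keeps the band proportions exact by
construction; `classify_on="raw"` classifies raw minute powers instead.
Thresholds require ≥ 1000 valid minutes (explicitly lowerable) because
tail percentiles of a short pooled distribution are unstable.

**Sleep scores and episode detection.** A0/A1 → +1, A2 → 0, A3 → −0.75,
A4 → −1. The two published penalty values are assigned monotonically
(heavier penalty for the higher band); the middle band is neutral because
the definitions leave it unassigned. Missing/wrist-off minutes contribute
nothing to any window mean (denominators count present minutes only).
Two sweep cut-offs are not published and were calibrated once on the
synthetic generator, before the acceptance measurements were frozen:

- seed threshold 0.5 on the 100-minute centered mean (a window must be
  majority-sleep-scored to seed an episode);
- edge threshold 0.0 on the 60-minute centered mean. The refinement edge
  lands where the local score balance crosses this value; with sleep
  minutes averaging ≈ +0.76 (not all sleep minutes fall below p25 when
  sleep occupies more than a quarter of the day) and wake minutes
  ≈ −0.65, a cut-off of 0.5 would sit ~19 minutes inside the true
  boundary, while 0 is the unbiased balance point.

Clean-up follows the printed constants exactly: neighbours connect when
every 90-minute window spanning their gap holds more than three-quarters
(> 67.5) minutes scored +1, then gaps ≤ 22.5 minutes join
unconditionally. The longest candidate ≥ 100 minutes wins (ties break to
the earlier start — determinism); the rest are naps. Expansion crawls
over contiguous A0/A1 minutes, clamped by a button press when one lies
within 60 minutes of the provisional bound (the nearest such press);
bedrest extends over contiguous A0–A2 minutes and never crosses another
candidate. Expansion uses the smoothed classification series, consistent
with the class definitions. An episode with > 25% missing minutes is
flagged low-confidence for QC.

**Metrics.** Equality at the 40th-percentile immobility cut goes to
*active* (the printed definitions say "higher than" / "lower than",
leaving the boundary unassigned). Light counts strictly above 1 lux.
Bouts merge runs separated by at most the 1-minute tolerance. The STRI
denominator is all 1440 minutes (agreement on both sleep and wake), per
the "24-hour sleep and wake minutes" description; the alternative
sleep-only overlap reading is available via `stri_denominator="sleep"`.
The average-day mask is the D highest-frequency slots (ties to the
earlier slot) and is *not* forced contiguous; D is the rounded mean
duration because a mask cardinality must be integral. The 14-day
backward smoothing is missing when more than 3 window days are missing —
reconciling the two adjacent printed phrasings of the tolerance — and
days before the start of the series count as missing, so the first
`window − 1 − max_missing` days of any series are undefined.

**Time zones and DST.** Correction is a pure clock relabeling per day
from a config-supplied itinerary (GPS inference is out of scope); travel
days and each DST transition night become missing data, and durations of
retained days are conserved by construction. All per-day metrics are
meant to be read after this correction.

## The synthetic generator

`actisleep.synthetic` emulates exactly the features the pipeline keys
on: each sample is a constant gravity projection plus independent
zero-mean Gaussian noise whose SD follows the minute's behavioural state.
Defaults (per axis): wake 0.05 g, sleep and naps 0.03 g, arousals 0.05 g,
non-wear 0.002 g — sleep fluctuation sits well above the 0.0185 g
wrist-off threshold and the ordering non-wear < sleep < wake is enforced.
The regular profile sleeps ~23:30–07:30 with ~20-min onset jitter and two
brief (3–10 min) arousals per night, takes a 45–70-min afternoon nap
every third day, and leaves the watch off for a 4–4.5-h daytime block
every fifth day. Button presses appear within ±20 minutes of the true
bounds with 85% compliance, matching reported real-world compliance
levels. The light channel is bright (50–300 lux) in wake and dark
(0.1 lux) in sleep, with a configurable violation rate; phone lock/unlock
sessions are confined to true wakefulness unless violations are
requested.

What this deliberately does **not** emulate: heterogeneous wake activity
(commuting vs desk work), gradual wake/sleep transitions, periodic limb
movements, device drift, or temperature-coupled non-wear. Passing tests
therefore demonstrate that the chain recovers its targets when the
signal-variance model holds, not that it handles every messy real-world
recording; in particular the ~7-minute inward bias of the recovered
bounds (from the 15-minute smoothing of a step change in power) is a
property of sharp synthetic transitions and is within the 10-minute
recovery tolerance used throughout.

## Problem sizes and numerical conventions

Tests and the acceptance script use 30-day studies at 10 Hz (the
generator's test-default rate; the pipeline is rate-agnostic given a
fixed known rate), which the full chain processes in well under a minute.
Percentiles use NumPy linear interpolation; window means are cumulative-
sum based and exactly match their brute-force definitions; per-minute SDs
are population (ddof 0) SDs; all-missing windows produce missing output;
a constant minute short-circuits to exactly zero power so the zero-
variance case is representable without rounding noise.

## Known limitations

- A single major episode per day is assumed; heavily polyphasic sleep is
  flagged (no-sleep or low-confidence days) rather than resolved.
- Sleep on moving platforms (trains, planes) produces continuous shaking
  that defeats variance-based detection; such days should be excluded via
  the travel itinerary.
- Episodes crossing 6 PM would be truncated by the day windowing; the
  window is chosen so this is rare for night sleepers.
- Non-wear detection trades specificity near flat segments for segment-
  length coverage (see the combination-mode discussion above).
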