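# actisleep

Longitudinal sleep analysis from raw wrist-accelerometer recordings.

Wearable watches that log continuous triaxial acceleration (in units of
gravity, g) capture a stark reduction in signal fluctuation during sleep.
`actisleep` turns months of such raw data into one estimated **major Sleep
Episode** per day — the longest continuous sleep period of at least 100
minutes — together with bedrest bounds, daily sleep metrics, and a
minute-level Sleep Timing Regularity Index (STRI). It is aimed at digital-
phenotyping and sleep-research groups who collect raw high-frequency
actigraphy (optionally with light, temperature, button presses, and
smartphone lock/unlock logs) and need reproducible, quality-controllable
sleep estimates without a sleep diary.

## Method

For each analysis day, running from 6 PM on the previous civil day to 6 PM
(so the night sits in the middle of the window):

1. **Non-wear removal.** The per-minute SD of each axis is smoothed with a
   150-minute forward-and-backward moving window; a minute is *wrist-off*
   when the RMS of the three smoothed axis values falls strictly below
   0.0185 g.
2. **Activity scoring.** Each minute's power is the area under its Welch
   power density spectrum (mean-removed, zero-frequency bin excluded —
   gravity drops out automatically), combined across axes as
   `sqrt((P_x² + P_y² + P_z²)/3)` and smoothed over 15 minutes. Minutes
   are classified against the *within-individual* 10/25/50/75th power
   percentiles of the whole study.
3. **Episode detection.** Classes map to sleep scores (+1 below the 25th
   percentile, 0 in the middle band, −0.75 and −1 above the median). A
   wide 100-minute window seeds candidate episodes, a narrow 60-minute
   window refines their edges, a 90-minute clean-up window connects
   densely sleep-scored neighbours, and candidates within 22.5 minutes
   join unconditionally. The longest candidate ≥ 100 min is the major
   Sleep Episode; its bounds expand over adjacent below-25th-percentile
   minutes, constrained by evening/waking button presses when one was
   recorded within 60 minutes of the estimate. Bedrest bounds then extend
   over adjacent below-median minutes.
4. **Metrics.** Per day: `SleepOnset/Offset/Duration`, bedrest bounds,
   `SleepOnsetLatency`, `SleepEfficiency`, active/immobile minutes split
   at the 40th percentile, bout counts with 1-minute tolerance, light
   (> 1 lux) and phone-event minutes during sleep, and `OffWrist`%. The
   STRI compares each day's 1440-minute sleep/wake pattern with the
   participant's *average sleep day* (the D most frequently slept clock
   minutes, D = mean daily sleep duration); longitudinal series are
   smoothed with a backward 14-day window tolerating up to 3 missing days.

Manual QC edits, time-zone itineraries (travel days and DST transition
nights become missing data), a lateral daily map, and a 48-hour
double-plot actogram are provided by the `qc` module. A built-in
synthetic-actigraphy generator (`actisleep.synthetic`) produces multi-day
recordings with known ground truth, which is how the whole chain is
tested.

## Worked example

```python
from actisleep import synthetic, pipeline

schedule = synthetic.regular_schedule(10, seed=1)   # truth: ~23:30-07:30
profile = synthetic.SimProfile(seed=1)              # 10 Hz triaxial + light
raw = synthetic.simulate_study(schedule, profile)

result = pipeline.run_study(raw)
day0 = result.episodes[0]
print(day0.clock("sleep_onset"), day0.clock("sleep_offset"))
print(result.metrics.loc[day0.day_index, ["SleepDuration", "SleepEfficiency", "OffWrist"]])
```

prints

```
23:44 07:49
SleepDuration          485.0
SleepEfficiency    94.174757
OffWrist                 0.0
```

— the detected major episode for the first study day (true night
23:37–07:58: both bounds recovered within 9 minutes), its duration in minutes, sleep
efficiency as a percentage of bedrest, and the wrist-off percentage of
that day. The same pipeline is available from the shell:

```sh
actisleep simulate --days 10 --seed 1 --out study/
actisleep run --raw study/raw.csv --out out/
```

which writes `sleep_episodes.csv`, `sleep_metrics.csv`, `stri.csv`,
`thresholds.json`, the daily map and the actogram.

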