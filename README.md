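# gaitbeep

Heel-strike detection, good-step feedback emulation and gait-quality
metrics from ankle-worn gyroscope recordings.

Older adults with a shuffling, foot-flat gait can relearn heel-first
stepping when each good step is rewarded in real time with an auditory
*beep*. A shank-mounted inertial sensor sees every step as a
characteristic sagittal-plane angular-velocity (AV) pattern: a large
positive lobe as the shank swings forward, then a sharp **negative** spike
as the heel lands and the foot decelerates. `gaitbeep` implements the
computational core of such a feedback device for researchers and
rehabilitation engineers:

* **detect** heel strikes in a recording: a swing peak ≥ `swing_min_amp`
  (default +50 deg/s) followed within `search_window` (0.40 s) by the most
  negative sample, which is the heel strike with peak AV `ω_min`;
* **classify** each step: *good* iff `ω_min ≤ θ` with threshold
  `θ = −90` deg/s by default (more negative = stronger heel-first
  contact; healthy adults typically reach −300 to −500 deg/s);
* **emulate the real-time loop**: a causal streaming detector consumes one
  sample at a time and emits a feedback event for every good step within
  0.45 s of the heel strike, provably matching batch detection;
* **summarize a session**: % good steps, cadence (steps/min), total
  walking time, AV mean/SD and coefficient of variation
  (CV = 100·SD/|mean|, an inconsistency index; <10% is regular gait),
  walking-bout segmentation and the ≥10-min-bout / ≥100 steps-per-minute
  physical-activity guideline check;
* **compare sessions** pre/post training with the ≥10 % clinically
  important change rule, direction-aware per parameter;
* **simulate** walking sessions with known ground truth (cadence, peak-AV
  distribution, fraction of good steps, walk/rest bout structure, sensor
  noise), including bundled reference personas A–F spanning severely
  impaired to functional gait.

No public corpus of labelled ankle-gyroscope recordings exists for this
problem, so the synthetic generator is a first-class, tested module: it is
how every pipeline stage is validated.

## Worked example

Simulate a pre-training session of reference persona B (43 % good steps
assigned, mean heel-strike AV −97 deg/s), analyze it, do the same for the
post-training persona, and compare:

```
$ gaitbeep simulate --reference B:pre:without --duration 120 --seed 7 -o pre/
INFO simulated 191 steps over 120.0 s -> pre
$ gaitbeep analyze pre/session.csv -o pre/
INFO detected 191 steps (73 good) in 1 bouts
$ gaitbeep simulate --reference B:post:without --duration 120 --seed 8 -o post/
$ gaitbeep analyze post/session.csv -o post/
$ gaitbeep compare pre/report.json post/report.json -o change.json
INFO overall important change: True
```

`pre/report.json` (abridged):

```json
{
  "pct_good": 38.2,
  "cadence": 95.5,
  "total_walk_time_s": 119.96,
  "av_mean": -77.8,
  "av_cv": 60.7,
  "n_bouts_ge_10min": 0
}
```

All 191 simulated steps were recovered and 38.2 % classified good — the
exact generated proportion for this seed. The session AV mean (−77.8) is
less negative than the persona's good-step mean (−97) because foot-flat
steps, included in the statistic, decelerate only weakly. `change.json`
then reports, pre → post: good steps 38.2 % → 78.3 % (+105 %,
important), AV −77.8 → −124.4 deg/s (+60 % more negative, important), CV
60.7 % → 36.8 % (−39 %, important), cadence +8.7 % (not important) —
so `overall_important` is true.

The same pipeline is available as a library:

```python
from gaitbeep import (GaitProfile, simulate_session, extract_sagittal,
                      detect_heel_strikes, segment_bouts, compute_metrics)

series, truth = simulate_session(GaitProfile(p_good=0.8, seed=1))
events = detect_heel_strikes(extract_sagittal(series))
metrics = compute_metrics(events, segment_bouts(events))
print(metrics.pct_good, metrics.cadence, metrics.av_mean)
```

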