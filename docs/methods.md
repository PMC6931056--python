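# Methods

## Problem and signal model

A gyroscope strapped above the ankle measures the shank's rotation rate.
During one step cycle the sagittal-plane (pitch) channel shows a large
positive lobe in mid-swing, a near-zero stance phase, and — when the heel
lands first — a sharp negative spike as the foot is decelerated onto the
ground. The depth of that spike (the per-step peak angular velocity,
deg/s, negative) is the quality statistic: strong heel-first contact is
several hundred deg/s in healthy adults, whereas shuffling, foot-flat
contact barely decelerates. A feedback device beeps whenever the spike
crosses a threshold, rewarding heel-first steps as they happen.

Conventions: the sagittal axis is gyro `y`, oriented so deceleration is
negative (`extract_sagittal` flips mirrored mountings); recordings are
uniformly sampled (default 100 Hz, accepted range limited only by the
filter realizability check), timestamps are session-relative seconds, and
timestamp jitter beyond 1 % of the nominal period is rejected as dropped
samples rather than silently resampled.

## Detection

The trace is low-passed (4th-order Butterworth, 15 Hz corner, applied
forward-backward so event times carry no phase delay) and scanned for
strict local maxima at or above `swing_min_amp` (+50 deg/s). For each
swing peak the most negative sample within the following `search_window`
(0.40 s) is taken as the heel strike; its value is the step's peak AV and
the step is good iff the peak is ≤ `threshold_av`, with the boundary
counting as good. Duplicate minima from multiple swing maxima collapse to
one event, and events closer than `refractory` (0.40 s) keep the earlier
one. Ties among equal minima take the earliest sample. The peak *angular
velocity* (not its derivative) is scored because that is the per-step
quantity gait reports tabulate, in deg/s.

Defaults were chosen so the reference personas classify sensibly — a
−48 deg/s mean with 0 % good steps must fall above the threshold, the
≈ −102 deg/s with-feedback means below it — and every constant is
configurable; devices in the field use unpublished, trainable thresholds,
so `threshold_av = −90` deg/s is a defensible middle setting, not a
calibrated constant.

## Streaming emulation

The real-time path re-implements the same rule causally: a single-pole
low-pass (same corner frequency) replaces the zero-phase filter, strict
local maxima are recognized one sample late, and each opens a running
minimum over the search window. A step is confirmed when its window
expires (or the stream ends). An early-confirmation rule — "the signal
rebounded N deg/s off the minimum" — was evaluated and rejected: with
realistic noise a later sample inside the window occasionally undercuts
the running minimum after the rebound, so early confirmation can disagree
with the batch path about the heel-strike sample. Waiting out the window
makes streaming and batch detection compute the minimum over the
identical sample set; the equivalence (same good-step sets, same sample
indices, arbitrary chunking) is asserted in the test suite with the batch
path run under the same causal filter, and the worst-case beep latency is
`search_window` plus one sample (measured ≤ 0.32 s, bound 0.45 s) —
comfortably within a stride, so the beep still reads as per-step
feedback. Beeps are logged events; no audio is synthesized.

## Session metrics

Bouts are maximal runs of steps with inter-step gaps below `gap_limit`
(default 10 s; "continuous walking" has no standard definition, and 10 s
is long enough to bridge hesitations but short enough to split genuine
rests). Bout edges are padded by half the median inter-step interval so
bout duration approximates walking time. Cadence divides total steps by
time inside bouts — elapsed time would penalize resting. AV statistics
use all steps (good and bad) with the sample (n−1) SD;
CV = 100·SD/|mean|, undefined below two steps or at zero mean. A session
with no steps reports zeros and an `empty_session` flag. The guideline
check is cadence ≥ 100 steps/min with at least one bout ≥ 10 min.

Pre/post comparison computes percent change per parameter in its
improving direction — good-steps ↑, cadence ↑, AV more negative, CV ↓ —
and flags changes ≥ 10 % as clinically important; a zero pre value falls
back to percentage points, flagged as such, rather than an undefined
ratio.

## Synthetic generator

Each step cycle (duration 60/cadence, jittered stride-to-stride with
SD 3 % of the cycle) is a raised-cosine swing lobe (amplitude 200 deg/s
by default, centred at 65 % of the cycle) plus a negative Gaussian
deceleration lobe (80 ms FWHM, centred at 90 %, snapped to the sample
grid so the array minimum equals the requested peak exactly). White
Gaussian noise is added per channel; the default 2 deg/s reflects MEMS
gyroscope noise plus strap/soft-tissue artifact, and tests exercise up to
10 deg/s. Accelerometer channels are filled with scaled copies of the
gyro activity plus noise and carry no ground-truth contract.

Good-step peaks are drawn from a truncated normal supported on
(−∞, `threshold_av` − `separation`] whose parent parameters are
moment-matched (via the truncated-normal moment equations, solved
numerically) so realized peaks have mean `av_mean` and SD `av_sd`; when
the target moments are infeasible under the truncation the sampler falls
back to plain rejection and the realized moments shift accordingly
(ground truth always records realized values). Bad steps attenuate a
parent draw by `bad_attenuation` (0.4) and are rejected into
(`threshold_av` + `separation`, −25]. Two modelling choices deserve
emphasis:

* the `separation` guard band (15 deg/s) encodes the assumption that
  heel-first and foot-flat contacts are morphologically distinct classes
  rather than a continuum straddling the threshold. It is what makes
  generated labels exactly recoverable through measurement noise — the
  all-good and all-bad recovery checks are exact *because of* this
  assumption, and passing them says nothing about classifying real steps
  whose peaks hover at the threshold;
* the −25 deg/s bad-peak ceiling keeps even foot-flat lobes deeper than
  the low-pass filter's transient undershoot after the swing lobe;
  physically, any ground contact decelerates the foot by tens of deg/s.

A single RNG is seeded per session and consumed in a fixed documented
order (per stride: timing jitter, class draw, peak draws; then the noise
arrays), so identical profiles give bitwise-identical sessions.

The bundled reference personas (A–F × pre/post × with/without feedback)
map published single-case summary values onto profiles
(`av_sd = |av_mean|·CV/100`). They span the observed clinical range but
are fixtures, not reconstructions: a profile's `av_mean` parameterizes
good-step peaks, so a fixture session's all-step AV mean will sit above
the cell value whenever many steps are bad.

## Validation design and problem sizes

All validation is property-based against generator ground truth:
noise-free detection (100 random sessions of 60–300 s) must recover step
counts exactly and times within 30 ms; good-step-proportion recovery runs
at noise SD 10 deg/s with ≥ 300 steps across p_good ∈ {0, ¼, ½, 0.8, 1}
(exact at the endpoints); AV mean/CV recovery uses ~500-step sessions at
the five observed (mean, CV) pairs from (−48, 59 %) to (−250, 11 %),
compared against the realized ground-truth step statistics — at n = 500
the sampling SD of a sample CV at CV = 59 % is ≈ 2.4 points, so realized
truth, not the profile parameter, is the well-posed oracle at this size
(parameter-level convergence is tested separately at n ≥ 1000). Streaming
equivalence runs 100 chunk-split sessions; bout segmentation is checked
against an O(n²) brute-force gap scan on 1000 random step-time sets.
These sizes keep the full suite under ~10 s while leaving every tolerance
dominated by method error, not sampling error.

## Limitations

Synthetic strides are stylized: no turning, stairs, shuffling transients,
left/right asymmetry, sensor drift or non-stationary noise, and the
good/bad dichotomy with a guard band is cleaner than real intermediate
contact patterns. Only the sagittal gyro channel is modelled
meaningfully. Detection constants are plausible engineering defaults, not
device-calibrated values; results on real recordings will depend on
per-device calibration of `threshold_av` and `swing_min_amp`.
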