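"""Batch heel-strike detection, step classification and bout segmentation.

Detection model: during each step cycle the shank swings forward (a large
positive sagittal angular-velocity lobe), then the heel lands and the foot
decelerates sharply (a negative spike).  A stride is therefore detected as
a positive swing peak of at least ``swing_min_amp`` followed, within
``search_window`` seconds, by the most negative sample — that minimum is
the heel strike, its value the step's peak angular velocity.  A step is
*good* when its peak is at or below (more negative than) ``threshold_av``;
the feedback device rewards exactly those steps with a beep.

The scored statistic is the peak angular velocity itself (deg/s), the
per-step quantity clinical reports tabulate, not its time derivative.

The batch path low-passes with a zero-phase Butterworth filter so detected
event times carry no group delay.  ``smoothing="causal"`` substitutes the
single-pole causal filter used by the streaming emulator
(:mod:`gaitbeep.stream`), which is how the two paths are compared like for
like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .io import SagittalTrace

__all__ = [
    "DetectionConfig", "StepEvent", "Bout",
    "detect_heel_strikes", "classify_step", "segment_bouts",
    "causal_lowpass", "smooth_trace",
]

#: Default inter-step interval (s) used to pad bout edges when a bout has
#: too few steps to estimate its own stride time (100 steps/min).
DEFAULT_STRIDE_S = 0.6


@dataclass
class DetectionConfig:
    """Tunable constants of the detector.

    threshold_av      classification threshold, deg/s (negative).  Steps
                      whose deceleration peak is <= this value are good.
    swing_min_amp     minimum positive mid-swing peak (deg/s) for a stride
                      candidate; rejects noise and non-gait motion.
    search_window     seconds after the swing peak in which the
                      deceleration minimum is sought.
    refractory        minimum inter-step interval, s; on conflict the
                      earlier event is kept.
    smoothing_cutoff  low-pass corner frequency, Hz.
    """

    threshold_av: float = -90.0
    swing_min_amp: float = 50.0
    search_window: float = 0.40
    refractory: float = 0.40
    smoothing_cutoff: float = 15.0

    def validate(self) -> "DetectionConfig":
        if self.threshold_av >= 0:
            raise ConfigurationError(f"threshold_av must be negative, got {self.threshold_av}")
        if self.search_window <= 0:
            raise ConfigurationError(f"search_window must be > 0, got {self.search_window}")
        if self.refractory <= 0:
            raise ConfigurationError(f"refractory must be > 0, got {self.refractory}")
        if self.smoothing_cutoff <= 0:
            raise ConfigurationError(f"smoothing_cutoff must be > 0, got {self.smoothing_cutoff}")
        if self.swing_min_amp <= 0:
            raise ConfigurationError(f"swing_min_amp must be > 0, got {self.swing_min_amp}")
        return self


@dataclass
class StepEvent:
    """One detected heel strike."""

    t_heel_strike: float
    peak_av: float
    is_good: bool


@dataclass
class Bout:
    """A maximal run of consecutive steps without a long rest.

    ``step_indices`` is a ``range`` into the session's time-ordered step
    list.
    """

    start: float
    end: float
    step_indices: range

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_steps(self) -> int:
        return len(self.step_indices)


def classify_step(peak_av: float, threshold_av: float) -> bool:
    """True iff the step is good: peak at or below the (negative) threshold."""
    if threshold_av >= 0:
        raise ConfigurationError(f"threshold_av must be negative, got {threshold_av}")
    return peak_av <= threshold_av


def causal_lowpass(av: np.ndarray, cutoff: float, sample_rate: float) -> np.ndarray:
    """Single-pole IIR low-pass, zero initial state — the streaming filter."""
    alpha = 1.0 - math.exp(-2.0 * math.pi * cutoff / sample_rate)
    return sps.lfilter([alpha], [1.0, alpha - 1.0], av)


def smooth_trace(av: np.ndarray, cutoff: float, sample_rate: float,
                 smoothing: str = "zero_phase") -> np.ndarray:
    """Low-pass the raw trace; ``zero_phase`` (Butterworth, filtfilt) or ``causal``."""
    if sample_rate < 2.0 * cutoff or math.isclose(sample_rate, 2.0 * cutoff):
        raise ConfigurationError(
            f"sample rate {sample_rate} Hz cannot realize a {cutoff} Hz low-pass"
        )
    if len(av) == 0:
        return np.asarray(av, dtype=float).copy()
    if smoothing == "causal":
        return causal_lowpass(av, cutoff, sample_rate)
    if smoothing != "zero_phase":
        raise ConfigurationError(f"unknown smoothing mode {smoothing!r}")
    sos = sps.butter(4, cutoff, btype="low", fs=sample_rate, output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), len(av) - 1)
    return sps.sosfiltfilt(sos, av, padlen=padlen)


def _scan_candidates(f: np.ndarray, sample_rate: float,
                     config: DetectionConfig) -> list[tuple[int, float]]:
    """Swing peaks -> (min_index, min_value) candidates, deduplicated."""
    peaks, _ = sps.find_peaks(f, height=config.swing_min_amp)
    w = int(math.floor(config.search_window * sample_rate + 1e-9))
    n = len(f)
    seen: dict[int, float] = {}
    for s in peaks:
        lo, hi = s + 1, min(s + w, n - 1)
        if lo > hi:
            continue
        i = lo + int(np.argmin(f[lo:hi + 1]))
        seen.setdefault(i, float(f[i]))
    return sorted(seen.items())


def detect_heel_strikes(trace: SagittalTrace, config: DetectionConfig | None = None,
                        smoothing: str = "zero_phase") -> list[StepEvent]:
    """Detect and classify every heel strike in a sagittal trace.

    Returns time-ordered events spaced at least ``config.refractory``
    apart (the earlier event wins a conflict).  An empty or stride-free
    trace yields an empty list.
    """
    config = (config or DetectionConfig()).validate()
    f = smooth_trace(trace.av, config.smoothing_cutoff, trace.sample_rate, smoothing)
    events: list[StepEvent] = []
    last_i = None
    for i, val in _scan_candidates(f, trace.sample_rate, config):
        if last_i is not None and (i - last_i) / trace.sample_rate < config.refractory - 1e-9:
            continue
        events.append(StepEvent(
            t_heel_strike=trace.t0 + i / trace.sample_rate,
            peak_av=val,
            is_good=classify_step(val, config.threshold_av),
        ))
        last_i = i
    return events


def segment_bouts(events: list[StepEvent], gap_limit: float = 10.0) -> list[Bout]:
    """Split time-ordered steps into walking bouts at rests >= ``gap_limit`` s.

    Bout edges are padded by half the median inter-step interval of the
    bout (first step time - half stride, last step time + half stride) so
    a bout's duration approximates actual walking time, not just
    first-to-last-step span.  Bouts with a single step fall back to the
    session-wide median interval, then to ``DEFAULT_STRIDE_S``.
    """
    if not events:
        return []
    times = np.array([e.t_heel_strike for e in events])
    breaks = np.flatnonzero(np.diff(times) >= gap_limit)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(times) - 1]])

    all_intervals = np.diff(times)
    within = np.delete(all_intervals, breaks) if len(all_intervals) else all_intervals
    global_half = 0.5 * float(np.median(within)) if len(within) else 0.5 * DEFAULT_STRIDE_S

    bouts = []
    for a, b in zip(starts, ends):
        if b > a:
            half = 0.5 * float(np.median(np.diff(times[a:b + 1])))
        else:
            half = global_half
        bouts.append(Bout(start=float(times[a] - half), end=float(times[b] + half),
                          step_indices=range(int(a), int(b) + 1)))
    return bouts
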