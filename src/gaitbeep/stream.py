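"""Sample-by-sample emulation of the real-time feedback loop.

The wearable device confirms each good step while walking continues, so
the detector must run causally: samples arrive one at a time, and a beep
must be issued within a bounded delay of the heel strike it rewards.  This
module re-implements the detection rule of :mod:`gaitbeep.detect` as an
incremental state machine:

* the raw sample is smoothed by a single-pole low-pass (the causal
  counterpart of the batch Butterworth filter);
* a strict local maximum of the filtered signal at or above
  ``swing_min_amp`` opens a *search*: the running minimum over the next
  ``search_window`` seconds;
* a search concludes when its window expires (or the stream ends), at
  which point the running minimum is the heel strike;
* concluded candidates pass the same refractory rule as the batch path.

A step is deliberately *not* confirmed early when the signal rebounds off
a deep minimum: under realistic sensor noise a later sample inside the
window can undercut the running minimum even after a sizeable rebound, so
early confirmation would occasionally disagree with the batch path about
the exact heel-strike sample.  Waiting out the window makes the two paths
compute the minimum over the identical sample set, and the resulting
worst-case beep delay — one search window plus one sample — still sits
well inside what a walker perceives as per-step feedback.

A :class:`FeedbackEvent` (the "beep") is emitted for good steps only.  Bad
steps are still recorded as :class:`StepEvent`s on the state, so session
statistics can be computed from a replayed stream.

The contract with the batch path, checked by the test-suite on synthetic
sessions: replaying a trace through :class:`StreamDetector` yields the same
good-step set as ``detect_heel_strikes(trace, config, smoothing="causal")``,
with event times agreeing to within one sample, regardless of how the
trace is chunked.  Worst-case feedback latency is ``search_window`` plus
one sample period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .detect import DetectionConfig, StepEvent, classify_step
from .errors import ConfigurationError, SequencingError, StreamClosedError
from .io import SagittalTrace

__all__ = ["FeedbackEvent", "StreamDetector", "replay"]


@dataclass
class FeedbackEvent:
    """An emitted beep: when it was issued and the step it rewards."""

    t_emit: float
    step: StepEvent

    @property
    def latency(self) -> float:
        return self.t_emit - self.step.t_heel_strike


class _Search:
    __slots__ = ("deadline", "min_idx", "min_val", "min_t")

    def __init__(self, deadline: int):
        self.deadline = deadline
        self.min_idx = -1
        self.min_val = math.inf
        self.min_t = math.nan


class StreamDetector:
    """Causal heel-strike detector consuming one sample per call.

    Parameters mirror the batch path; ``sample_rate`` must satisfy the
    same filter realizability constraint.  Samples must be pushed in
    strictly increasing time order; chunking is irrelevant — the state
    after n samples depends only on those samples and the config.
    """

    def __init__(self, sample_rate: float, config: DetectionConfig | None = None):
        self.config = (config or DetectionConfig()).validate()
        if sample_rate < 2.0 * self.config.smoothing_cutoff or math.isclose(
                sample_rate, 2.0 * self.config.smoothing_cutoff):
            raise ConfigurationError(
                f"sample rate {sample_rate} Hz cannot realize a "
                f"{self.config.smoothing_cutoff} Hz low-pass"
            )
        self.sample_rate = sample_rate
        self._alpha = 1.0 - math.exp(-2.0 * math.pi * self.config.smoothing_cutoff / sample_rate)
        self._window = int(math.floor(self.config.search_window * sample_rate + 1e-9))
        self._y = 0.0          # filter state
        self._f1 = None        # filtered value at i-1
        self._f2 = None        # filtered value at i-2
        self._i = -1
        self._last_t = -math.inf
        self._searches: list[_Search] = []
        self._last_accept_idx: int | None = None
        self._closed = False
        self.steps: list[StepEvent] = []       # every confirmed step, good and bad
        self.feedback: list[FeedbackEvent] = []  # beeps (good steps only)

    # -- internal ---------------------------------------------------------

    def _conclude(self, search: _Search, t_now: float) -> list[FeedbackEvent]:
        if search.min_idx < 0:
            return []
        i = search.min_idx
        if self._last_accept_idx is not None:
            if i <= self._last_accept_idx:
                return []
            if (i - self._last_accept_idx) / self.sample_rate < self.config.refractory - 1e-9:
                return []
        step = StepEvent(
            t_heel_strike=search.min_t,
            peak_av=search.min_val,
            is_good=classify_step(search.min_val, self.config.threshold_av),
        )
        self._last_accept_idx = i
        self.steps.append(step)
        if step.is_good:
            ev = FeedbackEvent(t_emit=t_now, step=step)
            self.feedback.append(ev)
            return [ev]
        return []

    # -- public -----------------------------------------------------------

    def push_sample(self, t: float, av: float) -> list[FeedbackEvent]:
        """Consume one sample; return any beeps confirmed by it."""
        if self._closed:
            raise StreamClosedError("stream already finalized")
        if t <= self._last_t:
            raise SequencingError(f"sample time {t} not after previous {self._last_t}")
        self._last_t = t
        self._i += 1
        i = self._i
        y = self._alpha * av + (1.0 - self._alpha) * self._y
        self._y = y

        emitted: list[FeedbackEvent] = []

        # 1. conclude searches whose window ended before this sample
        still_open = []
        for s in self._searches:
            if i > s.deadline:
                emitted.extend(self._conclude(s, t))
            else:
                still_open.append(s)
        self._searches = still_open

        # 2. a strict local max at i-1 at/above the swing amplitude opens a search
        if (self._f1 is not None and self._f2 is not None
                and self._f1 >= self.config.swing_min_amp
                and self._f2 < self._f1 and y < self._f1):
            self._searches.append(_Search(deadline=(i - 1) + self._window))

        # 3. feed the sample to open searches
        for s in self._searches:
            if y < s.min_val:
                s.min_val, s.min_idx, s.min_t = y, i, t

        self._f2, self._f1 = self._f1, y
        return emitted

    def finalize(self) -> list[FeedbackEvent]:
        """Flush pending searches at end of stream and close the detector."""
        if self._closed:
            raise StreamClosedError("finalize called twice")
        self._closed = True
        emitted: list[FeedbackEvent] = []
        for s in self._searches:
            emitted.extend(self._conclude(s, self._last_t))
        self._searches = []
        return emitted


def replay(trace: SagittalTrace, config: DetectionConfig | None = None) -> StreamDetector:
    """Push an entire trace through a fresh detector and finalize it."""
    det = StreamDetector(trace.sample_rate, config)
    for t, v in zip(trace.times, trace.av):
        det.push_sample(float(t), float(v))
    det.finalize()
    return det
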