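"""Session-level gait-quality summaries and pre/post change reports.

The summaries mirror what clinicians tabulate for feedback-based gait
training: proportion of good steps (%), average cadence (steps/min), total
walking time (s), and the mean, SD and coefficient of variation (CV) of
the per-step heel-strike angular velocity.  Heel-strike AV is negative and
"more negative is better" (typical healthy values are -300 to -500 deg/s);
a CV under 10% indicates regular stepping.  A change of at least 10% in
the improving direction of a parameter is treated as clinically important,
and a session qualifies for moderate-intensity walking guidelines when
cadence is at least 100 steps/min with at least one bout of 10 minutes.

AV statistics are computed over *all* detected steps, good and bad, with
the sample (n-1) standard deviation.  Cadence divides steps by time spent
walking within bouts, not elapsed session time, so rests do not deflate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Bout, StepEvent
from .errors import ConsistencyError, UndefinedStatisticError

__all__ = [
    "GaitMetrics", "ParameterChange", "ChangeReport",
    "compute_metrics", "coefficient_of_variation", "compare_sessions",
    "meets_guideline", "IMPORTANT_CHANGE_PCT", "GUIDELINE_CADENCE",
    "GUIDELINE_BOUT_S",
]

IMPORTANT_CHANGE_PCT = 10.0
GUIDELINE_CADENCE = 100.0
GUIDELINE_BOUT_S = 600.0


@dataclass
class GaitMetrics:
    """Summary of one walking session."""

    pct_good: float
    cadence: float
    total_walk_time: float
    av_mean: float
    av_sd: float
    av_cv: float
    bouts: list[Bout] = field(default_factory=list)
    n_bouts_ge_10min: int = 0
    n_steps: int = 0
    empty_session: bool = False

    def to_dict(self) -> dict:
        return {
            "pct_good": self.pct_good,
            "cadence": self.cadence,
            "total_walk_time_s": self.total_walk_time,
            "av_mean": self.av_mean,
            "av_sd": self.av_sd,
            "av_cv": self.av_cv,
            "bouts": [{"start": b.start, "end": b.end, "n_steps": b.n_steps}
                      for b in self.bouts],
            "n_bouts_ge_10min": self.n_bouts_ge_10min,
            "n_steps": self.n_steps,
            "empty_session": self.empty_session,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitMetrics":
        bouts = []
        i = 0
        for b in d.get("bouts", []):
            n = int(b.get("n_steps", 0))
            bouts.append(Bout(start=float(b["start"]), end=float(b["end"]),
                              step_indices=range(i, i + n)))
            i += n
        return cls(
            pct_good=float(d["pct_good"]),
            cadence=float(d["cadence"]),
            total_walk_time=float(d["total_walk_time_s"]),
            av_mean=float(d["av_mean"]),
            av_sd=float(d["av_sd"]),
            av_cv=float(d["av_cv"]),
            bouts=bouts,
            n_bouts_ge_10min=int(d.get("n_bouts_ge_10min", 0)),
            n_steps=int(d.get("n_steps", sum(b.n_steps for b in bouts))),
            empty_session=bool(d.get("empty_session", False)),
        )


def coefficient_of_variation(values) -> float:
    """100 * sample SD / |mean|, the between-step variability in percent.

    Undefined (raises) for fewer than two values or zero mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UndefinedStatisticError(f"CV needs at least 2 values, got {arr.size}")
    mean = float(arr.mean())
    if mean == 0.0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return 100.0 * float(arr.std(ddof=1)) / abs(mean)


def compute_metrics(events: list[StepEvent], bouts: list[Bout]) -> GaitMetrics:
    """Summarize a session from its detected steps and walking bouts.

    Every step must fall inside some bout.  A session with no steps
    returns zeros flagged ``empty_session``; AV SD and CV are reported as
    0 when fewer than two steps exist.
    """
    for e in events:
        if not any(b.start - 1e-9 <= e.t_heel_strike <= b.end + 1e-9 for b in bouts):
            raise ConsistencyError(
                f"step at t={e.t_heel_strike:.3f}s lies outside every bout"
            )
    n = len(events)
    total_walk = float(sum(b.duration for b in bouts))
    if n == 0:
        return GaitMetrics(pct_good=0.0, cadence=0.0, total_walk_time=total_walk,
                           av_mean=0.0, av_sd=0.0, av_cv=0.0, bouts=list(bouts),
                           n_bouts_ge_10min=sum(b.duration >= GUIDELINE_BOUT_S for b in bouts),
                           n_steps=0, empty_session=True)

    peaks = np.array([e.peak_av for e in events])
    n_good = sum(e.is_good for e in events)
    av_mean = float(peaks.mean())
    av_sd = float(peaks.std(ddof=1)) if n >= 2 else 0.0
    av_cv = 100.0 * av_sd / abs(av_mean) if av_mean != 0.0 else 0.0
    return GaitMetrics(
        pct_good=100.0 * n_good / n,
        cadence=60.0 * n / total_walk if total_walk > 0 else 0.0,
        total_walk_time=total_walk,
        av_mean=av_mean,
        av_sd=av_sd,
        av_cv=av_cv,
        bouts=list(bouts),
        n_bouts_ge_10min=sum(b.duration >= GUIDELINE_BOUT_S for b in bouts),
        n_steps=n,
    )


@dataclass
class ParameterChange:
    """Pre/post change of one gait parameter, signed toward improvement."""

    name: str
    pre: float
    post: float
    change_pct: float       # positive = improvement in this parameter's direction
    important: bool
    used_percentage_points: bool = False


@dataclass
class ChangeReport:
    parameters: dict[str, ParameterChange]
    overall_important: bool

    def to_dict(self) -> dict:
        return {
            "parameters": {
                k: {"pre": p.pre, "post": p.post, "change_pct": p.change_pct,
                    "important": p.important,
                    "used_percentage_points": p.used_percentage_points}
                for k, p in self.parameters.items()
            },
            "overall_important": self.overall_important,
        }


def _change(name: str, pre: float, post: float, improving_sign: float) -> ParameterChange:
    """Percent change in the improving direction; points fallback when pre == 0."""
    delta = improving_sign * (post - pre)
    if pre == 0.0:
        pct, points = delta, True
    else:
        pct, points = 100.0 * delta / abs(pre), False
    return ParameterChange(name=name, pre=pre, post=post, change_pct=pct,
                           important=pct >= IMPORTANT_CHANGE_PCT,
                           used_percentage_points=points)


def compare_sessions(pre: GaitMetrics, post: GaitMetrics) -> ChangeReport:
    """Pre/post report with the >=10% clinically-important-change rule.

    Improving directions: more good steps, higher cadence, more negative
    heel-strike AV, lower AV variability.  When a pre value is exactly 0
    (percent change undefined) the change is reported in percentage points
    and flagged.
    """
    params = {
        "pct_good": _change("pct_good", pre.pct_good, post.pct_good, +1.0),
        "cadence": _change("cadence", pre.cadence, post.cadence, +1.0),
        # improvement = more negative, i.e. |post| > |pre|
        "av_mean": _change("av_mean", abs(pre.av_mean), abs(post.av_mean), +1.0),
        "av_cv": _change("av_cv", pre.av_cv, post.av_cv, -1.0),
    }
    params["av_mean"].name = "av_mean"
    params["av_mean"].pre = pre.av_mean
    params["av_mean"].post = post.av_mean
    return ChangeReport(parameters=params,
                        overall_important=any(p.important for p in params.values()))


def meets_guideline(metrics: GaitMetrics) -> bool:
    """Moderate-intensity walking check: cadence >= 100 and a >=10-min bout."""
    return metrics.cadence >= GUIDELINE_CADENCE and metrics.n_bouts_ge_10min >= 1
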