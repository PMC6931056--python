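"""Synthetic walking sessions with known ground truth.

No public corpus of ankle-gyroscope walking recordings accompanies this
problem, so every downstream stage is exercised against a generator that
emits sagittal-plane angular-velocity traces with a fully known answer key:
where each heel strike is, how deep its deceleration peak is, and whether
the step was generated as heel-first ("good") or foot-flat ("bad").

Waveform model
--------------
One step cycle of duration ``T`` (``T = 60 / cadence`` seconds) consists of

* a stance segment near zero,
* a positive raised-cosine mid-swing lobe (the shank rotating forward),
  centred at ``0.65 T`` with support ``[0.5 T, 0.8 T]`` and amplitude
  ``swing_amp``,
* a negative Gaussian deceleration lobe at heel strike, centred at
  ``0.9 T`` with fixed 80 ms full width at half maximum, whose minimum is
  the step's peak angular velocity.

Only the peak value and its timing are contractual; the lobe shapes are a
modelling convenience.  The deceleration centre is snapped to the sample
grid so the array minimum equals the requested peak exactly before noise.

Peak-value model
----------------
Good steps draw their peak from a truncated normal supported on
``(-inf, threshold_av - separation]`` whose parent parameters are
moment-matched so the *realized* peaks still have mean ``av_mean`` and SD
``av_sd``.  Bad steps draw from the same parent, attenuate by
``bad_attenuation`` (foot-flat contact still decelerates, weakly), and are
rejected into ``(threshold_av + separation, -25]``.  The ``separation``
guard band (deg/s) encodes the modelling assumption that heel-first and
foot-flat contacts are morphologically distinct classes rather than a
continuum straddling the feedback threshold; it is what makes the
generated good/bad labels exactly recoverable by a detector that measures
peaks through sensor noise.

Determinism
-----------
A single ``numpy`` Generator is seeded per session and consumed in a fixed
documented order: for every stride, (1) timing jitter, (2) the good/bad
Bernoulli draw, (3) the peak rejection draws; after all bouts, the additive
noise arrays for gyro y, x, z and the three accelerometer channels, in that
order.  Two calls with the same profile are therefore bitwise identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .errors import ParameterError
from .io import IMUSeries

__all__ = ["GaitProfile", "GroundTruth", "stride_waveform", "simulate_session"]

# Step-cycle layout (fractions of the cycle) and deceleration-lobe width.
SWING_CENTER = 0.65
SWING_HALFWIDTH = 0.15
DECEL_CENTER = 0.90
DECEL_SIGMA_S = 0.080 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 80 ms FWHM

# Peaks are capped below this value so every generated step keeps a
# physically meaningful (negative) deceleration.
PEAK_CEILING = -1.0

# Foot-flat contact still decelerates the foot by tens of deg/s; bad-step
# peaks are kept at or below this ceiling so their deceleration lobe stays
# distinguishable from filter transients of the (much larger) swing lobe.
BAD_PEAK_MAX = -25.0


@dataclass
class GaitProfile:
    """Generative parameters for one synthetic walking session.

    cadence            steps per minute (each cycle is one step).
    av_mean, av_sd     mean and between-step SD of the heel-strike peak
                       angular velocity of *good* steps, deg/s (mean < 0).
    p_good             probability a step is generated heel-first.
    bad_attenuation    factor scaling the deceleration peak of foot-flat
                       steps (in (0, 1]).
    swing_amp          positive mid-swing lobe amplitude, deg/s.
    noise_sd           additive white sensor noise, deg/s.
    bout_plan          list of (walk_seconds, rest_seconds) pairs.
    threshold_av       classification threshold the session is generated
                       against; ground-truth labels satisfy
                       ``is_good == (peak <= threshold_av)``.
    separation         half-width of the guard band around the threshold
                       that neither class enters, deg/s.
    timing_jitter      stride-to-stride SD as a fraction of the cycle.
    """

    cadence: float = 100.0
    av_mean: float = -150.0
    av_sd: float = 30.0
    p_good: float = 0.8
    bad_attenuation: float = 0.4
    swing_amp: float = 200.0
    noise_sd: float = 2.0
    bout_plan: list[tuple[float, float]] = field(default_factory=lambda: [(120.0, 0.0)])
    seed: int = 0
    threshold_av: float = -90.0
    separation: float = 15.0
    timing_jitter: float = 0.03

    def validate(self) -> "GaitProfile":
        if self.cadence <= 0:
            raise ParameterError(f"cadence must be > 0, got {self.cadence}")
        if self.av_mean >= 0:
            raise ParameterError(f"av_mean must be negative, got {self.av_mean}")
        if self.av_sd < 0:
            raise ParameterError(f"av_sd must be >= 0, got {self.av_sd}")
        if not 0.0 <= self.p_good <= 1.0:
            raise ParameterError(f"p_good must be in [0, 1], got {self.p_good}")
        if not 0.0 < self.bad_attenuation <= 1.0:
            raise ParameterError(f"bad_attenuation must be in (0, 1], got {self.bad_attenuation}")
        if self.swing_amp <= 0:
            raise ParameterError(f"swing_amp must be > 0, got {self.swing_amp}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.threshold_av >= 0:
            raise ParameterError(f"threshold_av must be negative, got {self.threshold_av}")
        if self.separation < 0:
            raise ParameterError(f"separation must be >= 0, got {self.separation}")
        if self.threshold_av + self.separation >= PEAK_CEILING:
            raise ParameterError(
                "threshold_av + separation must stay below the peak ceiling "
                f"({PEAK_CEILING} deg/s)"
            )
        if not self.bout_plan:
            raise ParameterError("bout_plan must contain at least one (walk, rest) pair")
        for walk, rest in self.bout_plan:
            if walk <= 0 or rest < 0:
                raise ParameterError(f"invalid bout (walk={walk}, rest={rest})")
        return self


@dataclass
class GroundTruth:
    """The answer key of a simulated session."""

    heel_strike_times: np.ndarray
    true_peak_av: np.ndarray
    is_good: np.ndarray
    bout_intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.heel_strike_times = np.asarray(self.heel_strike_times, dtype=float)
        self.true_peak_av = np.asarray(self.true_peak_av, dtype=float)
        self.is_good = np.asarray(self.is_good, dtype=bool)

    @property
    def n_steps(self) -> int:
        return len(self.heel_strike_times)

    def validate(self, threshold_av: float | None = None) -> "GroundTruth":
        n = self.n_steps
        if len(self.true_peak_av) != n or len(self.is_good) != n:
            raise ParameterError("per-step lists must have equal length")
        if n and (np.diff(self.heel_strike_times) <= 0).any():
            raise ParameterError("heel_strike_times must be strictly increasing")
        for t in self.heel_strike_times:
            if not any(lo <= t < hi for lo, hi in self.bout_intervals):
                raise ParameterError(f"heel strike at {t:.3f}s outside every bout interval")
        if threshold_av is not None:
            expected = self.true_peak_av <= threshold_av
            if not np.array_equal(expected, self.is_good):
                raise ParameterError("is_good labels inconsistent with generation threshold")
        return self

    def to_dict(self) -> dict:
        return {
            "heel_strike_times": self.heel_strike_times.tolist(),
            "true_peak_av": self.true_peak_av.tolist(),
            "is_good": [bool(g) for g in self.is_good],
            "bout_intervals": [[lo, hi] for lo, hi in self.bout_intervals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            heel_strike_times=np.asarray(d["heel_strike_times"], dtype=float),
            true_peak_av=np.asarray(d["true_peak_av"], dtype=float),
            is_good=np.asarray(d["is_good"], dtype=bool),
            bout_intervals=[tuple(b) for b in d["bout_intervals"]],
        )


def _stride_arrays(swing_amp: float, peak_av: float, stride_duration: float,
                   sample_rate: float) -> tuple[np.ndarray, int]:
    """Return (waveform, heel_strike_index) for one noise-free step cycle."""
    if peak_av >= 0:
        raise ParameterError(f"peak_av must be negative, got {peak_av}")
    if stride_duration <= 0:
        raise ParameterError(f"stride_duration must be > 0, got {stride_duration}")
    n = int(round(stride_duration * sample_rate))
    if n == 0:
        return np.empty(0), 0
    phase = np.arange(n) / n
    w = np.zeros(n)
    in_swing = np.abs(phase - SWING_CENTER) <= SWING_HALFWIDTH
    w[in_swing] = swing_amp * 0.5 * (
        1.0 + np.cos(np.pi * (phase[in_swing] - SWING_CENTER) / SWING_HALFWIDTH)
    )
    c = min(int(round(DECEL_CENTER * n)), n - 1)
    t_rel = (np.arange(n) - c) / sample_rate
    w += peak_av * np.exp(-0.5 * (t_rel / DECEL_SIGMA_S) ** 2)
    return w, c


def stride_waveform(profile: GaitProfile, peak_av: float, stride_duration: float,
                    sample_rate: float) -> np.ndarray:
    """Noise-free waveform of a single step cycle.

    The returned array has ``round(stride_duration * sample_rate)`` samples
    and its minimum equals ``peak_av`` (the deceleration centre is snapped
    to the grid).
    """
    w, _ = _stride_arrays(profile.swing_amp, peak_av, stride_duration, sample_rate)
    return w


class _GoodPeakSampler:
    """Truncated-normal peak sampler whose realized moments match the target.

    Solves for parent (mu, sigma) such that a normal truncated to
    ``(-inf, upper]`` has mean ``m`` and SD ``s``.  Matching is feasible
    when ``m < upper`` and ``s`` is comfortably below ``upper - m`` (the
    one-sided truncated normal cannot exceed SD == distance-to-bound); when
    infeasible the sampler falls back to plain rejection of N(m, s) draws,
    accepting the realized-moment bias.
    """

    def __init__(self, m: float, s: float, upper: float):
        self.upper = upper
        self.mu, self.sigma = m, max(s, 1e-9)
        if m < upper and 0 < s < 0.95 * (upper - m):
            def residual(p):
                mu, logsig = p
                sigma = math.exp(logsig)
                z = (upper - mu) / sigma
                mean, var = stats.truncnorm.stats(-np.inf, z, loc=mu, scale=sigma,
                                                  moments="mv")
                return [float(mean) - m, math.sqrt(float(var)) - s]

            try:
                sol, info, ok, _ = optimize.fsolve(residual, [m, math.log(s)],
                                                   full_output=True)
                if ok == 1 and max(abs(r) for r in info["fvec"]) < 1e-6:
                    self.mu, self.sigma = float(sol[0]), math.exp(float(sol[1]))
            except (ValueError, OverflowError):
                pass

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            v = self.mu + self.sigma * rng.standard_normal()
            if v <= self.upper:
                return v
        return self.upper


def _draw_bad_peak(rng: np.random.Generator, profile: GaitProfile) -> float:
    lo = profile.threshold_av + profile.separation
    hi = BAD_PEAK_MAX if lo < BAD_PEAK_MAX else PEAK_CEILING
    v = hi
    for _ in range(1000):
        v = profile.bad_attenuation * (profile.av_mean + profile.av_sd * rng.standard_normal())
        if lo < v <= hi:
            return v
    return float(np.clip(v, lo + 1e-9, hi))


def simulate_session(profile: GaitProfile,
                     sample_rate: float = 100.0) -> tuple[IMUSeries, GroundTruth]:
    """Generate one walking session and its answer key.

    The session alternates walking and rest per ``profile.bout_plan``;
    strides are laid down back to back inside each walking interval with
    Gaussian timing jitter, so the per-bout step count is
    ``cadence * walk / 60`` up to +-1.  Rest intervals contain only noise.
    Deterministic for a fixed profile (see module docstring for the draw
    order).
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    total = sum(w + r for w, r in profile.bout_plan)
    n = int(round(total * sample_rate))
    av = np.zeros(n)

    good_sampler = _GoodPeakSampler(profile.av_mean, profile.av_sd,
                                    profile.threshold_av - profile.separation)
    period = 60.0 / profile.cadence

    hs_times: list[float] = []
    peaks: list[float] = []
    goods: list[bool] = []
    bout_intervals: list[tuple[float, float]] = []

    cursor = 0.0
    for walk, rest in profile.bout_plan:
        b0 = cursor
        bout_intervals.append((b0, b0 + walk))
        s = b0
        while True:
            z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
            stride = period * (1.0 + profile.timing_jitter * z)
            if s + stride > b0 + walk + 1e-9:
                break
            good = bool(rng.random() < profile.p_good)
            peak = good_sampler.draw(rng) if good else _draw_bad_peak(rng, profile)
            w, c = _stride_arrays(profile.swing_amp, peak, stride, sample_rate)
            i0 = int(round(s * sample_rate))
            hi = min(i0 + len(w), n)
            av[i0:hi] += w[: hi - i0]
            hs_times.append((i0 + c) / sample_rate)
            peaks.append(peak)
            goods.append(peak <= profile.threshold_av)
            s += stride
        cursor += walk + rest

    av += rng.normal(0.0, profile.noise_sd, n)
    gyro = np.column_stack([
        rng.normal(0.0, 0.5 * profile.noise_sd, n),
        np.zeros(n),  # placeholder, filled below to keep draw order explicit
        rng.normal(0.0, 0.5 * profile.noise_sd, n),
    ])
    gyro[:, 1] = av
    # Accelerometer channels carry no ground-truth contract: scaled copies
    # of the sagittal activity plus noise, gravity on z.
    accel = np.column_stack([
        0.01 * av + rng.normal(0.0, 0.2, n),
        rng.normal(0.0, 0.2, n),
        9.81 + 0.005 * np.abs(av) + rng.normal(0.0, 0.2, n),
    ])

    series = IMUSeries(sample_rate=sample_rate, gyro=gyro, accel=accel).validate()
    truth = GroundTruth(
        heel_strike_times=np.asarray(hs_times),
        true_peak_av=np.asarray(peaks),
        is_good=np.asarray(goods, dtype=bool),
        bout_intervals=bout_intervals,
    )
    return series, truth
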