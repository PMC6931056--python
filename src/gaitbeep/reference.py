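"""Reference gait profiles spanning the clinically observed range.

Six personas (A-F) of older adults with walking capacity from very limited
to functional, each observed at two timepoints (``pre``/``post`` a
five-session feedback-training block) and two feedback conditions
(``with``/``without`` the auditory beep).  Each cell carries the four
session summaries — percent good steps, cadence (steps/min), mean
heel-strike angular velocity (deg/s) and its coefficient of variation (%)
— and is converted to a :class:`~gaitbeep.simulate.GaitProfile` via::

    av_mean = AV cell        av_sd = |AV| * CV / 100
    cadence = cadence cell   p_good = good-steps cell / 100

These profiles are fixtures for simulation studies: persona A pre-training
(0% good steps, AV -48 deg/s) is severely impaired gait, persona F
post-training (99% good, AV -250 deg/s) approaches the -300 to -500 deg/s
range typical of healthy adults.
"""

from __future__ import annotations

from dataclasses import replace

from .errors import ProfileLookupError
from .simulate import GaitProfile

PARTICIPANTS = ("A", "B", "C", "D", "E", "F")
TIMEPOINTS = ("pre", "post")
FEEDBACK = ("without", "with")

# (pct_good, cadence, av_mean, av_cv_pct) per participant, by condition.
_TABLE: dict[tuple[str, str], dict[str, tuple[float, float, float, float]]] = {
    ("pre", "without"): {
        "A": (0, 70, -48, 59), "B": (43, 95, -97, 39), "C": (80, 97, -147, 40),
        "D": (84, 110, -145, 31), "E": (92, 113, -165, 24), "F": (93, 96, -163, 24),
    },
    ("pre", "with"): {
        "A": (56, 69, -102, 41), "B": (82, 102, -128, 33), "C": (83, 95, -157, 39),
        "D": (97, 95, -186, 17), "E": (92, 110, -173, 23), "F": (99, 95, -213, 14),
    },
    ("post", "without"): {
        "A": (29, 77, -80, 52), "B": (80, 104, -126, 33), "C": (89, 100, -163, 24),
        "D": (97, 121, -227, 20), "E": (95, 105, -176, 17), "F": (99, 110, -250, 11),
    },
    ("post", "with"): {
        "A": (66, 84, -102, 50), "B": (90, 96, -147, 21), "C": (92, 99, -159, 21),
        "D": (94, 122, -208, 24), "E": (93, 111, -173, 22), "F": (100, 109, -263, 10),
    },
}


def reference_summary(participant: str, timepoint: str, feedback: str
                      ) -> dict[str, float]:
    """The four session summaries of one reference cell, as a dict."""
    key = (timepoint, feedback)
    if key not in _TABLE or participant not in _TABLE[key]:
        raise ProfileLookupError(
            f"no reference profile for participant={participant!r}, "
            f"timepoint={timepoint!r}, feedback={feedback!r}"
        )
    pct_good, cadence, av_mean, av_cv = _TABLE[key][participant]
    return {"pct_good": pct_good, "cadence": cadence,
            "av_mean": av_mean, "av_cv": av_cv}


def reference_profile(participant: str, timepoint: str, feedback: str,
                      **overrides) -> GaitProfile:
    """Build a :class:`GaitProfile` from one reference cell.

    Keyword overrides (``bout_plan``, ``seed``, ``noise_sd``, ...) are
    forwarded to the profile.  The default bout plan is a single 120 s
    walk, mirroring a two-minute walking assessment.
    """
    cell = reference_summary(participant, timepoint, feedback)
    profile = GaitProfile(
        cadence=cell["cadence"],
        av_mean=cell["av_mean"],
        av_sd=abs(cell["av_mean"]) * cell["av_cv"] / 100.0,
        p_good=cell["pct_good"] / 100.0,
    )
    return replace(profile, **overrides) if overrides else profile
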