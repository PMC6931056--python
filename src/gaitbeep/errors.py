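"""Exception hierarchy.

Every error raised by the library derives from :class:`GaitError` so callers
(and the CLI) can distinguish usage/configuration problems from bad data.
"""


class GaitError(Exception):
    """Base class for all gaitbeep errors."""


class FormatError(GaitError):
    """Input file does not conform to the expected dialect (missing columns, bad header)."""


class ValidationError(GaitError):
    """Data are syntactically readable but violate an invariant (non-monotonic time, NaN)."""


class EmptyInputError(GaitError):
    """A data section that must contain samples is empty."""


class ConfigurationError(GaitError):
    """Configuration values are inconsistent or unrealizable (e.g. filter above Nyquist)."""


class ParameterError(GaitError):
    """A function argument is outside its documented domain."""


class ProfileLookupError(GaitError, KeyError):
    """Unknown reference-profile key."""


class SequencingError(GaitError):
    """Streaming samples pushed out of time order."""


class StreamClosedError(GaitError):
    """Samples pushed (or finalize called again) after a stream was finalized."""


class ConsistencyError(GaitError):
    """Cross-object inconsistency (e.g. a step event outside every walking bout)."""


class UndefinedStatisticError(GaitError):
    """A statistic is undefined for the given input (CV of <2 values or zero mean)."""
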